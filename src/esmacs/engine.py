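"""Trajectory-combination protocols and the variational entropy estimator.

The binding free energy is the end-state difference

    ΔG = ⟨G_complex⟩ − ⟨G_receptor⟩ − ⟨G_ligand⟩,

where each ⟨·⟩ is an ensemble mean over replica means. The six protocols
differ in where the receptor and ligand terms come from:

============  =========  =============  =============
protocol      complex    receptor       ligand
============  =========  =============  =============
1traj         complex    complex        complex
1traj-ar      complex    constant       complex
2traj-fr      complex    independent R  complex
2traj-fl      complex    complex        independent L
2traj-ar      complex    constant       independent L
3traj         complex    independent R  independent L
============  =========  =============  =============

"complex" means the species is extracted frame-by-frame from the complex
ensemble; "constant" is the averaged-receptor value over a set of
comparable ligands; "independent" means a separately simulated ensemble.

The variational entropy penalty is −TΔS_var = k_B·T·ln⟨exp(β·ΔE_inter)⟩
with ΔE_inter the fluctuation of the receptor–ligand interaction energy
E_inter = G_ele_MM + G_vdW_MM about its ensemble mean; by Jensen's
inequality the penalty is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .model import (COMPONENTS, EnsembleSpec, ValidationError, table_total,
                    validate_energy_table)

PROTOCOLS = ("1traj", "1traj-ar", "2traj-fr", "2traj-fl", "2traj-ar", "3traj")

#: Table of component origins per protocol: (receptor source, ligand source),
#: where "C" = complex-frame extraction, "I" = independent ensemble,
#: "const" = averaged-receptor constant.
_ORIGIN = {
    "1traj": ("C", "C"),
    "1traj-ar": ("const", "C"),
    "2traj-fr": ("I", "C"),
    "2traj-fl": ("C", "I"),
    "2traj-ar": ("const", "I"),
    "3traj": ("I", "I"),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Which protocol to run, with optional water shell and entropy options."""

    protocol: str = "1traj"
    n_waters: int = 0
    entropy: str = "none"  # "none" | "variational"
    comparable_ligands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}; "
                                  f"choose from {PROTOCOLS}")
        if self.entropy not in ("none", "variational"):
            raise ValidationError("entropy must be 'none' or 'variational'")
        if self.protocol.endswith("-ar") and not self.comparable_ligands:
            raise ValidationError(
                f"{self.protocol} requires a non-empty comparable-ligand set")


@dataclass
class BindingEstimate:
    """ΔG_MMPBSA for one ligand with bootstrap uncertainty."""

    ligand_id: str
    protocol: str
    dG: float                      # kcal/mol
    se: float | None = None        # bootstrap standard error
    ci: tuple[float, float] | None = None
    minus_T_dS: float | None = None
    components: dict[str, float] = field(default_factory=dict)
    replica_dG: np.ndarray | None = None  # per-replica ΔG (bootstrap unit)

    @property
    def total(self) -> float:
        """ΔG_MMPBSA plus the entropy penalty when present."""
        return self.dG + (self.minus_T_dS or 0.0)


# ---------------------------------------------------------------------------
# Replica aggregation


def _select(records: pd.DataFrame, role: str, ligand: str) -> pd.DataFrame:
    sub = records[(records["role"] == role) & (records["ligand_id"] == ligand)]
    if sub.empty:
        raise ValidationError(f"no records for role={role!r}, ligand={ligand!r}")
    return sub


def replica_means(records: pd.DataFrame, role: str, ligand: str,
                  ensemble: EnsembleSpec | None = None,
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-replica mean of total G and of each component.

    Returns (total means indexed by replica, component means per replica).
    If an :class:`EnsembleSpec` is given, coverage is checked: every replica
    must have exactly the declared number of frames.
    """
    sub = _select(records, role, ligand)
    if ensemble is not None:
        counts = sub.groupby("replica")["frame"].count()
        if len(counts) != ensemble.replicas or (counts != ensemble.frames).any():
            bad = (counts[counts != ensemble.frames].index.tolist()
                   if len(counts) == ensemble.replicas else
                   sorted(set(range(1, ensemble.replicas + 1)) - set(counts.index)))
            raise ValidationError(
                f"coverage error for role={role!r}, ligand={ligand!r}: expected "
                f"{ensemble.replicas} replicas × {ensemble.frames} frames, "
                f"problem at replica(s) {bad}")
    comp_means = sub.groupby("replica")[list(COMPONENTS)].mean()
    totals = comp_means.sum(axis=1)
    return totals, comp_means


def averaged_receptor_constant(records: pd.DataFrame,
                               comparable_ligands: Iterable[str]) -> float:
    """Mean over comparable ligands of the ensemble-mean receptor G.

    Receptor records must be the complex-frame extractions of each ligand's
    complex ensemble; the result is a single constant reused for every
    ligand in an averaged-receptor (-ar) protocol.
    """
    ligands = sorted(set(comparable_ligands))
    if not ligands:
        raise ValidationError("comparable-ligand set is empty")
    per_ligand = []
    for lig in ligands:
        totals, _ = replica_means(records, "receptor", lig)
        per_ligand.append(totals.mean())
    return float(np.mean(per_ligand))


def protocol_delta_g(spec: ProtocolSpec, complex_records: pd.DataFrame,
                     ligand_id: str,
                     receptor_records: pd.DataFrame | None = None,
                     ligand_records: pd.DataFrame | None = None,
                     ensemble: EnsembleSpec | None = None,
                     ) -> BindingEstimate:
    """ΔG_MMPBSA for one ligand under the chosen protocol (no bootstrap yet).

    ``complex_records`` must contain roles complex/receptor/ligand, all
    extracted from the complex ensemble. Independent-ensemble tables are
    required when the protocol calls for them. The per-replica ΔG series
    (the bootstrap resampling unit) is attached to the estimate.
    """
    complex_records = validate_energy_table(complex_records)
    rec_origin, lig_origin = _ORIGIN[spec.protocol]
    c_tot, c_comp = replica_means(complex_records, "complex", ligand_id, ensemble)

    def term(origin: str, role: str, indep: pd.DataFrame | None):
        if origin == "C":
            return replica_means(complex_records, role, ligand_id, ensemble)
        if origin == "I":
            if indep is None:
                raise ValidationError(
                    f"protocol {spec.protocol} needs an independent {role} "
                    f"ensemble table, which was not provided")
            return replica_means(validate_energy_table(indep), role, ligand_id)
        raise AssertionError(origin)

    comp = {}
    if rec_origin == "const":
        r_const = averaged_receptor_constant(complex_records, spec.comparable_ligands)
        r_tot = pd.Series(r_const, index=c_tot.index)
        r_comp = None
    else:
        r_tot, r_comp = term(rec_origin, "receptor", receptor_records)
    l_tot, l_comp = term(lig_origin, "ligand", ligand_records)

    # replica-level ΔG pairs replicas by index; a mismatch in replica sets
    # between independent ensembles is a configuration error
    for name, series in (("receptor", r_tot), ("ligand", l_tot)):
        if not series.index.equals(c_tot.index):
            raise ValidationError(
                f"replica indices of the {name} ensemble do not match the "
                f"complex ensemble for ligand {ligand_id!r}")
    rep_dg = c_tot - r_tot - l_tot
    if r_comp is not None and l_comp is not None:
        comp = (c_comp.mean() - r_comp.mean() - l_comp.mean()).to_dict()
    return BindingEstimate(
        ligand_id=ligand_id, protocol=spec.protocol,
        dG=float(rep_dg.mean()), components=comp,
        replica_dG=rep_dg.to_numpy())


# ---------------------------------------------------------------------------
# Variational entropy


def interaction_energy_series(complex_records: pd.DataFrame, ligand_id: str,
                              ) -> pd.DataFrame:
    """Per-(replica, frame) receptor–ligand interaction energy from 1traj data.

    E_inter = G_ele_MM + G_vdW_MM of (complex − receptor − ligand) evaluated
    on the same complex frame; internal and solvation terms cancel out of
    the interaction by construction.
    """
    cols = ["G_ele_MM", "G_vdW_MM"]
    parts = {}
    for role in ("complex", "receptor", "ligand"):
        sub = _select(complex_records, role, ligand_id)
        parts[role] = sub.set_index(["replica", "frame"])[cols].sum(axis=1)
    e_inter = parts["complex"] - parts["receptor"] - parts["ligand"]
    if e_inter.isna().any():
        raise ValidationError(
            f"replica/frame keys of complex and extracted species do not "
            f"align for ligand {ligand_id!r}")
    return e_inter.rename("E_inter").reset_index()


def variational_entropy(e_inter: Sequence[float] | pd.DataFrame,
                        constants: PhysicalConstants = DEFAULT_CONSTANTS,
                        per_replica: bool = False) -> float:
    """−TΔS_var = k_B·T·ln⟨exp(β·ΔE_inter)⟩ over pooled frames (kcal/mol).

    Evaluated in log-sum-exp form to avoid overflow. ``per_replica=True``
    averages per-replica estimates instead of pooling frames first; the
    pooled form is canonical here because the exponential average is
    nonlinear.
    """
    if isinstance(e_inter, pd.DataFrame):
        if per_replica:
            vals = [variational_entropy(g["E_inter"].to_numpy(), constants)
                    for _, g in e_inter.groupby("replica")]
            return float(np.mean(vals))
        series = e_inter["E_inter"].to_numpy(dtype=float)
    else:
        series = np.asarray(e_inter, dtype=float)
    if series.size == 0:
        raise ValidationError("variational entropy needs at least one sample")
    beta = constants.beta_thermo
    if np.all(series == series.flat[0]):  # constant series: ΔE ≡ 0 exactly
        return 0.0
    delta = series - series.mean()
    return float(constants.kT * (logsumexp(beta * delta) - np.log(delta.size)))


def total_with_entropy(estimate: BindingEstimate, minus_T_dS: float,
                       ) -> BindingEstimate:
    """Attach the entropy penalty; ``estimate.total`` then includes it."""
    estimate.minus_T_dS = float(minus_T_dS)
    return estimate


def aggregate_estimates(spec: ProtocolSpec, complex_records: pd.DataFrame,
                        receptor_records: pd.DataFrame | None = None,
                        ligand_records: pd.DataFrame | None = None,
                        bootstrap=None,
                        constants: PhysicalConstants = DEFAULT_CONSTANTS,
                        ensemble: EnsembleSpec | None = None,
                        ) -> list[BindingEstimate]:
    """Per-ligand ΔG estimates with bootstrap errors (and entropy if asked).

    Ligands are taken from the complex table. ``bootstrap`` is a
    :class:`~esmacs.stats.BootstrapSpec`; pass ``None`` to skip resampling.
    """
    from .stats import BootstrapSpec, bootstrap_se  # local import: no cycle

    complex_records = validate_energy_table(complex_records)
    ligands = sorted(complex_records.loc[complex_records["role"] == "complex",
                                         "ligand_id"].unique())
    estimates = []
    for lig in ligands:
        est = protocol_delta_g(spec, complex_records, lig,
                               receptor_records, ligand_records, ensemble)
        if bootstrap is not None:
            se, ci = bootstrap_se(est.replica_dG, bootstrap)
            est.se, est.ci = se, ci
        if spec.entropy == "variational":
            series = interaction_energy_series(complex_records, lig)
            est = total_with_entropy(est, variational_entropy(series, constants))
        estimates.append(est)
    return estimates


def estimates_to_frame(estimates: Sequence[BindingEstimate]) -> pd.DataFrame:
    """Flatten estimates into the on-disk CSV layout."""
    rows = []
    for e in estimates:
        rows.append({
            "ligand_id": e.ligand_id, "protocol": e.protocol, "dG": e.dG,
            "err": e.se,
            "ci_low": e.ci[0] if e.ci else None,
            "ci_high": e.ci[1] if e.ci else None,
            "minus_TdS": e.minus_T_dS, "total": e.total})
    return pd.DataFrame(rows)
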