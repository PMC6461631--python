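"""Deterministic synthetic fixtures: energy ensembles and toy complexes.

Two generators make the whole pipeline testable without MD output:

* :func:`gen_energy_ensembles` emulates collated per-frame MMPBSA component
  tables for a set of ligands with known true binding free energies,
  controlled replica-to-replica and frame-to-frame variability, adaptation
  (strain) offsets and interaction-energy fluctuations. Within each complex
  frame the complex row equals the sum of its receptor-extract, ligand-
  extract and interaction parts component-by-component, reproducing the
  cancellation structure that makes single-trajectory analysis low-noise.
* :func:`gen_toy_complex` builds a rigid host cage with a small charged
  ligand in its cavity and waters on concentric shells — a desk-scale stand
  of a solvated protein–ligand complex for the geometric and energy
  backends (synthetic, not derived from any crystal structure).

All randomness flows from one seed through per-ligand/per-replica
``SeedSequence`` splits, so tables are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS
from .model import (ENERGY_COLUMNS, MolecularSystem, TrajectoryFrame,
                    ValidationError, validate_energy_table)
from .sasa import fibonacci_sphere

#: How a scalar noise/mean draw is allocated over the five components.
_WEIGHTS = np.array([0.35, 0.20, 0.25, 0.05, 0.15])
#: Interaction energy split over (G_ele_MM, G_vdW_MM).
_INTER_SPLIT = np.array([0.6, 0.4, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class EnsembleGeneratorConfig:
    """Study conditions for synthetic component-energy ensembles.

    Defaults mirror a 25-replica × 40-frame production ensemble with
    frame-level fluctuations of 3 kcal/mol, replica-level spread of
    1 kcal/mol and interaction-energy fluctuations of 1.5 kcal/mol.
    """

    ligands: dict[str, float] = field(
        default_factory=lambda: {f"L{i:02d}": -5.0 - float(i) for i in range(10)})
    receptor_base: float = -3500.0     # free-receptor mean total G
    ligand_base: float = -45.0         # free-ligand mean total G
    receptor_strain: float = 2.0       # adaptation cost of the bound receptor
    ligand_strain: float = 1.0         # adaptation cost of the bound ligand
    inter_replica_sd: float = 1.0      # kcal/mol, replica-mean spread
    intra_replica_sd: float = 3.0      # kcal/mol, frame noise within a replica
    interaction_sd: float = 1.5        # kcal/mol, E_inter frame fluctuation
    replicas: int = 25
    frames: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.inter_replica_sd, self.intra_replica_sd,
               self.interaction_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.replicas < 1 or self.frames < 1:
            raise ValidationError("need replicas >= 1 and frames >= 1")
        if not self.ligands:
            raise ValidationError("at least one ligand is required")


def _species_rows(rng, mean_total, split, rep_sd, frame_sd, R, F):
    """(R·F, 5) component matrix: mean + replica offset + frame noise."""
    base = mean_total * split
    rep_off = rng.normal(0.0, rep_sd, size=R) if rep_sd > 0 else np.zeros(R)
    frame_noise = (rng.normal(0.0, frame_sd, size=(R, F))
                   if frame_sd > 0 else np.zeros((R, F)))
    scalar = rep_off[:, None] + frame_noise          # (R, F)
    return base[None, None, :] + scalar[:, :, None] * _WEIGHTS[None, None, :]


def gen_energy_ensembles(config: EnsembleGeneratorConfig = EnsembleGeneratorConfig(),
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (complex, receptor, ligand) record tables plus a manifest.

    The complex table holds roles complex/receptor/ligand, the latter two
    being complex-frame extractions; the receptor and ligand tables are the
    independent ensembles. The manifest records, per ligand, the true ΔG
    and the expected value of every protocol estimate together with the
    generator's own standard error for the ligand-level mean, so tests can
    audit recovery against the generator's bookkeeping.
    """
    R, F = config.replicas, config.frames
    replicas = np.repeat(np.arange(1, R + 1), F)
    frames = np.tile(np.arange(1, F + 1), R)
    kT = DEFAULT_CONSTANTS.kT
    rows_complex, rows_receptor, rows_ligand = [], [], []
    manifest: dict = {
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in config.__dict__.items()},
        "ligands": {},
    }
    root = np.random.SeedSequence(config.seed)
    for li, (lig, true_dg) in enumerate(sorted(config.ligands.items())):
        rng = np.random.default_rng(root.spawn(li + 1)[0])
        inter_mean = true_dg - config.receptor_strain - config.ligand_strain

        rex = _species_rows(rng, config.receptor_base + config.receptor_strain,
                            _WEIGHTS, config.inter_replica_sd,
                            config.intra_replica_sd, R, F)
        lex = _species_rows(rng, config.ligand_base + config.ligand_strain,
                            _WEIGHTS, config.inter_replica_sd,
                            config.intra_replica_sd, R, F)
        inter_noise = (rng.normal(0.0, config.interaction_sd, size=(R, F))
                       if config.interaction_sd > 0 else np.zeros((R, F)))
        inter = (inter_mean + inter_noise)[:, :, None] * _INTER_SPLIT[None, None, :]
        cplx = rex + lex + inter

        rec_free = _species_rows(rng, config.receptor_base, _WEIGHTS,
                                 config.inter_replica_sd,
                                 config.intra_replica_sd, R, F)
        lig_free = _species_rows(rng, config.ligand_base, _WEIGHTS,
                                 config.inter_replica_sd,
                                 config.intra_replica_sd, R, F)

        def table(role, mat, rows):
            flat = mat.reshape(R * F, 5)
            rows.append(pd.DataFrame({
                "role": role, "ligand_id": lig,
                "replica": replicas, "frame": frames,
                "G_ele_MM": flat[:, 0], "G_vdW_MM": flat[:, 1],
                "G_int_MM": flat[:, 2], "G_nonpol_sol": flat[:, 3],
                "G_pol_sol": flat[:, 4]}))

        table("complex", cplx, rows_complex)
        table("receptor", rex, rows_complex)
        table("ligand", lex, rows_complex)
        table("receptor", rec_free, rows_receptor)
        table("ligand", lig_free, rows_ligand)

        sr, sf, si = (config.inter_replica_sd, config.intra_replica_sd,
                      config.interaction_sd)
        var_1traj = (si ** 2 / F) / R
        var_3traj = (4 * sr ** 2 + (4 * sf ** 2 + si ** 2) / F) / R
        var_2fl = (sr ** 2 + (sf ** 2)/F)/R + (si ** 2 / F) / R
        manifest["ligands"][lig] = {
            "true_dG": true_dg,
            "expected": {
                "1traj": inter_mean,
                "1traj-ar": None,  # depends on the comparable set
                "2traj-fr": true_dg - config.ligand_strain,
                "2traj-fl": true_dg - config.receptor_strain,
                "2traj-ar": None,
                "3traj": true_dg,
            },
            "se": {"1traj": float(np.sqrt(var_1traj)),
                   "2traj-fl": float(np.sqrt(var_2fl)),
                   "3traj": float(np.sqrt(var_3traj))},
            "expected_minus_T_dS": float(si ** 2 / (2.0 * kT)),
        }
    complex_table = validate_energy_table(pd.concat(rows_complex, ignore_index=True))
    receptor_table = validate_energy_table(pd.concat(rows_receptor, ignore_index=True))
    ligand_table = validate_energy_table(pd.concat(rows_ligand, ignore_index=True))
    return complex_table, receptor_table, ligand_table, manifest


# ---------------------------------------------------------------------------
# Toy host–ligand–water systems


@dataclass(frozen=True)
class ToySystemConfig:
    """Geometry of the synthetic host–ligand–water complex."""

    host_atoms: int = 16
    cavity_radius: float = 7.0       # Å, host cage radius
    ligand_atoms: int = 3
    ligand_spread: float = 0.9       # Å, ligand cluster radius
    water_radii: tuple[float, ...] = (3.5, 4.3, 5.1)  # one water per shell
    host_charge: float = 0.2         # e, alternating ± on cage atoms
    ligand_charge: float = 0.3       # e, total ligand charge
    jitter_sd: float = 0.05          # Å, per-frame Gaussian jitter
    replicas: int = 1
    frames: int = 1
    seed: int = 0
    min_separation: float = 0.8      # Å, initial-placement overlap limit

    def __post_init__(self) -> None:
        if self.host_atoms < 4 or self.ligand_atoms < 1:
            raise ValidationError("need >= 4 host atoms and >= 1 ligand atom")
        if self.jitter_sd < 0:
            raise ValidationError("jitter SD must be >= 0")


def gen_toy_complex(config: ToySystemConfig = ToySystemConfig(),
                    ) -> tuple[MolecularSystem, list[TrajectoryFrame]]:
    """Build the toy complex and its jittered frames (see class docstring)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    coords, ids = [], []
    elements, resnames, resnums, segments, roles = [], [], [], [], []
    charges, sigma, epsilon, radius = [], [], [], []
    next_id = 1

    host_dirs = fibonacci_sphere(config.host_atoms)
    for i, d in enumerate(host_dirs):
        coords.append(config.cavity_radius * d)
        ids.append(next_id); next_id += 1
        elements.append("C"); resnames.append("HST"); resnums.append(1)
        segments.append("H"); roles.append("receptor")
        charges.append(config.host_charge * (1 if i % 2 == 0 else -1))
        sigma.append(3.4); epsilon.append(0.09); radius.append(1.7)
    if config.host_atoms % 2:  # keep the cage neutral
        charges[len(charges) - 1] = 0.0

    lig_dirs = fibonacci_sphere(max(config.ligand_atoms, 2))[:config.ligand_atoms]
    for i, d in enumerate(lig_dirs):
        coords.append(config.ligand_spread * d if config.ligand_atoms > 1
                      else np.zeros(3))
        ids.append(next_id); next_id += 1
        elements.append("C"); resnames.append("LIG"); resnums.append(2)
        segments.append("L"); roles.append("ligand")
        charges.append(config.ligand_charge / config.ligand_atoms)
        sigma.append(3.4); epsilon.append(0.11); radius.append(1.7)

    # waters sit on shells around the ligand, offset from host directions
    water_dirs = fibonacci_sphere(max(len(config.water_radii) * 7, 7))
    for wi, r_shell in enumerate(config.water_radii):
        d = water_dirs[3 * wi + 1]
        o = r_shell * d
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        for name, pos, q in (("O", o, -0.834),
                             ("H", o + 0.9572 * perp, 0.417),
                             ("H", o + 0.9572 * (0.5 * perp + 0.866 * d)
                              / np.linalg.norm(0.5 * perp + 0.866 * d), 0.417)):
            coords.append(pos)
            ids.append(next_id); next_id += 1
            elements.append(name); resnames.append("HOH")
            resnums.append(10 + wi); segments.append("W"); roles.append("water")
            charges.append(q)
            sigma.append(3.15 if name == "O" else 0.4)
            epsilon.append(0.152 if name == "O" else 0.0)
            radius.append(1.6 if name == "O" else 0.3)

    base = np.array(coords)
    d2 = np.sqrt(((base[:, None] - base[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d2, np.inf)
    if d2.min() < config.min_separation:
        raise ValidationError(
            f"initial placement violates the {config.min_separation} Å "
            f"separation limit (closest pair {d2.min():.2f} Å); "
            "adjust shell radii or atom counts")

    # bonded terms: ligand chain bonds at their base lengths (zero strain in
    # the base geometry) and zero-constant water bonds that supply the usual
    # intramolecular nonbonded exclusions without internal energetics
    lig_ids = [ids[i] for i in range(len(ids))
               if roles[i] == "ligand"]
    bonds, bond_params = [], []
    for a, b in zip(lig_ids[:-1], lig_ids[1:]):
        ia, ib = ids.index(a), ids.index(b)
        bonds.append([a, b])
        bond_params.append([300.0, float(np.linalg.norm(base[ia] - base[ib]))])
    angles, angle_params = [], []
    wat_ids = [ids[i] for i in range(len(ids)) if roles[i] == "water"]
    for k in range(0, len(wat_ids), 3):
        o, h1, h2 = wat_ids[k:k + 3]
        bonds.extend([[o, h1], [o, h2]])
        bond_params.extend([[0.0, 0.9572], [0.0, 0.9572]])
        angles.append([h1, o, h2])
        angle_params.append([0.0, 1.8242])

    system = MolecularSystem(
        ids=np.array(ids), elements=np.array(elements),
        resnames=np.array(resnames), resnums=np.array(resnums),
        segments=np.array(segments), charges=np.array(charges, float),
        sigma=np.array(sigma, float), epsilon=np.array(epsilon, float),
        radius=np.array(radius, float), roles=np.array(roles),
        bonds=np.array(bonds, int).reshape(-1, 2),
        bond_params=np.array(bond_params, float).reshape(-1, 2),
        angles=np.array(angles, int).reshape(-1, 3),
        angle_params=np.array(angle_params, float).reshape(-1, 2))

    frames = []
    for rep in range(1, config.replicas + 1):
        for fr in range(1, config.frames + 1):
            jitter = (rng.normal(0.0, config.jitter_sd, size=base.shape)
                      if config.jitter_sd > 0 else 0.0)
            frames.append(TrajectoryFrame(replica=rep, frame=fr,
                                          coords=base + jitter))
    return system, frames
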