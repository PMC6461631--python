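"""Core domain types: molecular systems, trajectory frames and energy records.

A :class:`MolecularSystem` is a fixed set of atoms (with force-field
parameters and a binding role per atom) plus bonded terms; a
:class:`TrajectoryFrame` carries one set of coordinates for those atoms.
Per-frame MMPBSA component energies are tabulated as pandas DataFrames with
the column layout of :data:`ENERGY_COLUMNS`; :class:`ComponentEnergyRecord`
is the single-row view of that table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("receptor", "ligand", "water", "ion")
SPECIES = ("complex", "receptor", "ligand")

#: Residue names auto-labelled as water on input.
WATER_RESNAMES = ("HOH", "WAT", "TIP3")

#: The five per-species component energies (kcal/mol), in canonical order.
COMPONENTS = ("G_ele_MM", "G_vdW_MM", "G_int_MM", "G_nonpol_sol", "G_pol_sol")
KEY_COLUMNS = ("role", "ligand_id", "replica", "frame")
ENERGY_COLUMNS = KEY_COLUMNS + COMPONENTS


class ValidationError(ValueError):
    """Raised when an input record violates a model invariant."""


@dataclass
class MolecularSystem:
    """Atoms, force-field parameters, bonded terms and binding roles.

    Per-atom arrays are aligned; ``ids`` are stable labels preserved through
    subsetting (bonded terms reference ids, not positions).
    """

    ids: np.ndarray            # (n,) int
    elements: np.ndarray       # (n,) str
    resnames: np.ndarray       # (n,) str
    resnums: np.ndarray        # (n,) int
    segments: np.ndarray       # (n,) str
    charges: np.ndarray        # (n,) float, e
    sigma: np.ndarray          # (n,) float, Å
    epsilon: np.ndarray        # (n,) float, kcal/mol
    radius: np.ndarray         # (n,) float, Å (intrinsic/PB radius)
    roles: np.ndarray          # (n,) str in ROLES
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    bond_params: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))   # k, r0
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    angle_params: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # k, θ0
    dihedrals: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))
    dihedral_params: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))  # V, n, δ

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("elements", "resnames", "resnums", "segments", "charges",
                     "sigma", "epsilon", "radius", "roles"):
            arr = np.asarray(getattr(self, name))
            if arr.dtype.kind in "US":
                arr = arr.astype(object)  # avoid fixed-width truncation on edit
            if arr.shape[0] != n:
                raise ValidationError(f"field {name!r} length {arr.shape[0]} != atom count {n}")
            setattr(self, name, arr)
        self.ids = np.asarray(self.ids, dtype=int)
        if len(np.unique(self.ids)) != n:
            raise ValidationError("atom ids must be unique")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if np.any(self.radius <= 0):
            bad = self.ids[self.radius <= 0][0]
            raise ValidationError(f"atom {bad}: intrinsic radius must be > 0")
        if np.any(self.epsilon < 0):
            bad = self.ids[self.epsilon < 0][0]
            raise ValidationError(f"atom {bad}: LJ epsilon must be >= 0")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValidationError(f"unknown role label(s): {sorted(unknown)}")
        for label, terms in (("bond", self.bonds), ("angle", self.angles),
                             ("dihedral", self.dihedrals)):
            t = np.asarray(terms, dtype=int)
            if t.size:
                ok = np.isin(t, self.ids)
                if not ok.all():
                    raise ValidationError(
                        f"{label} references unknown atom id {int(t[~ok][0])}")
        for mol in self.water_molecules():
            if len(mol) != 3:
                raise ValidationError(
                    f"water residue {mol} has {len(mol)} atoms; waters must be 3-atom molecules")

    # -- convenience -----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        """Positions of the given atom ids in the per-atom arrays."""
        lookup = {int(a): i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[int(a)] for a in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - guarded by validate()
            raise ValidationError(f"unknown atom id {exc.args[0]}") from exc

    def water_molecules(self) -> list[tuple[int, ...]]:
        """Water molecules as tuples of atom ids, grouped by (segment, resnum)."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i in np.flatnonzero(self.roles == "water"):
            key = (str(self.segments[i]), int(self.resnums[i]))
            groups.setdefault(key, []).append(int(self.ids[i]))
        return [tuple(v) for _, v in sorted(groups.items())]

    def mask(self, role_set: Iterable[str]) -> np.ndarray:
        role_set = set(role_set)
        return np.isin(self.roles, sorted(role_set))


@dataclass
class TrajectoryFrame:
    """Coordinates (Å) for all atoms of one system at one snapshot."""

    replica: int
    frame: int
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in frame "
                                  f"(replica={self.replica}, frame={self.frame})")

    def check(self, system: MolecularSystem) -> None:
        if self.coords.shape[0] != system.n_atoms:
            raise ValidationError(
                f"frame has {self.coords.shape[0]} coordinates, "
                f"system has {system.n_atoms} atoms")


@dataclass(frozen=True)
class EnsembleSpec:
    """Replica/frame layout of an ensemble (defaults: 25 replicas × 40 frames)."""

    replicas: int = 25
    frames: int = 40

    def __post_init__(self) -> None:
        if self.replicas < 1 or self.frames < 1:
            raise ValidationError("EnsembleSpec requires replicas >= 1 and frames >= 1")


@dataclass(frozen=True)
class ComponentEnergyRecord:
    """One frame's five component energies for one species/replica/frame."""

    role: str
    ligand_id: str
    replica: int
    frame: int
    G_ele_MM: float
    G_vdW_MM: float
    G_int_MM: float
    G_nonpol_sol: float
    G_pol_sol: float

    def __post_init__(self) -> None:
        if self.role not in SPECIES:
            raise ValidationError(f"role must be one of {SPECIES}, got {self.role!r}")
        for comp in COMPONENTS:
            if not np.isfinite(getattr(self, comp)):
                raise ValidationError(f"{comp} is not finite for "
                                      f"({self.role}, {self.ligand_id}, {self.replica}, {self.frame})")

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)


@dataclass(frozen=True)
class ExperimentalRecord:
    """One ligand's experimental affinity (ΔG in kcal/mol and/or pIC50)."""

    ligand_id: str
    dataset: str = "DIV"
    dG_expt: float | None = None
    dG_err: float | None = None
    pIC50: float | None = None
    bound: bool = False  # True for '<' entries (affinity is an upper bound)

    def __post_init__(self) -> None:
        if self.dG_expt is None and self.pIC50 is None:
            raise ValidationError(f"ligand {self.ligand_id}: need dG_expt or pIC50")


# ---------------------------------------------------------------------------
# Energy-record tables


def records_to_table(records: Iterable[ComponentEnergyRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(ENERGY_COLUMNS))
    return validate_energy_table(df)


def validate_energy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check column layout, dtypes, finiteness and key uniqueness."""
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"energy table missing column(s): {missing}")
    df = df[list(ENERGY_COLUMNS)].copy()
    for col in ("replica", "frame"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    for col in COMPONENTS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = vals.astype(float)
        if not np.all(np.isfinite(df[col].to_numpy())):
            raise ValidationError(f"non-finite value in column {col!r}")
    bad_role = set(df["role"]) - set(SPECIES)
    if bad_role:
        raise ValidationError(f"unknown role(s) in energy table: {sorted(bad_role)}")
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        key = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise ValidationError(f"duplicate energy-record key {tuple(key)}")
    return df


def concat_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate record tables; key sets must be disjoint."""
    out = pd.concat(tables, ignore_index=True)
    return validate_energy_table(out)


def table_total(df: pd.DataFrame) -> pd.Series:
    """Per-row total G = sum of the five components."""
    return df[list(COMPONENTS)].sum(axis=1)


def extract_subsystem(system: MolecularSystem, frame: TrajectoryFrame,
                      role_set: Iterable[str],
                      ) -> tuple[MolecularSystem, TrajectoryFrame]:
    """Select the atoms with roles in ``role_set``, keeping complex-frame coordinates.

    Bonded terms are retained only when wholly internal to the selection, so
    a term spanning receptor and ligand appears in neither subsystem.
    """
    role_set = set(role_set)
    if not role_set:
        raise ValidationError("role_set must be non-empty")
    frame.check(system)
    keep = system.mask(role_set)
    if not keep.any():
        raise ValidationError(f"role_set {sorted(role_set)} selects zero atoms")
    idx = np.flatnonzero(keep)
    kept_ids = set(system.ids[idx].tolist())

    def filter_terms(terms: np.ndarray, params: np.ndarray):
        if not len(terms):
            return terms, params
        inside = np.array([all(int(a) in kept_ids for a in row) for row in terms])
        return terms[inside], params[inside]

    bonds, bond_params = filter_terms(system.bonds, system.bond_params)
    angles, angle_params = filter_terms(system.angles, system.angle_params)
    dihedrals, dihedral_params = filter_terms(system.dihedrals, system.dihedral_params)
    sub = MolecularSystem(
        ids=system.ids[idx], elements=system.elements[idx],
        resnames=system.resnames[idx], resnums=system.resnums[idx],
        segments=system.segments[idx], charges=system.charges[idx],
        sigma=system.sigma[idx], epsilon=system.epsilon[idx],
        radius=system.radius[idx], roles=system.roles[idx],
        bonds=bonds, bond_params=bond_params,
        angles=angles, angle_params=angle_params,
        dihedrals=dihedrals, dihedral_params=dihedral_params,
    )
    sub_frame = TrajectoryFrame(replica=frame.replica, frame=frame.frame,
                                coords=frame.coords[idx].copy())
    return sub, sub_frame
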