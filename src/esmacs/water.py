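"""Explicit-water augmentation of the receptor.

Continuum solvent misses bridging waters in the binding site, so the N
water molecules closest to the ligand in a frame can be relabelled as
receptor atoms: the complex species becomes protein + N waters + ligand and
the receptor species protein + N waters, while the ligand is unchanged.
Waters outside the shell are dropped from the analysis species for that
frame. Selection is recomputed every frame by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import MolecularSystem, TrajectoryFrame, ValidationError

Metric = Literal["oxygen-heavy", "com-heavy", "any-any"]


@dataclass(frozen=True)
class WaterShellSpec:
    """Closest-N water selection rule.

    ``metric`` choices: "oxygen-heavy" (water oxygen to nearest ligand heavy
    atom — default), "com-heavy" (water centre of mass), "any-any" (minimum
    over all atom pairs). Ties are broken by water molecule id (the id of
    the molecule's first atom), lowest first.
    """

    n_waters: int = 0
    metric: Metric = "oxygen-heavy"
    per_trajectory: bool = False  # majority-vote membership across frames

    def __post_init__(self) -> None:
        if self.n_waters < 0:
            raise ValidationError("water count must be >= 0")


def _ligand_reference(system: MolecularSystem, coords: np.ndarray,
                      metric: Metric) -> np.ndarray:
    lig = system.roles == "ligand"
    if not lig.any():
        raise ValidationError("system has no ligand atoms to measure distances from")
    if metric in ("oxygen-heavy", "com-heavy"):
        heavy = lig & (system.elements != "H")
        if heavy.any():
            return coords[heavy]
    return coords[lig]


def rank_waters(system: MolecularSystem, frame: TrajectoryFrame,
                metric: Metric = "oxygen-heavy") -> list[tuple[int, float]]:
    """Water molecules ordered by distance to the ligand (ascending).

    Returns (molecule id, distance Å) with molecule id = id of the water's
    first atom; equal distances are ordered by molecule id.
    """
    frame.check(system)
    lig_pts = _ligand_reference(system, frame.coords, metric)
    entries = []
    for mol in system.water_molecules():
        idx = system.index_of(mol)
        if metric == "oxygen-heavy":
            oxy = [i for i in idx if str(system.elements[i]).upper().startswith("O")]
            pts = frame.coords[oxy if oxy else idx[:1]]
        elif metric == "com-heavy":
            pts = frame.coords[idx].mean(axis=0, keepdims=True)
        else:
            pts = frame.coords[idx]
        d = np.sqrt(((pts[:, None, :] - lig_pts[None, :, :]) ** 2).sum(-1)).min()
        entries.append((int(mol[0]), float(d)))
    entries.sort(key=lambda e: (e[1], e[0]))
    return entries


def apply_shell(system: MolecularSystem, frame: TrajectoryFrame,
                spec: WaterShellSpec) -> MolecularSystem:
    """Relabel the closest-N waters as receptor and drop the rest.

    Returns a system valid for this frame only (water membership is
    frame-dependent); the returned system contains no atoms with role
    "water".
    """
    frame.check(system)
    waters = system.water_molecules()
    if spec.n_waters > len(waters):
        raise ValidationError(
            f"requested {spec.n_waters} shell waters but only "
            f"{len(waters)} water molecules are present")
    if spec.n_waters == 0 and not waters:
        return system
    ranked = rank_waters(system, frame, spec.metric)
    selected = {mol_id for mol_id, _ in ranked[:spec.n_waters]}
    sel_atom_ids: set[int] = set()
    for mol in waters:
        if mol[0] in selected:
            sel_atom_ids.update(mol)
    roles = system.roles.copy()
    for i, aid in enumerate(system.ids):
        if int(aid) in sel_atom_ids:
            roles[i] = "receptor"
    keep = roles != "water"  # unselected waters leave the analysis species
    idx = np.flatnonzero(keep)
    kept = set(system.ids[idx].tolist())

    def filt(terms, params):
        if not len(terms):
            return terms, params
        inside = np.array([all(int(a) in kept for a in row) for row in terms])
        return terms[inside], params[inside]

    bonds, bond_params = filt(system.bonds, system.bond_params)
    angles, angle_params = filt(system.angles, system.angle_params)
    dihedrals, dihedral_params = filt(system.dihedrals, system.dihedral_params)
    return MolecularSystem(
        ids=system.ids[idx], elements=system.elements[idx],
        resnames=system.resnames[idx], resnums=system.resnums[idx],
        segments=system.segments[idx], charges=system.charges[idx],
        sigma=system.sigma[idx], epsilon=system.epsilon[idx],
        radius=system.radius[idx], roles=roles[idx],
        bonds=bonds, bond_params=bond_params,
        angles=angles, angle_params=angle_params,
        dihedrals=dihedrals, dihedral_params=dihedral_params)


def shell_frame(system: MolecularSystem, frame: TrajectoryFrame,
                shelled: MolecularSystem) -> TrajectoryFrame:
    """Coordinates of the shelled system taken from the full-complex frame."""
    idx = system.index_of(shelled.ids)
    return TrajectoryFrame(replica=frame.replica, frame=frame.frame,
                           coords=frame.coords[idx].copy())
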