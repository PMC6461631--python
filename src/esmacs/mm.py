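"""Molecular-mechanics energy terms for single frames.

The gas-phase part of the MMPBSA decomposition: pairwise Coulomb and
Lennard-Jones sums (no cutoff — single-frame analysis convention) and the
internal bonded energy (AMBER functional forms, i.e. no factor ½ on the
harmonic bond/angle constants).

Nonbonded exclusions follow the bonded graph: 1-2 and 1-3 pairs are
excluded, 1-4 pairs are scaled by the AMBER factors (electrostatics ÷ 1.2,
van der Waals ÷ 2.0, both configurable).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB
from .model import MolecularSystem, TrajectoryFrame, ValidationError


class GeometryError(ValueError):
    """Raised for degenerate geometries (coincident atoms, collinear angles)."""


@dataclass(frozen=True)
class NonbondedOptions:
    scale_ee_14: float = 1.2   # 1-4 electrostatic divisor (AMBER SCEE)
    scale_vdw_14: float = 2.0  # 1-4 van der Waals divisor (AMBER SCNB)


def bonded_separation_masks(system: MolecularSystem) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n, n) masks: pairs excluded (1-2/1-3) and pairs scaled (1-4)."""
    n = system.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    if len(system.bonds):
        bidx = system.index_of(system.bonds[:, 0]), system.index_of(system.bonds[:, 1])
        for i, j in zip(*bidx):
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
    excluded = np.zeros((n, n), dtype=bool)
    scaled = np.zeros((n, n), dtype=bool)
    for start in range(n):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if dist[u] == 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v, d in dist.items():
            if v == start:
                continue
            if d <= 2:
                excluded[start, v] = True
            elif d == 3:
                scaled[start, v] = True
    scaled &= ~excluded
    return excluded, scaled


def _pair_matrices(system: MolecularSystem, frame: TrajectoryFrame):
    frame.check(system)
    x = frame.coords
    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return r


def mm_nonbonded(system: MolecularSystem, frame: TrajectoryFrame,
                 options: NonbondedOptions = NonbondedOptions(),
                 ) -> tuple[float, float]:
    """Coulomb and Lennard-Jones pair sums over the whole system (kcal/mol).

    Coulomb: Σ 332.0636·q_i·q_j / r_ij with a vacuum dielectric of 1 and no
    cutoff. LJ: Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with Lorentz–Berthelot
    combination rules.
    """
    n = system.n_atoms
    if n < 2:
        return 0.0, 0.0
    r = _pair_matrices(system, frame)
    excluded, scaled = bonded_separation_masks(system)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    active = upper & ~excluded
    if np.any(r[active] == 0.0):
        ii, jj = np.nonzero(active & (r == 0.0))
        raise GeometryError(
            f"zero distance between non-excluded atoms "
            f"{int(system.ids[ii[0]])} and {int(system.ids[jj[0]])}")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(r > 0, 1.0 / r, 0.0)
    qq = np.outer(system.charges, system.charges)
    ele = COULOMB * qq * inv_r
    sig = 0.5 * (system.sigma[:, None] + system.sigma[None, :])
    eps = np.sqrt(np.outer(system.epsilon, system.epsilon))
    sr6 = (sig * inv_r) ** 6
    vdw = 4.0 * eps * (sr6 ** 2 - sr6)
    scale = np.zeros((n, n))
    scale[active] = 1.0
    scale_v = scale.copy()
    scale[scaled & upper] = 1.0 / options.scale_ee_14
    scale_v[scaled & upper] = 1.0 / options.scale_vdw_14
    return float(np.sum(ele * scale)), float(np.sum(vdw * scale_v))


def cross_nonbonded(system: MolecularSystem, frame: TrajectoryFrame,
                    group_a: np.ndarray, group_b: np.ndarray,
                    options: NonbondedOptions = NonbondedOptions(),
                    ) -> tuple[float, float]:
    """Coulomb/LJ sums restricted to pairs with one atom in each group.

    ``group_a``/``group_b`` are boolean masks over the system's atoms. This
    is the receptor↔ligand interaction energy used by the variational
    entropy estimator; exclusions and 1-4 scaling still apply if bonded
    terms span the groups.
    """
    frame.check(system)
    n = system.n_atoms
    r = _pair_matrices(system, frame)
    excluded, scaled = bonded_separation_masks(system)
    cross = np.outer(group_a, group_b) | np.outer(group_b, group_a)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    active = upper & cross & ~excluded
    if np.any(r[active] == 0.0):
        raise GeometryError("zero distance between interacting group atoms")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(r > 0, 1.0 / r, 0.0)
    qq = np.outer(system.charges, system.charges)
    sig = 0.5 * (system.sigma[:, None] + system.sigma[None, :])
    eps = np.sqrt(np.outer(system.epsilon, system.epsilon))
    sr6 = (sig * inv_r) ** 6
    scale = np.zeros((n, n))
    scale[active] = 1.0
    scale_v = scale.copy()
    sc14 = scaled & upper & cross
    scale[sc14] = 1.0 / options.scale_ee_14
    scale_v[sc14] = 1.0 / options.scale_vdw_14
    ele = float(np.sum(COULOMB * qq * inv_r * scale))
    vdw = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6) * scale_v))
    return ele, vdw


def mm_internal(system: MolecularSystem, frame: TrajectoryFrame) -> float:
    """Internal bonded energy: Σ k(r−r0)² + Σ k(θ−θ0)² + Σ (V/2)(1+cos(nφ−δ))."""
    frame.check(system)
    x = frame.coords
    energy = 0.0
    if len(system.bonds):
        i = system.index_of(system.bonds[:, 0])
        j = system.index_of(system.bonds[:, 1])
        r = np.linalg.norm(x[i] - x[j], axis=1)
        k, r0 = system.bond_params.T
        energy += float(np.sum(k * (r - r0) ** 2))
    if len(system.angles):
        i = system.index_of(system.angles[:, 0])
        j = system.index_of(system.angles[:, 1])
        k_ = system.index_of(system.angles[:, 2])
        v1 = x[i] - x[j]
        v2 = x[k_] - x[j]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
        sin2 = 1.0 - np.clip(cosang, -1.0, 1.0) ** 2
        if np.any(sin2 < 1e-16):
            t = int(np.flatnonzero(sin2 < 1e-16)[0])
            raise GeometryError(
                f"collinear atoms in angle term "
                f"({int(system.angles[t, 0])}, {int(system.angles[t, 1])}, "
                f"{int(system.angles[t, 2])})")
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        kth, th0 = system.angle_params.T
        energy += float(np.sum(kth * (theta - th0) ** 2))
    if len(system.dihedrals):
        i = system.index_of(system.dihedrals[:, 0])
        j = system.index_of(system.dihedrals[:, 1])
        k_ = system.index_of(system.dihedrals[:, 2])
        l_ = system.index_of(system.dihedrals[:, 3])
        b1 = x[j] - x[i]
        b2 = x[k_] - x[j]
        b3 = x[l_] - x[k_]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
        cosphi = np.einsum("ij,ij->i", n1, n2)
        sinphi = np.einsum("ij,ij->i", m1, n2)
        phi = np.arctan2(sinphi, cosphi)
        barrier, period, phase = system.dihedral_params.T
        energy += float(np.sum(0.5 * barrier * (1.0 + np.cos(period * phi - phase))))
    return energy
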