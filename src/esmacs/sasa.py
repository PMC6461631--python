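"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom's accessible sphere (radius = intrinsic radius + probe) is
sampled with a deterministic Fibonacci-lattice quadrature; a point is
accessible when it lies outside every other atom's accessible sphere. The
per-atom areas sum to the total by construction.
"""

from __future__ import annotations

import numpy as np

from .model import MolecularSystem, TrajectoryFrame

DEFAULT_PROBE = 1.4     # Å, water probe
DEFAULT_POINTS = 960    # quadrature points per atom


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(system: MolecularSystem, frame: TrajectoryFrame,
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
         ) -> tuple[float, np.ndarray]:
    """Total and per-atom SASA in Å²."""
    frame.check(system)
    x = frame.coords
    n = system.n_atoms
    rad = system.radius + probe
    pts = fibonacci_sphere(n_points)
    per_atom = np.zeros(n)
    if n > 1:
        diff = x[:, None, :] - x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
    for i in range(n):
        if n > 1:
            cutoff = (rad[i] + rad) ** 2
            nbr = np.flatnonzero((d2[i] < cutoff) & (np.arange(n) != i))
        else:
            nbr = np.empty(0, dtype=int)
        surface = x[i] + rad[i] * pts
        if len(nbr):
            dd = surface[:, None, :] - x[nbr][None, :, :]
            inside = np.any(np.einsum("pjk,pjk->pj", dd, dd) < rad[nbr] ** 2, axis=1)
            frac = 1.0 - inside.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * rad[i] ** 2 * frac
    return float(per_atom.sum()), per_atom
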