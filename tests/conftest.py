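import numpy as np
import pytest

from esmacs.model import MolecularSystem, TrajectoryFrame
from esmacs.synthetic import (EnsembleGeneratorConfig, ToySystemConfig,
                              gen_energy_ensembles, gen_toy_complex)


def make_system(coords, charges, *, radius=1.6, sigma=3.2, epsilon=0.1,
                roles=None, resnames=None, resnums=None, elements=None,
                bonds=None, bond_params=None, angles=None, angle_params=None,
                dihedrals=None, dihedral_params=None, segments=None):
    """Small-system builder for hand-constructed fixtures."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)

    def arr(val, default, dtype=None):
        if val is None:
            val = [default] * n
        if np.isscalar(val):
            val = [val] * n
        return np.asarray(val, dtype=dtype)

    kwargs = {}
    for name, terms, params, width in (
            ("bonds", bonds, bond_params, 2),
            ("angles", angles, angle_params, 3),
            ("dihedrals", dihedrals, dihedral_params, 4)):
        if terms is not None:
            kwargs[name] = np.asarray(terms, int).reshape(-1, width)
            kwargs[name.rstrip("s") + "_params"] = np.asarray(params, float)
    system = MolecularSystem(
        ids=np.arange(1, n + 1),
        elements=arr(elements, "C"),
        resnames=arr(resnames, "MOL"),
        resnums=arr(resnums, 1, int),
        segments=arr(segments, "A"),
        charges=arr(charges, 0.0, float),
        sigma=arr(sigma, 3.2, float),
        epsilon=arr(epsilon, 0.1, float),
        radius=arr(radius, 1.6, float),
        roles=arr(roles, "ligand"),
        **kwargs)
    frame = TrajectoryFrame(replica=1, frame=1, coords=coords)
    return system, frame


@pytest.fixture
def single_ion():
    """A +1e ion of radius 2 Å at the origin — the Born oracle fixture."""
    return make_system([[0.0, 0.0, 0.0]], [1.0], radius=2.0, epsilon=0.0,
                       roles=["ion"], resnames=["ION"])


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic host–ligand–water complex, no jitter."""
    return gen_toy_complex(ToySystemConfig(jitter_sd=0.0))


@pytest.fixture(scope="session")
def noise_free_ensembles():
    config = EnsembleGeneratorConfig(
        ligands={"A": -7.0, "B": -9.0, "C": -5.5},
        inter_replica_sd=0.0, intra_replica_sd=0.0, interaction_sd=0.0,
        replicas=4, frames=5, seed=11)
    return config, *gen_energy_ensembles(config)


@pytest.fixture(scope="session")
def noisy_ensembles():
    config = EnsembleGeneratorConfig(
        ligands={f"L{i}": -4.0 - i for i in range(8)},
        replicas=25, frames=40, seed=5)
    return config, *gen_energy_ensembles(config)
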