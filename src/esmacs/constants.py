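"""Physical constants used throughout the package.

Energies are kcal/mol, lengths Å, charges elementary charges, angles
radians. The electrostatic conversion factor follows the AMBER convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal/mol/K (AMBER convention).
K_B = 0.0019872

#: Analysis temperature in K (matches the simulation thermostat).
T_DEFAULT = 300.0

#: Coulomb conversion factor in kcal·Å/mol/e² (AMBER convention).
COULOMB = 332.0636


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants bundled so T can be overridden in config.

    ``beta_thermo`` is 1/(k_B·T); the nonpolar-model offset is a different
    quantity and lives on :class:`~esmacs.energy.NonpolarModel` as ``beta_np``.
    """

    k_B: float = K_B
    T: float = T_DEFAULT
    coulomb: float = COULOMB

    @property
    def kT(self) -> float:
        return self.k_B * self.T

    @property
    def beta_thermo(self) -> float:
        return 1.0 / (self.k_B * self.T)

    def __post_init__(self) -> None:
        if self.k_B <= 0 or self.T <= 0:
            raise ValueError("k_B and T must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()
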