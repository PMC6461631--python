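"""Per-frame assembly of the five MMPBSA component energies.

For one species (complex, receptor or ligand) on one frame:

* ``G_ele_MM``, ``G_vdW_MM`` — gas-phase Coulomb/LJ pair sums,
* ``G_int_MM`` — bonded (internal) energy,
* ``G_nonpol_sol`` — γ·SASA + β with γ = 0.00542 kcal/mol/Å² and
  β = 0.92 kcal/mol (the one-term surface-area model),
* ``G_pol_sol`` — finite-difference PB polar solvation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mm import NonbondedOptions, mm_internal, mm_nonbonded
from .model import ComponentEnergyRecord, MolecularSystem, TrajectoryFrame, ValidationError
from .pb import PBGridSpec, pb_polar_solvation
from .sasa import DEFAULT_POINTS, DEFAULT_PROBE, sasa


@dataclass(frozen=True)
class NonpolarModel:
    """One-term SASA nonpolar solvation model: G = γ·SASA + β_np."""

    gamma: float = 0.00542      # kcal/mol/Å², surface tension
    beta_np: float = 0.92       # kcal/mol, offset
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_POINTS

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("surface tension gamma must be > 0")


def nonpolar_solvation(sasa_total: float,
                       model: NonpolarModel = NonpolarModel()) -> float:
    """γ·SASA + β_np (the offset applies even at zero area)."""
    if sasa_total < 0:
        raise ValidationError("SASA must be non-negative")
    return model.gamma * sasa_total + model.beta_np


def species_frame_records(system: MolecularSystem, frame: TrajectoryFrame,
                          ligand_id: str,
                          shell: "WaterShellSpec | None" = None,
                          grid: PBGridSpec = PBGridSpec(),
                          model: NonpolarModel = NonpolarModel(),
                          nb_options: NonbondedOptions = NonbondedOptions(),
                          ) -> list[ComponentEnergyRecord]:
    """Complex/receptor/ligand component records for one complex frame.

    The receptor and ligand species are extracted from the complex frame
    (single-trajectory convention). When a water shell is requested, the
    closest-N waters join the complex and receptor species; all other
    waters leave the analysis.
    """
    from .model import extract_subsystem
    from .water import WaterShellSpec, apply_shell, shell_frame

    shell = shell or WaterShellSpec(0)
    shelled = apply_shell(system, frame, shell)
    fr = shell_frame(system, frame, shelled)
    records = [frame_components(shelled, fr, "complex", ligand_id,
                                grid, model, nb_options)]
    for role_set, role in ((("receptor", "ion"), "receptor"),
                           (("ligand",), "ligand")):
        present = [r for r in role_set if (shelled.roles == r).any()]
        sub, sub_fr = extract_subsystem(shelled, fr, present)
        records.append(frame_components(sub, sub_fr, role, ligand_id,
                                        grid, model, nb_options))
    return records


def frame_components(system: MolecularSystem, frame: TrajectoryFrame,
                     role: str, ligand_id: str,
                     grid: PBGridSpec = PBGridSpec(),
                     model: NonpolarModel = NonpolarModel(),
                     nb_options: NonbondedOptions = NonbondedOptions(),
                     ) -> ComponentEnergyRecord:
    """Evaluate all five components of one species on one frame."""
    g_ele, g_vdw = mm_nonbonded(system, frame, nb_options)
    g_int = mm_internal(system, frame)
    total_sasa, _ = sasa(system, frame, probe=model.probe, n_points=model.n_points)
    g_np = nonpolar_solvation(total_sasa, model)
    g_pol = pb_polar_solvation(system, frame, grid)
    return ComponentEnergyRecord(
        role=role, ligand_id=ligand_id,
        replica=frame.replica, frame=frame.frame,
        G_ele_MM=g_ele, G_vdW_MM=g_vdw, G_int_MM=g_int,
        G_nonpol_sol=g_np, G_pol_sol=g_pol)
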