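"""Compare the six trajectory-combination protocols on synthetic ensembles.

Generates 25-replica x 40-frame component-energy ensembles for three
ligands with known true binding free energies, then shows how the protocol
choice moves the estimate: single-trajectory analysis misses the
adaptation (strain) energies that multi-trajectory protocols capture.
Also evaluates the variational entropy penalty from the interaction-energy
fluctuations of the complex ensemble.
"""

from esmacs import (BootstrapSpec, EnsembleGeneratorConfig, ProtocolSpec,
                    gen_energy_ensembles, interaction_energy_series,
                    protocol_delta_g, variational_entropy)

config = EnsembleGeneratorConfig(
    ligands={"lig-A": -7.0, "lig-B": -9.0, "lig-C": -5.5}, seed=7)
cpx, rec, lig, manifest = gen_energy_ensembles(config)

print(f"receptor strain {config.receptor_strain} kcal/mol, "
      f"ligand strain {config.ligand_strain} kcal/mol\n")
print(f"{'ligand':>7s} {'true':>6s} {'1traj':>7s} {'2traj-fl':>9s} {'3traj':>7s} "
      f"{'-TdS_var':>9s}")
for lid, truth in sorted(config.ligands.items()):
    e1 = protocol_delta_g(ProtocolSpec("1traj"), cpx, lid)
    e2 = protocol_delta_g(ProtocolSpec("2traj-fl"), cpx, lid,
                          ligand_records=lig)
    e3 = protocol_delta_g(ProtocolSpec("3traj"), cpx, lid,
                          receptor_records=rec, ligand_records=lig)
    ent = variational_entropy(interaction_energy_series(cpx, lid))
    print(f"{lid:>7s} {truth:6.1f} {e1.dG:7.2f} {e2.dG:9.2f} {e3.dG:7.2f} "
          f"{ent:9.2f}")

print("\n1traj sits ~3 kcal/mol below truth (it omits both strain terms), "
      "2traj-fl recovers the ligand strain, 3traj estimates the full cycle; "
      "-TdS_var is the entropic penalty from interaction-energy fluctuations "
      "(sigma^2/2kT ~ 1.9 kcal/mol at the generator's 1.5 kcal/mol sigma).")
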