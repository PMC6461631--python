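"""Core types, file formats and subsystem extraction."""

import numpy as np
import pandas as pd
import pytest

from esmacs.io import (dumps_pdb, dumps_topology, loads_pdb_frames,
                       loads_topology, read_energy_table,
                       read_experimental_table, read_system,
                       write_energy_table, write_experimental_table,
                       write_system)
from esmacs.model import (ComponentEnergyRecord, EnsembleSpec,
                          ExperimentalRecord, ValidationError, concat_tables,
                          extract_subsystem, records_to_table)
from esmacs.synthetic import EnsembleGeneratorConfig, gen_energy_ensembles

from conftest import make_system

WATER_TOPOLOGY = """{
 "atoms": [
  {"id": 1, "element": "O", "resname": "HOH", "resnum": 1, "segment": "W",
   "charge": -0.834, "sigma": 3.15, "epsilon": 0.152, "radius": 1.6},
  {"id": 2, "element": "H", "resname": "HOH", "resnum": 1, "segment": "W",
   "charge": 0.417, "sigma": 0.4, "epsilon": 0.0, "radius": 0.3},
  {"id": 3, "element": "H", "resname": "HOH", "resnum": 1, "segment": "W",
   "charge": 0.417, "sigma": 0.4, "epsilon": 0.0, "radius": 0.3}
 ]
}"""

WATER_PDB = """ATOM      1 O    HOH    1       0.000   0.000   0.000  1.00  0.00      W    O
ATOM      2 H    HOH    1       0.957   0.000   0.000  1.00  0.00      W    H
ATOM      3 H    HOH    1      -0.240   0.927   0.000  1.00  0.00      W    H
END
"""


class TestReadSystem:
    def test_water_auto_labelled(self):
        system, frames = read_system(WATER_TOPOLOGY, WATER_PDB)
        assert system.n_atoms == 3
        assert list(system.roles) == ["water"] * 3
        assert system.water_molecules() == [(1, 2, 3)]
        assert len(frames) == 1
        np.testing.assert_allclose(frames[0].coords[1], [0.957, 0.0, 0.0])

    def test_atom_count_mismatch_is_an_error(self):
        short_pdb = "\n".join(WATER_PDB.splitlines()[:2]) + "\nEND\n"
        with pytest.raises(ValidationError, match="mismatch"):
            read_system(WATER_TOPOLOGY, short_pdb)

    def test_unknown_role_is_an_error(self):
        bad = WATER_TOPOLOGY.replace('"resname": "HOH"', '"resname": "XXX"')
        with pytest.raises(ValidationError, match="role"):
            loads_topology(bad)
        labelled = WATER_TOPOLOGY.replace('"radius": 1.6',
                                          '"radius": 1.6, "role": "sol"')
        with pytest.raises(ValidationError, match="sol"):
            loads_topology(labelled)

    def test_round_trip_is_lossless(self):
        system, frames = read_system(WATER_TOPOLOGY, WATER_PDB)
        top2, pdb2 = write_system(system, frames)
        system2, frames2 = read_system(top2, pdb2)
        for field in ("ids", "charges", "sigma", "epsilon", "radius"):
            np.testing.assert_array_equal(getattr(system, field),
                                          getattr(system2, field))
        assert list(system.roles) == list(system2.roles)
        # PDB coordinates are written at 3-decimal precision
        np.testing.assert_array_equal(frames[0].coords, frames2[0].coords)

    def test_multi_model_pdb_maps_to_frames(self):
        system, frames = read_system(WATER_TOPOLOGY, WATER_PDB)
        frames[0].replica = 1
        shifted = frames[0].coords + 1.0
        from esmacs.model import TrajectoryFrame
        two = [frames[0], TrajectoryFrame(replica=1, frame=2, coords=shifted)]
        pdb = dumps_pdb(system, two)
        assert pdb.count("MODEL") == pdb.count("ENDMDL") == 2
        back = loads_pdb_frames(pdb)
        assert len(back) == 2
        np.testing.assert_allclose(back[1] - back[0], 1.0)

    def test_nonfinite_coordinate_rejected(self):
        bad = WATER_PDB.replace("   0.957", "     nan")
        with pytest.raises(ValidationError, match="non-finite"):
            loads_pdb_frames(bad)


class TestEnergyTables:
    HEADER = "role,ligand_id,replica,frame,G_ele_MM,G_vdW_MM,G_int_MM,G_nonpol_sol,G_pol_sol"

    def test_single_row(self):
        df = read_energy_table(self.HEADER +
                               "\ncomplex,L1,1,1,-10.0,-5.0,100.0,2.0,-40.0\n")
        assert len(df) == 1
        assert df.loc[0, "G_pol_sol"] == -40.0

    def test_duplicate_key_rejected(self):
        text = (self.HEADER + "\ncomplex,L1,1,1,-10,-5,100,2,-40"
                + "\ncomplex,L1,1,1,-11,-5,100,2,-40\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_energy_table(text)

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="G_pol_sol"):
            read_energy_table(
                "role,ligand_id,replica,frame,G_ele_MM,G_vdW_MM,G_int_MM,G_nonpol_sol"
                "\ncomplex,L1,1,1,-10,-5,100,2\n")

    def test_non_numeric_cell_rejected(self):
        with pytest.raises(ValidationError, match="non-numeric"):
            read_energy_table(self.HEADER + "\ncomplex,L1,1,1,-10,oops,100,2,-40\n")

    def test_round_trip_full_precision(self, tmp_path):
        config = EnsembleGeneratorConfig(ligands={"L": -8.0},
                                         replicas=25, frames=40, seed=3)
        cpx, _, _, _ = gen_energy_ensembles(config)
        path = tmp_path / "e.csv"
        write_energy_table(cpx, path)
        back = read_energy_table(path)
        pd.testing.assert_frame_equal(cpx, back)

    def test_concatenation_of_disjoint_keys(self):
        r1 = records_to_table([ComponentEnergyRecord("complex", "A", 1, 1,
                                                     1, 2, 3, 4, 5)])
        r2 = records_to_table([ComponentEnergyRecord("complex", "A", 1, 2,
                                                     1, 2, 3, 4, 5)])
        assert len(concat_tables([r1, r2])) == 2
        with pytest.raises(ValidationError, match="duplicate"):
            concat_tables([r1, r1])


class TestExtractSubsystem:
    def _complex(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [5, 0, 0], [20, 0, 0], [20.9, 0, 0], [20.3, 0.9, 0]]
        roles = ["receptor", "receptor", "ligand", "water", "water", "water"]
        return make_system(coords, 0.0, roles=roles,
                           resnames=["PRT", "PRT", "LIG", "HOH", "HOH", "HOH"],
                           resnums=[1, 1, 2, 3, 3, 3],
                           bonds=[[1, 2], [2, 3]],
                           bond_params=[[100.0, 1.5], [100.0, 3.5]])

    def test_ligand_subset_keeps_complex_coordinates(self):
        system, frame = self._complex()
        sub, sub_frame = extract_subsystem(system, frame, {"ligand"})
        assert sub.n_atoms == 1
        np.testing.assert_array_equal(sub_frame.coords, [[5, 0, 0]])

    def test_receptor_plus_water_selection(self):
        system, frame = self._complex()
        sub, _ = extract_subsystem(system, frame, {"receptor", "water"})
        assert sub.n_atoms == 5
        assert set(sub.roles) == {"receptor", "water"}

    def test_cross_role_bonded_term_dropped_from_both_sides(self):
        system, frame = self._complex()
        rec, _ = extract_subsystem(system, frame, {"receptor"})
        lig, _ = extract_subsystem(system, frame, {"ligand"})
        assert len(rec.bonds) == 1  # the 1-2 receptor bond survives
        assert len(lig.bonds) == 0  # the receptor-ligand bond is in neither

    def test_partition_covers_every_atom_once(self):
        system, frame = self._complex()
        part1, _ = extract_subsystem(system, frame, {"receptor", "water"})
        part2, _ = extract_subsystem(system, frame, {"ligand"})
        ids = sorted(part1.ids.tolist() + part2.ids.tolist())
        assert ids == sorted(system.ids.tolist())

    def test_empty_selection_is_an_error(self):
        system, frame = self._complex()
        with pytest.raises(ValidationError, match="zero atoms"):
            extract_subsystem(system, frame, {"ion"})
        with pytest.raises(ValidationError, match="non-empty"):
            extract_subsystem(system, frame, set())


class TestExperimentalRecords:
    def test_requires_dg_or_pic50(self):
        with pytest.raises(ValidationError):
            ExperimentalRecord(ligand_id="X")
        assert ExperimentalRecord(ligand_id="X", pIC50=7.0).pIC50 == 7.0

    def test_round_trip(self, tmp_path):
        records = [
            ExperimentalRecord("1", "DIV", dG_expt=-9.8, dG_err=0.1),
            ExperimentalRecord("THQ9", "THQ", dG_expt=-5.9, pIC50=4.3, bound=True),
        ]
        path = tmp_path / "exp.csv"
        write_experimental_table(records, path)
        back = read_experimental_table(path)
        assert back[0].dG_expt == -9.8
        assert back[1].bound is True
        assert back[1].pIC50 == 4.3


class TestEnsembleSpec:
    def test_rejects_degenerate_layout(self):
        with pytest.raises(ValidationError):
            EnsembleSpec(replicas=0)
        assert EnsembleSpec().replicas == 25
        assert EnsembleSpec().frames == 40
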