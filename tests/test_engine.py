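"""Protocol combination, averaged-receptor constants and variational entropy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from esmacs.constants import DEFAULT_CONSTANTS
from esmacs.engine import (ProtocolSpec, aggregate_estimates,
                           averaged_receptor_constant,
                           interaction_energy_series, protocol_delta_g,
                           replica_means, total_with_entropy,
                           variational_entropy)
from esmacs.model import (EnsembleSpec, ValidationError, records_to_table,
                          ComponentEnergyRecord, table_total)


def tiny_table(role_totals, ligand="A"):
    """Build a table from {role: {replica: [frame totals]}} (total in G_ele)."""
    records = []
    for role, reps in role_totals.items():
        for rep, frames in reps.items():
            for fi, total in enumerate(frames, start=1):
                records.append(ComponentEnergyRecord(
                    role, ligand, rep, fi, total, 0.0, 0.0, 0.0, 0.0))
    return records_to_table(records)


class TestReplicaMeans:
    def test_mean_over_frames_within_replica(self):
        table = tiny_table({"complex": {1: [-10.0, -12.0]}})
        totals, comps = replica_means(table, "complex", "A")
        assert totals.loc[1] == pytest.approx(-11.0)
        assert comps.loc[1, "G_ele_MM"] == pytest.approx(-11.0)

    def test_identical_frames_have_zero_spread(self):
        table = tiny_table({"complex": {1: [-5.0, -5.0], 2: [-5.0, -5.0]}})
        totals, _ = replica_means(table, "complex", "A")
        assert totals.std() == 0.0

    def test_ragged_coverage_is_an_error(self):
        table = tiny_table({"complex": {1: [-5.0, -5.0], 2: [-5.0]}})
        with pytest.raises(ValidationError, match="coverage"):
            replica_means(table, "complex", "A", EnsembleSpec(replicas=2, frames=2))

    def test_missing_replica_is_an_error(self):
        table = tiny_table({"complex": {1: [-5.0, -5.0]}})
        with pytest.raises(ValidationError, match="coverage"):
            replica_means(table, "complex", "A", EnsembleSpec(replicas=2, frames=2))


class TestAveragedReceptorConstant:
    def _table(self):
        a = tiny_table({"receptor": {1: [-100.0]}}, ligand="A")
        b = tiny_table({"receptor": {1: [-102.0]}}, ligand="B")
        return pd.concat([a, b], ignore_index=True)

    def test_mean_over_comparable_ligands(self):
        assert averaged_receptor_constant(self._table(), ["A", "B"]) == -101.0

    def test_single_ligand_set(self):
        assert averaged_receptor_constant(self._table(), ["A"]) == -100.0

    def test_invariant_to_ligand_ordering(self):
        t = self._table()
        assert (averaged_receptor_constant(t, ["A", "B"])
                == averaged_receptor_constant(t, ["B", "A"]))

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValidationError, match="empty"):
            averaged_receptor_constant(self._table(), [])


class TestProtocolDeltaG:
    def test_perfect_cancellation_gives_zero(self):
        table = tiny_table({
            "complex": {1: [-90.0, -92.0]},
            "receptor": {1: [-60.0, -61.0]},
            "ligand": {1: [-30.0, -31.0]}})
        est = protocol_delta_g(ProtocolSpec("1traj"), table, "A")
        assert est.dG == pytest.approx(0.0, abs=1e-12)

    def test_three_trajectory_arithmetic(self):
        cpx = tiny_table({"complex": {1: [-99.0]},
                          "receptor": {1: [0.0]}, "ligand": {1: [0.0]}})
        rec = tiny_table({"receptor": {1: [-60.0]}})
        lig = tiny_table({"ligand": {1: [-31.0]}})
        est = protocol_delta_g(ProtocolSpec("3traj"), cpx, "A",
                               receptor_records=rec, ligand_records=lig)
        assert est.dG == pytest.approx(-8.0)

    def test_one_traj_matches_per_frame_oracle(self, noisy_ensembles):
        _, cpx, _, _, _ = noisy_ensembles
        lig = sorted(cpx["ligand_id"].unique())[0]
        est = protocol_delta_g(ProtocolSpec("1traj"), cpx, lig)
        # brute force: average of per-frame (complex - receptor - ligand)
        sub = cpx[cpx["ligand_id"] == lig].copy()
        sub["total"] = table_total(sub)
        wide = sub.pivot_table(index=["replica", "frame"], columns="role",
                               values="total")
        per_frame = wide["complex"] - wide["receptor"] - wide["ligand"]
        oracle = per_frame.groupby(level="replica").mean().mean()
        assert est.dG == pytest.approx(oracle, abs=1e-9)

    def test_internal_energy_cancels_exactly_in_one_traj(self, noisy_ensembles):
        _, cpx, _, _, _ = noisy_ensembles
        for lig in sorted(cpx["ligand_id"].unique())[:3]:
            est = protocol_delta_g(ProtocolSpec("1traj"), cpx, lig)
            assert est.components["G_int_MM"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_independent_ensemble_is_named(self):
        table = tiny_table({"complex": {1: [-90.0]},
                            "receptor": {1: [-60.0]}, "ligand": {1: [-30.0]}})
        with pytest.raises(ValidationError, match="independent ligand"):
            protocol_delta_g(ProtocolSpec("2traj-fl"), table, "A")

    def test_uniform_complex_shift_shifts_delta_g(self, noise_free_ensembles):
        _, cpx, rec, lig, _ = noise_free_ensembles
        base = protocol_delta_g(ProtocolSpec("1traj"), cpx, "A")
        shifted = cpx.copy()
        mask = shifted["role"] == "complex"
        shifted.loc[mask, "G_ele_MM"] += 3.5
        moved = protocol_delta_g(ProtocolSpec("1traj"), shifted, "A")
        assert moved.dG - base.dG == pytest.approx(3.5, abs=1e-10)

    def test_ar_protocol_requires_comparable_set(self):
        with pytest.raises(ValidationError, match="comparable"):
            ProtocolSpec("2traj-ar")


class TestVariationalEntropy:
    def test_constant_series_has_zero_penalty(self):
        assert variational_entropy([-12.3] * 50) == 0.0

    def test_two_point_closed_form(self):
        # ±1 kcal/mol about the mean: k_B·T·ln(cosh(β)) at 300 K
        kT = DEFAULT_CONSTANTS.kT
        expected = kT * np.log(np.cosh(1.0 / kT))
        got = variational_entropy([-10.0, -12.0])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.607, abs=5e-4)

    def test_gaussian_limit(self):
        rng = np.random.default_rng(12)
        sigma = 1.0
        samples = rng.normal(-20.0, sigma, size=1_000_000)
        got = variational_entropy(samples)
        kT = DEFAULT_CONSTANTS.kT
        expected = sigma ** 2 / (2 * kT)
        assert expected == pytest.approx(0.8387, abs=5e-4)
        # sampling error of the exponential average at n=1e6
        assert got == pytest.approx(expected, abs=0.02)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=40))
    def test_penalty_is_nonnegative(self, values):
        assert variational_entropy(values) >= -1e-12

    def test_overflow_guarded(self):
        # fluctuations of hundreds of kT must not overflow
        assert np.isfinite(variational_entropy([0.0, 500.0, -500.0]))

    def test_pooled_vs_per_replica_modes(self, noisy_ensembles):
        _, cpx, _, _, _ = noisy_ensembles
        lig = sorted(cpx["ligand_id"].unique())[0]
        series = interaction_energy_series(cpx, lig)
        pooled = variational_entropy(series)
        per_rep = variational_entropy(series, per_replica=True)
        assert pooled >= 0 and per_rep >= 0
        # modes agree in order of magnitude but are not the same estimator
        assert pooled == pytest.approx(per_rep, abs=1.0)

    def test_total_with_entropy_addition(self):
        from esmacs.engine import BindingEstimate
        est = BindingEstimate("A", "1traj", dG=-8.0)
        est = total_with_entropy(est, 0.6)
        assert est.total == pytest.approx(-7.4)
        est0 = total_with_entropy(BindingEstimate("A", "1traj", dG=-8.0), 0.0)
        assert est0.total == est0.dG


class TestInteractionSeries:
    def test_recovers_generator_interaction_stats(self, noisy_ensembles):
        config, cpx, _, _, manifest = noisy_ensembles
        lig = sorted(config.ligands)[0]
        series = interaction_energy_series(cpx, lig)
        assert len(series) == config.replicas * config.frames
        # mean E_inter equals the 1traj expectation; SD the configured one
        assert series["E_inter"].mean() == pytest.approx(
            manifest["ligands"][lig]["expected"]["1traj"], abs=0.2)
        assert series["E_inter"].std() == pytest.approx(
            config.interaction_sd, rel=0.15)


class TestAggregateEstimates:
    def test_noise_free_estimates_with_entropy(self, noise_free_ensembles):
        _, cpx, rec, lig, manifest = noise_free_ensembles
        from esmacs.stats import BootstrapSpec
        ests = aggregate_estimates(
            ProtocolSpec("1traj", entropy="variational"), cpx,
            bootstrap=BootstrapSpec(resamples=200, seed=1))
        for est in ests:
            expected = manifest["ligands"][est.ligand_id]["expected"]["1traj"]
            assert est.dG == pytest.approx(expected, abs=1e-9)
            assert est.minus_T_dS == pytest.approx(0.0, abs=1e-9)
            assert est.se == pytest.approx(0.0, abs=1e-9)
            assert est.ci[0] == pytest.approx(est.ci[1], abs=1e-9)
            assert est.ci[0] == pytest.approx(est.dG, abs=1e-9)
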