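"""Dataset screening and the two-step parameter-fitting protocol."""

import numpy as np
import pytest

import trapdensity as td
from tests.conftest import ladder, make_noiseless_dataset


def dataset_from_counts(distances, released, caught, **meta):
    return td.ReleaseRecaptureDataset(
        tuple(
            td.DistanceCatchRecord(float(d), int(n), int(c))
            for d, n, c in zip(distances, released, caught)
        ),
        **meta,
    )


class TestRecords:
    def test_caught_cannot_exceed_released(self):
        with pytest.raises(ValueError, match="exceeds"):
            td.DistanceCatchRecord(10.0, 5, 6)

    def test_proportion_filled_from_counts(self):
        rec = td.DistanceCatchRecord(10.0, 200, 30)
        assert rec.proportion == pytest.approx(0.15)

    def test_inconsistent_proportion_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            td.DistanceCatchRecord(10.0, 200, 30, proportion=0.2)

    def test_records_sorted_by_distance(self):
        ds = dataset_from_counts([50, 0, 25], [10, 10, 10], [1, 5, 3])
        assert ds.distances.tolist() == [0, 25, 50]


class TestValidateDataset:
    def test_well_designed_ladder_passes(self):
        ds = dataset_from_counts(
            [0, 15, 25, 30, 45], [50, 50, 50, 100, 100], [20, 15, 10, 12, 8]
        )
        assert td.validate_dataset(ds) == []

    def test_too_few_distances_flagged(self):
        ds = dataset_from_counts([0, 10, 20], [50, 50, 50], [20, 10, 5])
        warnings_ = td.validate_dataset(ds)
        assert len(warnings_) == 1 and "criterion 1" in warnings_[0]

    def test_interior_zero_catch_flagged(self):
        ds = dataset_from_counts([0, 10, 20, 30], [50] * 4, [5, 0, 3, 1])
        assert any("criterion 3" in w for w in td.validate_dataset(ds))

    def test_trailing_zeros_are_not_interior(self):
        ds = dataset_from_counts([0, 10, 20, 30], [50] * 4, [5, 3, 0, 0])
        assert not any("criterion 3" in w for w in td.validate_dataset(ds))

    def test_shrinking_cohorts_flagged(self):
        ds = dataset_from_counts([0, 10, 20, 30], [100, 80, 60, 40], [5, 3, 2, 1])
        assert any("criterion 2" in w for w in td.validate_dataset(ds))

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            td.validate_dataset(td.ReleaseRecaptureDataset(()))


class TestNoiselessRecovery:
    TRUTH = td.TrapSystemParams(0.4, 30.0, 1600.0)
    DISTANCES = (0, 10, 20, 30, 45, 60, 100, 200)

    def test_step1_recovers_both_parameters(self):
        ds = make_noiseless_dataset(self.TRUTH, self.DISTANCES)
        s0, d50 = td.fit_step1_untransformed(ds)
        assert s0 == pytest.approx(0.4, rel=1e-4)
        assert d50 == pytest.approx(30.0, rel=1e-4)

    def test_step2_recovers_d50(self):
        truth = td.TrapSystemParams(0.37, 27.3, 1600.0)
        ds = make_noiseless_dataset(truth, self.DISTANCES)
        d50, _ = td.fit_step2_log(ds, 0.37)
        assert d50 == pytest.approx(27.3, rel=1e-4)

    def test_two_step_composition_is_exact(self):
        ds = make_noiseless_dataset(self.TRUTH, self.DISTANCES)
        result = td.fit_two_step(ds, rmax=1600.0)
        assert result.method == "two_step"
        assert result.params.sptfer0 == pytest.approx(0.4, rel=1e-4)
        assert result.params.d50 == pytest.approx(30.0, rel=1e-4)
        assert result.params.rmax == 1600.0
        assert result.r_correlation == pytest.approx(1.0, abs=1e-6)

    def test_any_two_point_subset_identifies_step2(self):
        # the one-parameter log fit is exactly identified by any >=2 points
        for pair in [(0, 3), (2, 6), (5, 7)]:
            ds = make_noiseless_dataset(
                self.TRUTH, [self.DISTANCES[i] for i in pair]
            )
            d50, _ = td.fit_step2_log(ds, 0.4)
            assert d50 == pytest.approx(30.0, rel=1e-4)

    def test_distance_unit_rescaling_rescales_d50(self):
        ds_m = make_noiseless_dataset(self.TRUTH, self.DISTANCES)
        km_records = tuple(
            td.DistanceCatchRecord(
                rec.distance / 1000.0, rec.n_released, rec.n_caught
            )
            for rec in ds_m.records
        )
        d50_m, _ = td.fit_step2_log(ds_m, 0.4)
        d50_km, _ = td.fit_step2_log(td.ReleaseRecaptureDataset(km_records), 0.4)
        assert d50_km * 1000.0 == pytest.approx(d50_m, rel=1e-6)

    def test_flat_near_origin_proportions_pin_sptfer0(self):
        truth = td.TrapSystemParams(0.25, 5000.0, None)
        ds = make_noiseless_dataset(truth, [0, 1, 2, 3, 4, 5])
        s0, _ = td.fit_step1_untransformed(ds)
        assert s0 == pytest.approx(0.25, rel=1e-3)


class TestFitEdgeCases:
    def test_all_zero_catches_cannot_be_fit(self):
        ds = dataset_from_counts([0, 10, 20, 30], [50] * 4, [0, 0, 0, 0])
        with pytest.raises(td.FitError):
            td.fit_step1_untransformed(ds)

    def test_single_positive_record_cannot_anchor_log_fit(self):
        ds = dataset_from_counts([0, 10, 20, 30], [50] * 4, [5, 0, 0, 0])
        with pytest.raises(td.FitError):
            td.fit_step2_log(ds, 0.1)

    def test_sptfer0_outside_unit_interval_rejected(self):
        ds = dataset_from_counts([0, 10, 20, 30], [50] * 4, [20, 10, 5, 2])
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                td.fit_with_known_sptfer0(ds, bad)

    def test_sptfer0_above_every_observation_still_converges(self):
        ds = dataset_from_counts([0, 10, 20, 30], [100] * 4, [20, 10, 5, 2])
        d50, _ = td.fit_step2_log(ds, 0.9)
        assert d50 > 0

    def test_interior_zero_produces_result_with_exclusions(self):
        truth = td.TrapSystemParams(0.4, 25.0, 1600.0)
        base = make_noiseless_dataset(truth, [0, 10, 20, 40, 80], n_released=100)
        records = list(base.records)
        records[3] = td.DistanceCatchRecord(40.0, 100, 0)  # knocked-out point
        ds = td.ReleaseRecaptureDataset(tuple(records))
        result = td.fit_two_step(ds)
        assert result.excluded_points and result.excluded_points[0][0] == 40.0
        assert result.n_points_used + len(result.excluded_points) == len(ds)
        assert any("criterion 3" in w for w in result.warnings)

    def test_duplicate_distances_pooled_with_warning(self):
        ds = dataset_from_counts(
            [0, 0, 10, 20, 30], [50, 150, 100, 100, 100], [25, 75, 25, 10, 5]
        )
        with pytest.warns(UserWarning, match="duplicate"):
            s0, _ = td.fit_step1_untransformed(ds)
        assert s0 == pytest.approx(0.5, rel=0.05)  # pooled 100/200 at the origin

    def test_weighted_fit_without_sems_falls_back(self):
        ds = dataset_from_counts([0, 10, 20, 30], [100] * 4, [40, 20, 10, 4])
        with pytest.warns(UserWarning, match="falling back"):
            s0, _ = td.fit_step1_untransformed(ds, weighted=True)
        assert 0 < s0 <= 1


class TestSeededRecovery:
    def test_two_step_recovers_d50_from_binomial_noise(self):
        truth = td.TrapSystemParams(0.09, 250.0, 1040.0)
        design = td.SimulationDesign(
            truth, ladder(250.0, 1040.0), 10_000, seed=7, replicates=5
        )
        for sim in td.simulate_release_recapture(design):
            result = td.fit_two_step(sim, rmax=1040.0)
            assert result.params.d50 == pytest.approx(
                250.0, abs=3 * result.params.d50_sem
            )

    def test_known_sptfer0_recovery_within_sem(self):
        truth = td.TrapSystemParams(0.37, 27.3, 1600.0)
        design = td.SimulationDesign(
            truth, ladder(27.3, 1600.0), 10_000, seed=11, replicates=5
        )
        for sim in td.simulate_release_recapture(design):
            result = td.fit_with_known_sptfer0(sim, 0.37, rmax=1600.0)
            assert result.method == "fixed_sptfer0"
            assert result.params.d50 == pytest.approx(
                27.3, abs=3 * result.params.d50_sem
            )

    def test_fit_result_serializes_to_json_dict(self):
        truth = td.TrapSystemParams(0.3, 40.0, 800.0)
        design = td.SimulationDesign(truth, ladder(40.0, 800.0), 5_000, seed=3)
        result = td.fit_two_step(td.simulate_release_recapture(design)[0], rmax=800.0)
        payload = result.to_dict()
        assert payload["method"] == "two_step"
        assert len(payload["residuals"]) == payload["n_points_used"]
        assert -1.0 <= payload["r_correlation"] <= 1.0
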