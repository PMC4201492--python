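"""Cohort simulation: allocation, determinism, statistics, calibration, sweeps."""

import math

import numpy as np
import pandas as pd
import pytest

import moodcourse as mc
from moodcourse.cohort import allocate_subpopulations


def single_cohort(params, n, seed, days):
    return mc.CohortConfig(
        subpopulations=(mc.SubpopulationSpec("only", 1.0, params),),
        n_individuals=n,
        master_seed=seed,
        duration_days=days,
    )


class TestAllocation:
    def test_proportional_allocation_is_deterministic(self):
        idx = allocate_subpopulations([0.93, 0.07], 100)
        assert (idx == 0).sum() == 93 and (idx == 1).sum() == 7
        assert np.array_equal(idx, allocate_subpopulations([0.93, 0.07], 100))

    def test_largest_remainder_rounding(self):
        idx = allocate_subpopulations([0.5, 0.5], 3)
        assert sorted(np.bincount(idx, minlength=2)) == [1, 2]

    def test_weights_must_sum_to_one(self, low_risk):
        with pytest.raises(mc.ConfigurationError, match="sum to 1"):
            mc.CohortConfig(
                subpopulations=(mc.SubpopulationSpec("x", 0.5, low_risk),),
                n_individuals=10,
                master_seed=0,
            )


class TestSimulateCohort:
    def test_no_noise_means_no_episodes(self, low_risk):
        records = mc.simulate_cohort(
            single_cohort(low_risk.replace(sigma=0.0), 20, 0, 365)
        )
        assert (records["nde"] == 0).all()
        assert records["first_onset_day"].isna().all()

    def test_same_master_seed_reproduces_records(self, high_risk):
        a = mc.simulate_cohort(single_cohort(high_risk, 25, 7, 10 * 365))
        b = mc.simulate_cohort(single_cohort(high_risk, 25, 7, 10 * 365))
        pd.testing.assert_frame_equal(a, b)
        c = mc.simulate_cohort(single_cohort(high_risk, 25, 8, 10 * 365))
        assert not a["first_onset_day"].equals(c["first_onset_day"])

    def test_mixture_records_tag_subpopulations(self, low_risk, high_risk):
        cfg = mc.CohortConfig(
            subpopulations=(
                mc.SubpopulationSpec("low_risk", 0.8, low_risk),
                mc.SubpopulationSpec("high_risk", 0.2, high_risk),
            ),
            n_individuals=10,
            master_seed=1,
            duration_days=365,
        )
        records = mc.simulate_cohort(cfg)
        assert (records["subpopulation"] == "low_risk").sum() == 8
        assert (records["subpopulation"] == "high_risk").sum() == 2


class TestMedianAgeOfOnset:
    def test_median_of_known_onsets(self):
        records = pd.DataFrame({"first_onset_day": [365.0, 3650.0, 7300.0]})
        assert mc.median_age_of_onset(records) == pytest.approx(10.0)

    def test_single_onset_at_day_zero(self):
        records = pd.DataFrame({"first_onset_day": [0.0]})
        assert mc.median_age_of_onset(records) == 0.0

    def test_no_affected_individuals_is_an_error(self):
        with pytest.raises(ValueError, match="no affected"):
            mc.median_age_of_onset(pd.DataFrame({"first_onset_day": [math.nan]}))


class TestCalibrateNoise:
    def test_occurrence_increases_with_noise(self, low_risk):
        ors = []
        for sigma in (9.0, 10.5, 12.0):
            records = mc.simulate_cohort(
                single_cohort(low_risk.replace(sigma=sigma), 80, 11, 70 * 365)
            )
            ors.append((records["nde"] >= 1).mean())
        assert ors[0] < ors[1] < ors[2]

    def test_unreachable_target_rejected(self, low_risk):
        with pytest.raises(mc.ConfigurationError):
            mc.calibrate_noise(low_risk, 0.0, n=10, seed=0)

    def test_unbracketed_target_reports_range(self, low_risk):
        with pytest.raises(mc.ConfigurationError, match="not bracketed"):
            mc.calibrate_noise(
                low_risk, 0.9, duration_days=5 * 365, n=20, seed=0,
                bracket=(1.0, 2.0),
            )

    def test_finds_sigma_for_reachable_target(self, high_risk):
        # short-horizon, small-n calibration on the steep high-risk curve
        sigma = mc.calibrate_noise(
            high_risk, 0.5, duration_days=10 * 365, n=60, seed=5,
            bracket=(6.0, 14.0), tol=0.08,
        )
        records = mc.simulate_cohort(
            single_cohort(high_risk.replace(sigma=sigma), 60, 5, 10 * 365)
        )
        assert abs((records["nde"] >= 1).mean() - 0.5) <= 0.2


class TestParameterSweep:
    def test_single_cell_equals_direct_simulation(self, low_risk):
        table = mc.parameter_sweep(
            low_risk, "a", [low_risk.a], "b", [low_risk.b],
            n=30, duration_days=5 * 365, master_seed=3,
        )
        cell_seed = np.random.SeedSequence(3).spawn(1)[0]
        records = mc.simulate_cohort(single_cohort(low_risk, 30, cell_seed, 5 * 365))
        assert table.loc[0, "or"] == (records["nde"] >= 1).mean()
        assert table.loc[0, "error"] == ""

    def test_invalid_cells_recorded_not_fatal(self, low_risk):
        table = mc.parameter_sweep(
            low_risk, "b", [low_risk.b, 1.0], "a", [low_risk.a],
            n=5, duration_days=365, master_seed=0,
        )
        good = table[table["error"] == ""]
        bad = table[table["error"] != ""]
        assert len(good) == 1 and len(bad) == 1
        assert math.isnan(bad["or"].iloc[0])

    def test_sweep_reproducible_under_master_seed(self, low_risk):
        kwargs = dict(n=10, duration_days=2 * 365, master_seed=9)
        a = mc.parameter_sweep(low_risk, "a", [4.8, 5.0], "b", [-2.9], **kwargs)
        b = mc.parameter_sweep(low_risk, "a", [4.8, 5.0], "b", [-2.9], **kwargs)
        pd.testing.assert_frame_equal(a, b)
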