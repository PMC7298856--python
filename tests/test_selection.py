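import numpy as np
import pandas as pd
import pytest

from vectorenm.selection import (
    EvalParams,
    aicc,
    calibrate_candidates,
    omission_rate,
    partial_roc,
    select_best,
)
from vectorenm.occurrences import split_calibration


class TestOmission:
    def test_eleven_of_145_is_7_5_percent(self):
        """145 evaluation points with 11 below threshold: the omission rate
        prints as 7.5% at one decimal (truncated)."""
        vals = np.concatenate([np.full(11, 0.1), np.full(134, 0.9)])
        rate = omission_rate(vals, 0.5)
        assert rate == pytest.approx(11 / 145)
        assert np.floor(rate * 1000) / 10 == 7.5

    def test_threshold_below_min_gives_zero(self):
        assert omission_rate(np.array([0.2, 0.4]), 0.1) == 0.0

    def test_threshold_above_max_gives_one(self):
        assert omission_rate(np.array([0.2, 0.4]), 0.9) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            omission_rate(np.array([]), 0.5)


class TestPartialRoc:
    def test_constant_prediction_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            ratio, p = partial_roc(np.ones(500), np.ones(50))
        assert (ratio, p) == (1.0, 1.0)

    def test_informative_prediction_is_significant(self, truth60, stack60):
        suit = truth60.suitability[stack60.mask]
        rng = np.random.default_rng(0)
        pts = suit[rng.choice(len(suit), size=100, p=suit / suit.sum())]
        ratio, p = partial_roc(suit, pts, iterations=500, seed=1)
        assert ratio > 1.0
        assert p < 0.05

    def test_needs_ten_points(self):
        with pytest.raises(ValueError):
            partial_roc(np.random.default_rng(0).random(100), np.ones(5))


class TestAicc:
    def test_worked_example(self):
        # 2k - 2 lnL + 2k(k+1)/(n-k-1) = 4 + 100 + 12/97
        val, flag = aicc(lnL=-50.0, k=2, n=100)
        assert val == pytest.approx(104.12371134, abs=1e-6)
        assert not flag

    def test_overparameterized_flagged(self):
        val, flag = aicc(lnL=-10.0, k=99, n=100)
        assert np.isinf(val) and flag

    def test_matches_independent_formula_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(0, 50))
            n = int(rng.integers(k + 2, 500))
            lnL = float(rng.normal(-100, 50))
            got, flag = aicc(lnL, k, n)
            # independent evaluation of the definition
            expect = 2 * k - 2 * lnL + (2 * k * (k + 1)) / (n - k - 1)
            assert not flag
            assert got == pytest.approx(expect, abs=1e-9)


def _table(rows):
    df = pd.DataFrame(
        rows,
        columns=["id", "variables", "classes", "rm", "auc_ratio", "p_value",
                 "omission", "aicc", "k"],
    )
    df["error"] = ""
    return df


class TestSelectBest:
    def test_unique_survivor_selected(self):
        t = _table([
            ("A", "x,y", "lq", 1.0, 1.1, 0.20, 0.01, 90.0, 3),
            ("B", "x,y", "lq", 0.5, 1.3, 0.01, 0.30, 80.0, 4),
            ("C", "x,y,z", "lq", 1.0, 1.4, 0.01, 0.02, 100.0, 5),
        ])
        rep = select_best(t, alpha=0.05, E=0.05)
        assert rep.selected_id == "C"
        assert rep.significant == 2

    def test_delta_aicc_reported(self):
        t = _table([
            ("A", "x,y", "lq", 1.0, 1.4, 0.0, 0.0, 100.0, 3),
            ("B", "x,y", "lq", 2.0, 1.4, 0.0, 0.0, 126.5, 3),
        ])
        rep = select_best(t)
        assert rep.selected_id == "A"
        assert rep.delta_aicc_runner_up == pytest.approx(26.5)

    def test_all_insignificant_raises(self):
        t = _table([("A", "x,y", "lq", 1.0, 1.0, 0.50, 0.0, 10.0, 1)])
        with pytest.raises(ValueError, match="significant"):
            select_best(t)

    def test_relaxed_fallback_when_omission_fails(self):
        t = _table([
            ("A", "x,y", "lq", 1.0, 1.3, 0.01, 0.40, 90.0, 3),
            ("B", "x,y", "lq", 2.0, 1.3, 0.01, 0.20, 95.0, 3),
        ])
        with pytest.warns(UserWarning, match="relaxed|minimum-omission"):
            rep = select_best(t, E=0.05)
        assert rep.relaxed
        assert rep.selected_id == "B"

    def test_aicc_tie_broken_by_k(self):
        t = _table([
            ("A", "x,y,z", "lq", 1.0, 1.3, 0.0, 0.0, 90.0, 5),
            ("B", "x,y", "lq", 1.0, 1.3, 0.0, 0.0, 90.0, 3),
        ])
        assert select_best(t).selected_id == "B"

    def test_counts_monotone(self):
        t = _table([
            ("A", "x,y", "lq", 1.0, 1.1, 0.20, 0.01, 90.0, 3),
            ("B", "x,y", "lq", 0.5, 1.3, 0.01, 0.01, 80.0, 4),
            ("C", "x,y", "lq", 2.0, 1.2, 0.01, 0.50, 85.0, 4),
        ])
        rep = select_best(t)
        assert rep.performant <= rep.significant <= rep.total


@pytest.fixture(scope="module")
def small_run(stack60, occ300):
    cal, ev = split_calibration(occ300, 0.5, seed=0)
    params = EvalParams(proc_iterations=100)
    kwargs = dict(
        variable_sets=[["bio1", "bio4"], ["bio12", "bio14"]],
        class_subsets=["l", "lq"],
        rms=[1.0, 5.0],
        params=params,
        seed=3,
    )
    df = calibrate_candidates(
        stack60,
        cal[["longitude", "latitude"]].to_numpy(),
        ev[["longitude", "latitude"]].to_numpy(),
        **kwargs,
    )
    return df, kwargs, (stack60, cal, ev)


class TestCalibrateCandidates:
    def test_grid_product_row_count(self, small_run):
        df, _, _ = small_run
        assert len(df) == 2 * 2 * 2
        assert (df["error"] == "").all()

    def test_deterministic_under_seed(self, small_run):
        df, kwargs, (stack, cal, ev) = small_run
        df2 = calibrate_candidates(
            stack,
            cal[["longitude", "latitude"]].to_numpy(),
            ev[["longitude", "latitude"]].to_numpy(),
            **kwargs,
        )
        pd.testing.assert_frame_equal(df, df2)

    def test_records_have_valid_ranges(self, small_run):
        df, _, _ = small_run
        assert df["omission"].between(0, 1).all()
        assert df["p_value"].between(0, 1).all()
        assert (df["k"] >= 0).all()

    def test_empty_grid_rejected(self, stack60, occ300):
        with pytest.raises(ValueError):
            calibrate_candidates(
                stack60, occ300[["longitude", "latitude"]].to_numpy(),
                occ300[["longitude", "latitude"]].to_numpy(),
                [], ["lq"], [1.0],
            )
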