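import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vectorenm.grids import Grid, GridMismatchError, LayerStack
from vectorenm.transfer import (
    agreement,
    binarize,
    bootstrap_median_model,
    classify_change,
    e_threshold,
    mop,
)


class TestBinarize:
    def test_worked_example_twenty_values(self):
        vals = np.arange(0.05, 1.01, 0.05)  # 0.05, 0.10, ..., 1.00
        thr = e_threshold(vals, 0.05)
        assert thr == pytest.approx(0.10)
        assert (vals < thr).mean() == pytest.approx(0.05)

    def test_zero_E_uses_minimum(self):
        vals = np.array([0.3, 0.7, 0.2])
        binary, thr = binarize(np.array([[0.1, 0.25]]), vals, E=0.0)
        assert thr == pytest.approx(0.2)
        np.testing.assert_array_equal(binary, [[False, True]])

    @settings(derandomize=True, max_examples=50)
    @given(
        n=st.integers(5, 200),
        E=st.sampled_from([0.01, 0.05, 0.1]),
        seed=st.integers(0, 10_000),
    )
    def test_threshold_is_maximal_with_omission_at_most_E(self, n, E, seed):
        vals = np.random.default_rng(seed).random(n)
        thr = e_threshold(vals, E)
        assert (vals < thr).mean() <= E
        # no larger observed value keeps omission <= E
        for v in vals[vals > thr]:
            if (vals < v).mean() <= E:
                pytest.fail("threshold not maximal")

    def test_nan_cells_are_unsuitable(self):
        binary, _ = binarize(np.array([[np.nan, 0.9]]), np.array([0.5]), 0.05)
        np.testing.assert_array_equal(binary, [[False, True]])


class TestMop:
    def _stack(self, arrs, grid=None):
        first = np.asarray(next(iter(arrs.values())))
        grid = grid or Grid(first.shape[0], first.shape[1], 1.0)
        return LayerStack(grid, {k: np.asarray(v, float) for k, v in arrs.items()})

    def test_exact_match_has_similarity_one(self):
        r = np.random.default_rng(0)
        calib = self._stack({"a": r.random((5, 5)), "b": r.random((5, 5))})
        proj = self._stack({
            "a": np.full((5, 5), calib["a"][2, 2]),
            "b": np.full((5, 5), calib["b"][2, 2]),
        })
        proj.layers["a"][0, 0] = calib["a"].max() + 5  # one distant cell
        surf = mop(calib, proj, reference_fraction=0.04)
        assert surf.similarity[2, 2] == pytest.approx(1.0)
        assert surf.distance[2, 2] == pytest.approx(0.0, abs=1e-12)

    def test_strict_extrapolation_flag(self):
        r = np.random.default_rng(1)
        calib = self._stack({"a": r.random((4, 4)), "b": r.random((4, 4))})
        pa = calib["a"].copy()
        pa[1, 1] = calib["a"].max() + 1.0  # outside the calibration range
        proj = self._stack({"a": pa, "b": calib["b"].copy()})
        surf = mop(calib, proj)
        assert surf.strict_extrapolation[1, 1]
        assert not surf.strict_extrapolation[0, 0]

    def test_matches_brute_force_all_pairs(self):
        r = np.random.default_rng(2)
        calib = self._stack({"a": r.random((10, 10)), "b": r.random((10, 10))})
        proj = self._stack({"a": r.random((10, 10)) * 1.5, "b": r.random((10, 10))})
        frac = 0.1
        surf = mop(calib, proj, reference_fraction=frac, sample_cap=10_000)
        # independent all-pairs oracle with explicit loops
        C = np.column_stack([calib["a"].ravel(), calib["b"].ravel()])
        lo, hi = C.min(axis=0), C.max(axis=0)
        Cn = (C - lo) / (hi - lo)
        k = int(np.ceil(frac * len(Cn)))
        dist = np.empty(100)
        for idx in range(100):
            p = np.array([proj["a"].ravel()[idx], proj["b"].ravel()[idx]])
            pn = (p - lo) / (hi - lo)
            d = np.sqrt(((Cn - pn) ** 2).sum(axis=1))
            dist[idx] = np.sort(d)[:k].mean()
        expect = 1.0 - dist / dist.max()
        np.testing.assert_allclose(surf.similarity.ravel(), expect, atol=1e-9)

    def test_invariant_under_affine_rescaling_of_one_variable(self):
        r = np.random.default_rng(3)
        a, b = r.random((6, 6)), r.random((6, 6))
        pa, pb = r.random((6, 6)), r.random((6, 6))
        s1 = mop(self._stack({"a": a, "b": b}), self._stack({"a": pa, "b": pb}))
        s2 = mop(
            self._stack({"a": a * 40 - 7, "b": b}),
            self._stack({"a": pa * 40 - 7, "b": pb}),
        )
        np.testing.assert_allclose(s1.similarity, s2.similarity, atol=1e-9)

    def test_variable_mismatch_rejected(self):
        r = np.random.default_rng(4)
        with pytest.raises(GridMismatchError):
            mop(self._stack({"a": r.random((3, 3))}), self._stack({"b": r.random((3, 3))}))


class TestAgreement:
    def test_cutoff_of_20_gcms_at_60_percent_is_12(self):
        binaries = [np.zeros((2, 2), bool) for _ in range(20)]
        agr = agreement(binaries, cutoff_frac=0.6)
        assert agr.cutoff == 12
        assert agr.n_models == 20

    def test_counts_equal_direct_vote_sum(self, rng):
        binaries = [rng.random((8, 8)) > 0.5 for _ in range(7)]
        agr = agreement(binaries)
        expect = np.zeros((8, 8), int)
        for b in binaries:
            expect += b.astype(int)
        np.testing.assert_array_equal(agr.counts, expect)

    def test_all_suitable_cell(self):
        binaries = [np.ones((1, 1), bool)] * 20
        assert agreement(binaries).counts[0, 0] == 20

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            agreement([np.ones((2, 2), bool), np.ones((3, 2), bool)])


class TestClassifyChange:
    def _agr(self, counts, G=20, frac=0.6):
        from vectorenm.transfer import AgreementMap

        return AgreementMap(np.asarray(counts), G, int(np.ceil(frac * G)))

    def test_gain_strong(self):
        out = classify_change(np.array([[False]]), self._agr([[15]]))
        assert out[0, 0] == 4

    def test_stable_suitable(self):
        out = classify_change(np.array([[True]]), self._agr([[20]]))
        assert out[0, 0] == 2

    def test_unsuitable(self):
        out = classify_change(np.array([[False]]), self._agr([[0]]))
        assert out[0, 0] == 0

    def test_classes_partition_grid(self, rng):
        present = rng.random((20, 20)) > 0.5
        counts = rng.integers(0, 21, size=(20, 20))
        out = classify_change(present, self._agr(counts))
        total = sum((out == c).sum() for c in range(5))
        assert total == out.size


@pytest.fixture(scope="module")
def boot_inputs(stack60, occ300):
    sub = stack60.subset(["bio1", "bio4", "bio6"])
    xy = occ300[["longitude", "latitude"]].to_numpy()[:60]
    return sub, xy


class TestBootstrapMedian:
    def test_single_replicate_equals_plain_fit(self, boot_inputs):
        sub, xy = boot_inputs
        out = bootstrap_median_model(
            sub, xy, {"present": sub}, n_boot=1, seed=0, resample=False
        )
        from vectorenm.maxent import MaxentNiche

        res = MaxentNiche.from_stack(sub, xy, classes="lq", seed=0).fit(rm=1.0)
        np.testing.assert_allclose(
            out["present"], res.predict(sub, scale="cloglog"), atol=1e-9
        )

    def test_identical_replicates_median_equals_any(self, boot_inputs):
        sub, xy = boot_inputs
        out = bootstrap_median_model(
            sub, xy, {"p": sub}, n_boot=4, seed=0, resample=False
        )
        single = bootstrap_median_model(
            sub, xy, {"p": sub}, n_boot=1, seed=0, resample=False
        )
        np.testing.assert_allclose(out["p"], single["p"], atol=1e-9)

    def test_seed_reproducible(self, boot_inputs):
        sub, xy = boot_inputs
        a = bootstrap_median_model(sub, xy, {"p": sub}, n_boot=5, seed=3)
        b = bootstrap_median_model(sub, xy, {"p": sub}, n_boot=5, seed=3)
        np.testing.assert_array_equal(a["p"], b["p"])
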