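"""Stability selection mechanics: strata, resampling, frequencies, thresholds."""

import warnings

import numpy as np
import pytest

from sbspca.preprocessing import autoscale
from sbspca.stability import (
    BootstrapPlan,
    StabilityResult,
    build_strata,
    choose_consensus_penalties,
    final_model,
    permutation_pvalues,
    run_sbs_grid,
    select_robust_markers,
    stratified_resample,
    _greedy_match,
)


class TestStrata:
    def test_default_52_by_5(self):
        strata = build_strata(52, 5)
        sizes = [len(s) for s in strata]
        assert sizes == [5] * 10 + [2]
        assert np.concatenate(strata).tolist() == list(range(52))

    def test_exact_division(self):
        assert [len(s) for s in build_strata(10, 5)] == [5, 5]

    def test_remainder_one_merged(self):
        assert [len(s) for s in build_strata(11, 5)] == [5, 6]

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="smaller than"):
            build_strata(4, 5)


class TestResampling:
    def test_single_stratum_is_plain_bootstrap(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        out = stratified_resample(X, [np.arange(10)], seed=3)
        assert out.shape == X.shape
        assert set(out[:, 0]) <= set(X[:, 0])

    def test_singleton_strata_reproduce_input(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        strata = [np.array([i]) for i in range(6)]
        np.testing.assert_array_equal(stratified_resample(X, strata, seed=0), X)

    def test_indices_stay_within_strata(self):
        X = np.arange(52, dtype=float)[:, None]
        strata = build_strata(52, 5)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            out = stratified_resample(X, strata, rng)
            for stratum in strata:
                seg = out[stratum, 0]
                assert seg.min() >= stratum.min() and seg.max() <= stratum.max()

    def test_seed_reproducibility(self):
        X = np.random.default_rng(0).standard_normal((52, 3))
        strata = build_strata(52, 5)
        a = stratified_resample(X, strata, seed=42)
        b = stratified_resample(X, strata, seed=42)
        np.testing.assert_array_equal(a, b)


class TestGreedyAlignment:
    def test_permutation_on_separated_components(self):
        rng = np.random.default_rng(0)
        B = np.linalg.qr(rng.standard_normal((8, 4)))[0]
        perm_true = np.array([2, 0, 3, 1])
        rep = B[:, perm_true] * np.array([1, -1, 1, -1])
        perm = _greedy_match(B, rep)
        assert sorted(perm) == [0, 1, 2, 3]  # a true permutation
        # ref component a is matched to the replicate column that holds it
        np.testing.assert_array_equal(perm, np.argsort(perm_true))


class TestRunSBS:
    def test_dominant_feature_always_selected(self):
        # feature 0 is the common factor driving three strong partners, so
        # it anchors PC1 in every replicate (re-autoscaling keeps unit
        # variances; dominance must come from the correlation structure)
        rng = np.random.default_rng(1)
        n, p = 30, 8
        X = rng.standard_normal((n, p))
        f = rng.standard_normal(n)
        X[:, 0] = f
        for j in (1, 2, 3):
            X[:, j] = 0.7 * f + 0.5 * rng.standard_normal(n)
        Z, _ = autoscale(X)
        plan = BootstrapPlan(
            n_reps=30, stratum_size=5, n_components=1, grid=((0.75, 1.0),), seed=2
        )
        stab = run_sbs_grid(Z, plan)
        assert stab.freq[0, 0, 0] == 1.0

    def test_single_rep_frequencies_binary(self):
        rng = np.random.default_rng(3)
        Z, _ = autoscale(rng.standard_normal((20, 6)))
        plan = BootstrapPlan(n_reps=1, stratum_size=5, n_components=2, grid=((0.5, 1.0),), seed=4)
        stab = run_sbs_grid(Z, plan)
        assert set(np.unique(stab.freq)) <= {0.0, 1.0}

    def test_frequency_granularity(self):
        rng = np.random.default_rng(5)
        Z, _ = autoscale(rng.standard_normal((20, 6)))
        plan = BootstrapPlan(n_reps=17, stratum_size=5, n_components=2, grid=((0.5, 1.0),), seed=6)
        stab = run_sbs_grid(Z, plan)
        counts = stab.freq * stab.n_reps_effective[:, None, None]
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert stab.freq.min() >= 0.0 and stab.freq.max() <= 1.0

    def test_pure_noise_uniform_selection_rate(self):
        """k=1, A=1: each feature selected ~1/p of the time on average."""
        rng = np.random.default_rng(7)
        p = 8
        Z, _ = autoscale(rng.standard_normal((40, p)))
        plan = BootstrapPlan(
            n_reps=200, stratum_size=5, n_components=1,
            grid=((1 - 1 / p - 1e-9, 1.0),), seed=8,
        )
        assert plan.config(*plan.grid[0]).cardinality(p) == 1
        stab = run_sbs_grid(Z, plan)
        mean_rate = stab.freq[0, 0].mean()
        # per-replicate exactly one selected feature
        assert mean_rate == pytest.approx(1 / p, abs=1e-9)
        sd = np.sqrt((1 / p) * (1 - 1 / p) / 200)
        assert np.all(stab.freq[0, 0] < 1 / p + 20 * sd)  # no runaway feature


class TestPermutationPvalues:
    def _small_stab(self):
        rng = np.random.default_rng(9)
        Z, _ = autoscale(rng.standard_normal((20, 6)))
        plan = BootstrapPlan(n_reps=20, stratum_size=5, n_components=1, grid=((0.5, 1.0),), seed=10)
        return Z, plan, run_sbs_grid(Z, plan)

    def test_minimum_n_perm_enforced(self):
        Z, plan, stab = self._small_stab()
        with pytest.raises(ValueError, match="19"):
            permutation_pvalues(Z, plan, (0.5, 1.0), stab, n_perm=5, seed=0)

    def test_bounds_and_floor(self):
        Z, plan, stab = self._small_stab()
        obs = np.zeros((1, 6))
        obs[0, 0] = 2.0  # above any attainable null frequency
        pv = permutation_pvalues(Z, plan, (0.5, 1.0), obs, n_perm=19, seed=1, null_reps=5)
        N = 19 * 6
        assert pv[0, 0] == pytest.approx(1.0 / (N + 1))
        obs2 = np.full((1, 6), -1.0)  # below every null value
        pv2 = permutation_pvalues(Z, plan, (0.5, 1.0), obs2, n_perm=19, seed=1, null_reps=5)
        assert np.all(pv2 == 1.0)


class TestThresholdsAndConsensus:
    def _stab_with(self, freq, pvals, configs=((0.6, 1.0),), var=(50.0,)):
        class _M:
            def __init__(self, v):
                self.total_adj_var = v

        n_c = len(configs)
        return StabilityResult(
            configs=list(configs),
            freq=np.asarray(freq, float),
            freq_subspace=np.asarray(freq, float),
            n_reps=100,
            n_reps_effective=np.full(n_c, 100),
            reference_models=[_M(v) for v in var],
            invalid=np.zeros(n_c, dtype=bool),
            pvals=np.asarray(pvals, float) if pvals is not None else None,
        )

    def test_robust_threshold_logic(self):
        freq = np.array([[[0.71, 0.70, 0.90]]])
        pvals = np.array([[[0.04, 0.04, 0.06]]])
        stab = self._stab_with(freq, pvals)
        robust = select_robust_markers(stab)
        assert robust.tolist() == [[[True, False, False]]]

    def test_robust_requires_pvalues(self):
        stab = self._stab_with(np.ones((1, 1, 3)), None)
        with pytest.raises(ValueError, match="p-values"):
            select_robust_markers(stab)

    def test_single_config_returned(self):
        stab = self._stab_with(np.ones((1, 1, 3)) * 0.8, None)
        assert choose_consensus_penalties(stab) == [(0.6, 1.0)]

    def test_tied_configs_both_returned_ordered(self):
        freq = np.array([[[0.8, 0.8, 0.1]], [[0.8, 0.8, 0.1]]])
        stab = self._stab_with(
            freq, None, configs=((0.7, 10.0), (0.6, 1.0)), var=(40.0, 40.0)
        )
        chosen = choose_consensus_penalties(stab)
        assert chosen == [(0.6, 1.0), (0.7, 10.0)]  # lower sparsity, ridge near 1 first

    def test_variance_floor_rejection(self):
        stab = self._stab_with(np.ones((1, 1, 3)), None, var=(5.0,))
        with pytest.raises(ValueError, match="adjusted variance"):
            choose_consensus_penalties(stab, variance_floor=10.0)


class TestFinalModel:
    def test_deterministic_and_ranked(self):
        rng = np.random.default_rng(11)
        Z, _ = autoscale(rng.standard_normal((30, 10)))
        plan = BootstrapPlan(n_components=2, grid=((0.6, 1.0), (0.7, 1.0)))
        ids = [f"f{i}" for i in range(10)]
        m1, r1 = final_model(Z, plan, (0.6, 1.0), feature_ids=ids)
        m2, r2 = final_model(Z, plan, (0.6, 1.0), feature_ids=ids)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        assert r1["rankings"][1].equals(r2["rankings"][1])
        assert set(r1["control_limits"]) == {1, 2}

    def test_config_outside_grid_rejected(self):
        rng = np.random.default_rng(12)
        Z, _ = autoscale(rng.standard_normal((30, 6)))
        plan = BootstrapPlan(n_components=2, grid=((0.6, 1.0),))
        with pytest.raises(ValueError, match="not on the plan grid"):
            final_model(Z, plan, (0.8, 1.0))

    def test_spill_recovery_noiseless(self):
        """A single clean left-sided spill ranks first in its component."""
        rng = np.random.default_rng(13)
        n, p = 40, 12
        X = rng.standard_normal((n, p))
        spill = np.zeros(n)
        spill[:4] = 8.0  # brief left-sided spill (10% exposure)
        X[:, 4] = spill + 0.05 * rng.standard_normal(n)
        Z, _ = autoscale(X)
        Z[:, 4] *= 4.0  # spill feature carries dominant variance
        plan = BootstrapPlan(n_components=1, grid=((0.75, 1.0),))
        model, report = final_model(Z, plan, (0.75, 1.0), feature_ids=[f"f{i}" for i in range(p)])
        assert report["rankings"][1]["feature_id"].iloc[0] == "f4"
        # the component's score trajectory deviates inside the spill window
        flagged = report["flagged_time_points"][1]
        assert flagged and all(t <= 4 for t in flagged)
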