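import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hvtime.containers import NormalizedMatrix, ReferenceGroup
from hvtime.errors import InsufficientData, InsufficientReplication
from hvtime.hv import (
    HVDetector,
    build_reference_group,
    detect_hv,
    hv_test,
    hv_threshold,
    loo_filter,
    residual_variance,
)
from hvtime.normalization import apply_model
from hvtime.simulate import SimulationConfig, generate_timecourse


class TestResidualVariance:
    def test_equal_within_groups(self):
        v, df = residual_variance([5, 5, 9, 9], ["a", "a", "b", "b"])
        assert v == 0.0 and df == 2

    def test_hand_arithmetic(self):
        # residuals +-1 in each pair: SSR = 4, df = 2 -> variance 2
        v, df = residual_variance([0, 2, 10, 12], ["a", "a", "b", "b"])
        assert v == pytest.approx(2.0) and df == 2

    def test_one_sample_per_group(self):
        with pytest.raises(InsufficientReplication):
            residual_variance([1, 2, 3], ["a", "b", "c"])


class TestReferenceGroup:
    def test_iid_noise_retains_most_genes(self, pair_groups):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 0.05, (2000, 10)))
        ref = build_reference_group(X, pair_groups)
        assert len(ref.member_probe_ids) >= 0.90 * 2000
        # bias-corrected pool close to the generating variance
        assert ref.pooled_variance == pytest.approx(0.0025, rel=0.05)

    def test_inflated_genes_excluded(self, pair_groups):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.05, (1800, 10)), rng.normal(0, 0.05 * np.sqrt(10), (200, 10))]
        )
        ref = build_reference_group(pd.DataFrame(X), pair_groups)
        members = set(map(int, ref.member_probe_ids))
        inflated_kept = sum(1 for i in range(1800, 2000) if i in members)
        assert inflated_kept <= 0.10 * 200

    def test_too_few_genes(self, pair_groups):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 10)))
        with pytest.raises(InsufficientData):
            build_reference_group(X, pair_groups)


class TestHvTest:
    def test_equal_variance_equal_df_gives_median(self):
        ref = ReferenceGroup(["x"], pooled_variance=0.5, pooled_df=10, iterations_to_converge=1)
        F, p = hv_test(0.5, 10, ref)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(0.5, abs=1e-12)  # F = 1 is the median at equal dfs

    def test_ratio_arithmetic(self):
        ref = ReferenceGroup(["x"], pooled_variance=0.5, pooled_df=200, iterations_to_converge=1)
        F, _ = hv_test(2.5, 4, ref)
        assert F == pytest.approx(5.0)

    def test_p_matches_monte_carlo_tail(self):
        # oracle: 10^6 scaled chi-square-ratio draws
        ref = ReferenceGroup(["x"], pooled_variance=1.0, pooled_df=200, iterations_to_converge=1)
        _, p = hv_test(5.0, 4, ref)
        rng = np.random.default_rng(3)
        n = 1_000_000
        draws = (rng.chisquare(4, n) / 4) / (rng.chisquare(200, n) / 200)
        mc = (draws >= 5.0).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(p - mc) < 3 * se


class TestThreshold:
    def test_cutoff_is_one_over_n(self):
        flags = hv_threshold([1e-4, 2e-4, 1e-5], 10_000)
        assert list(flags) == [False, False, True]

    def test_boundary_is_strict(self):
        assert not hv_threshold([1.0 / 500], 500)[0]

    def test_degenerate_n1(self):
        assert hv_threshold([0.999], 1)[0]

    def test_monotone_in_n(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 0.01, 200)
        counts = [hv_threshold(p, n).sum() for n in (100, 1_000, 10_000)]
        assert counts == sorted(counts, reverse=True)


class TestLooFilter:
    def test_displaced_sample_dropped_and_identified(self, pair_groups):
        x = np.zeros(10) + np.random.default_rng(0).normal(0, 0.01, 10)
        x[4] += 10 * 1.0  # 10 reference SDs on a flat gene
        keep, suspect = loo_filter(x, pair_groups)
        assert not keep
        assert suspect in (4, 5)  # within a pair the two members are symmetric

    def test_smooth_trend_kept_at_nominal_rate(self, pair_groups):
        rng = np.random.default_rng(1)
        trend = np.repeat(np.linspace(0, 0.25, 5), 2)
        drops = sum(
            not loo_filter(trend + rng.normal(0, 0.05, 10), pair_groups)[0]
            for _ in range(800)
        )
        rate = drops / 800
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 800)

    def test_artifact_flag_rate(self, pair_groups):
        rng = np.random.default_rng(2)
        flagged = 0
        n = 600
        for _ in range(n):
            x = rng.normal(0, 1, 10)
            x[rng.integers(10)] += 10.0
            flagged += not loo_filter(x, pair_groups)[0]
        assert flagged / n >= 0.90


def _null_norm(seed):
    cfg = SimulationConfig(
        seed=seed,
        n_genes=2000,
        treatments=("treated",),
        background_fraction=0.0,
        hv_fraction=0.0,
        artifact_fraction=0.0,
        identity_distortions=True,
    )
    matrix, truth = generate_timecourse(cfg)
    return matrix, apply_model(matrix, truth.background_model)


class TestDetectHv:
    def test_null_count_near_expectation(self):
        counts = []
        for seed in range(20):
            matrix, norm = _null_norm(3000 + seed)
            res = detect_hv(norm, [s.group for s in matrix.samples])
            counts.append(int((res.table["p"] < res.p_cutoff).sum()))
        assert np.mean(counts) <= 3.0  # expectation ~ N * (1/N) = 1

    def test_sensitivity_and_precision(self):
        # pooled over several datasets: a single 40-gene truth set is too
        # small to estimate a rate against a 0.8 bound
        from hvtime.normalization import normalize_matrix

        tp = n_true = n_called = 0
        for seed in range(4):
            cfg = SimulationConfig(seed=seed, n_genes=2000, treatments=("treated",))
            matrix, truth = generate_timecourse(cfg)
            norm = normalize_matrix(matrix)
            res = detect_hv(norm, [s.group for s in matrix.samples])
            hv = set(res.hv_probes)
            true_hv = set(truth.probes("hv"))
            tp += len(hv & true_hv)
            n_true += len(true_hv)
            n_called += len(hv)
        assert tp / n_true >= 0.8
        assert tp / n_called >= 0.8

    def test_result_invariants(self, normalized_sim):
        cfg, matrix, truth, norm = normalized_sim
        res = detect_hv(norm, [s.group for s in matrix.samples])
        t = res.table
        assert res.p_cutoff == pytest.approx(1.0 / res.n_expressed)
        np.testing.assert_allclose(
            t["F"], t["variance"] / res.reference.pooled_variance, rtol=1e-12
        )
        assert not (t["hv_flag"] & t["loo_dropped"]).any()
        assert (t.loc[t["hv_flag"], "p"] < res.p_cutoff).all()

    def test_permutation_equivariance(self, null_sim):
        cfg, matrix, truth, norm = null_sim
        groups = [s.group for s in matrix.samples]
        res = detect_hv(norm, groups)
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.log_values.index)
        norm_p = NormalizedMatrix(
            log_values=norm.log_values.loc[perm],
            expressed=norm.expressed.loc[perm],
            z_threshold=norm.z_threshold,
            floor_z=norm.floor_z,
        )
        res_p = detect_hv(norm_p, groups)
        pd.testing.assert_frame_equal(res_p.table.sort_index(), res.table.sort_index())

    def test_scale_invariance_of_flags(self, null_sim):
        cfg, matrix, truth, norm = null_sim
        groups = [s.group for s in matrix.samples]
        res = detect_hv(norm, groups)
        scaled = NormalizedMatrix(
            log_values=norm.log_values * 3.7,
            expressed=norm.expressed,
            z_threshold=norm.z_threshold,
            floor_z=norm.floor_z,
        )
        res_s = detect_hv(scaled, groups)
        np.testing.assert_allclose(res_s.table["F"], res.table["F"], rtol=1e-9)
        np.testing.assert_allclose(res_s.table["p"], res.table["p"], rtol=1e-6, atol=1e-12)
        assert (res_s.table["hv_flag"] == res.table["hv_flag"]).all()

    def test_null_pvalues_uniform(self, null_sim):
        cfg, matrix, truth, norm = null_sim
        res = detect_hv(norm, [s.group for s in matrix.samples])
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_empty_expressed_set(self, pair_groups):
        lv = pd.DataFrame(np.zeros((100, 10)))
        mask = pd.DataFrame(False, index=lv.index, columns=lv.columns)
        norm = NormalizedMatrix(log_values=lv, expressed=mask)
        with pytest.raises(InsufficientData):
            detect_hv(norm, pair_groups)

    def test_estimator_api(self, null_sim):
        cfg, matrix, truth, norm = null_sim
        det = HVDetector(alpha_loo=0.01)
        assert det.get_params()["alpha_loo"] == 0.01
        det.set_params(alpha_loo=0.05).fit(norm, [s.group for s in matrix.samples])
        assert hasattr(det, "result_") and det.n_expressed_ > 0
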