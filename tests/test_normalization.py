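import numpy as np
import pandas as pd
import pytest

from hvtime.errors import (
    DegenerateDistribution,
    InsufficientData,
    InvalidModel,
)
from hvtime.normalization import (
    align_arrays,
    fit_background,
    log_transform,
    normalize_array,
    normalize_matrix,
)


class TestFitBackground:
    def test_symmetric_gaussian(self):
        rng = np.random.default_rng(0)
        mean, sd = fit_background(rng.normal(0.0, 1.0, 50_000))
        assert abs(mean) < 0.05 and abs(sd - 1.0) < 0.05

    def test_mixture_recovers_background_component(self):
        # 90% background N(0, 2), 10% strongly expressed; oracle = moments
        # of the labeled background draws.
        rng = np.random.default_rng(1)
        bg = rng.normal(0.0, 2.0, 18_000)
        fg = rng.uniform(20.0, 500.0, 2_000)
        mean, sd = fit_background(np.concatenate([bg, fg]))
        assert abs(mean - bg.mean()) < 0.05 * bg.std()
        assert abs(sd - bg.std()) < 0.05 * bg.std()

    def test_constant_input(self):
        with pytest.raises(DegenerateDistribution):
            fit_background(np.full(1000, 7.3))

    def test_too_few_values(self):
        with pytest.raises(InsufficientData):
            fit_background(np.random.default_rng(0).normal(size=499))

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 15_000), rng.uniform(10, 80, 5_000)])
        m1, s1 = fit_background(x)
        m2, s2 = fit_background(c * x)
        assert m2 == pytest.approx(c * m1, abs=0.02 * c * s1)
        assert s2 == pytest.approx(c * s1, rel=0.02)


class TestNormalizeArray:
    @pytest.mark.parametrize(
        "x, mean, sd, expected",
        [(5.0, 5.0, 2.0, 0.0), (11.0, 5.0, 2.0, 3.0), (7.0, 5.0, 2.0, 1.0)],
    )
    def test_z_identities(self, x, mean, sd, expected):
        assert normalize_array(np.array([x]), mean, sd)[0] == pytest.approx(expected)

    def test_invalid_sd(self):
        with pytest.raises(InvalidModel):
            normalize_array(np.array([1.0]), 0.0, 0.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(3.0, 40.0, 1000)
        z = normalize_array(raw, 3.0, 40.0)
        np.testing.assert_allclose(z * 40.0 + 3.0, raw, atol=1e-10)


class TestLogTransform:
    def test_expression_cutoff_maps_to_0477(self):
        logv, expr = log_transform(np.array([3.0]))
        assert round(float(logv[0]), 3) == 0.477
        assert bool(expr[0])

    @pytest.mark.parametrize(
        "z, expected_log, expected_expr",
        [(10.0, 1.0, True), (-2.0, 0.0, False), (1.0, 0.0, False), (2.9, np.log10(2.9), False)],
    )
    def test_floor_and_mask(self, z, expected_log, expected_expr):
        logv, expr = log_transform(np.array([z]))
        assert logv[0] == pytest.approx(expected_log)
        assert bool(expr[0]) is expected_expr

    def test_precondition(self):
        with pytest.raises(InvalidModel):
            log_transform(np.array([1.0]), z_threshold=0.5, floor_z=1.0)


def _clean_logs(n=600, n_arrays=5, seed=1):
    rng = np.random.default_rng(seed)
    true = rng.uniform(0.5, 2.5, n)
    cols = {f"a{i}": true + rng.normal(0, 0.03, n) for i in range(n_arrays)}
    lv = pd.DataFrame(cols)
    mask = pd.DataFrame(True, index=lv.index, columns=lv.columns)
    return lv, mask, rng


class TestAlignArrays:
    def test_identical_arrays_unchanged(self):
        lv = pd.DataFrame({"a": [1.0, 2, 3] * 20, "b": [1.0, 2, 3] * 20})
        mask = pd.DataFrame(True, index=lv.index, columns=lv.columns)
        adj, coefs = align_arrays(lv, mask)
        for slope, intercept in coefs.values():
            assert slope == pytest.approx(1.0, abs=1e-6)
            assert intercept == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(adj.to_numpy(), lv.to_numpy(), atol=1e-6)

    def test_known_affine_recovered(self):
        lv, mask, _ = _clean_logs()
        lv["a4"] = 1.2 * lv["a4"] + 0.3
        adj, coefs = align_arrays(lv, mask)
        slope, intercept = coefs["a4"]
        assert slope == pytest.approx(1.2, rel=0.01)
        assert intercept == pytest.approx(0.3, abs=0.01 * 0.3 + 0.005)
        # ordinary post-fit regression returns identity on clean data
        ref = adj.drop(columns="a4").median(axis=1)
        b1, b0 = np.polyfit(ref, adj["a4"], 1)
        assert b1 == pytest.approx(1.0, abs=1e-2)

    def test_robust_to_outliers_where_ols_fails(self):
        lv, mask, rng = _clean_logs(seed=3)
        lv["a4"] = 1.2 * lv["a4"] + 0.3
        out = rng.choice(len(lv), len(lv) // 20, replace=False)
        lv.loc[out, "a4"] = rng.uniform(4.0, 6.0, len(out))
        adj, coefs = align_arrays(lv, mask)
        slope, intercept = coefs["a4"]
        assert slope == pytest.approx(1.2, rel=0.03)
        ref = lv.drop(columns="a4").median(axis=1)
        ols_slope = np.polyfit(ref, lv["a4"], 1)[0]
        assert abs(ols_slope - 1.2) > abs(slope - 1.2)  # OLS errs by more

    def test_too_few_common_genes(self):
        lv, mask, _ = _clean_logs(n=100)
        mask.iloc[20:] = False
        with pytest.raises(InsufficientData):
            align_arrays(lv, mask)


class TestOnSyntheticData:
    def test_mask_invariant_under_alignment(self, small_sim):
        cfg, matrix, truth = small_sim
        aligned = normalize_matrix(matrix)
        unaligned = normalize_matrix(matrix, align=False)
        pd.testing.assert_frame_equal(aligned.expressed, unaligned.expressed)

    def test_background_false_positive_mask_rate(self, small_sim):
        # nominal upper tail beyond 3 SD is 0.135%; allow estimation slack
        cfg, matrix, truth = small_sim
        norm = normalize_matrix(matrix)
        bg = truth.probes("background")
        frac = norm.expressed.loc[bg].to_numpy().mean()
        assert frac <= 0.005

    def test_background_recovery_on_platform_scale_arrays(self):
        # at the 24,526-probe panel size the mode/mirror estimator must
        # recover the generating background within 5%
        from hvtime.simulate import SimulationConfig, generate_timecourse

        cfg = SimulationConfig(seed=19, treatments=("treated",))
        matrix, truth = generate_timecourse(cfg)
        for aid in matrix.array_ids[:4]:
            mean, sd = fit_background(matrix.values[aid].to_numpy())
            assert abs(mean) <= 0.05 * cfg.background_sd
            assert sd == pytest.approx(cfg.background_sd, rel=0.05)
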