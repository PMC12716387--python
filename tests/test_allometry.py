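"""SMA allometry: fits, slope tests, investment residuals."""

import numpy as np
import pandas as pd
import pytest

import cuticlevol as cv
from cuticlevol import allometry as al


def random_xy(rng, n=50, slope=1.1, noise=0.2):
    x = rng.normal(6.0, 0.8, n)
    y = slope * x + rng.normal(0.0, noise, n)
    return x, y


class TestSmaFit:
    def test_matches_moment_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = random_xy(rng)
            fit = cv.sma_fit(x, y)
            cov = np.cov(x, y, ddof=1)
            oracle = np.sign(cov[0, 1]) * np.sqrt(cov[1, 1] / cov[0, 0])
            assert fit.slope == pytest.approx(oracle, abs=1e-12)

    def test_residuals_sum_to_zero_and_line_through_centroid(self):
        rng = np.random.default_rng(2)
        x, y = random_xy(rng)
        fit = cv.sma_fit(x, y)
        assert abs(fit.residuals.sum()) < 1e-9
        assert fit.intercept + fit.slope * x.mean() == pytest.approx(y.mean())

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = random_xy(rng)
        assert cv.sma_fit(x, y).slope * cv.sma_fit(y, x).slope == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x, y = random_xy(rng)
        b = cv.sma_fit(x, y).slope
        assert cv.sma_fit(x, 3.0 * y).slope == pytest.approx(3.0 * b)
        assert cv.sma_fit(2.0 * x, y).slope == pytest.approx(b / 2.0)

    def test_negative_correlation_gives_negative_slope(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = -2.0 * x + rng.normal(0, 0.1, 40)
        fit = cv.sma_fit(x, y)
        assert fit.slope < 0
        assert fit.ci[0] < fit.slope < fit.ci[1]

    def test_exact_line(self):
        x = np.arange(10.0)
        fit = cv.sma_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.ci[0] == pytest.approx(2.0) and fit.ci[1] == pytest.approx(2.0)

    def test_ci_covers_slope_and_tightens_with_n(self):
        rng = np.random.default_rng(6)
        x, y = random_xy(rng, n=500)
        fit = cv.sma_fit(x, y)
        assert fit.ci[0] < fit.slope < fit.ci[1]
        small = cv.sma_fit(x[:20], y[:20])
        assert (fit.ci[1] - fit.ci[0]) < (small.ci[1] - small.ci[0])

    def test_validation(self):
        with pytest.raises(ValueError):
            cv.sma_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            cv.sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="finite"):
            cv.sma_fit([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])


class TestSlopeTests:
    def test_isometry_rejected_for_steep_slope(self):
        rng = np.random.default_rng(7)
        x = rng.normal(6, 0.8, 200)
        y = 1.5 * x + rng.normal(0, 0.1, 200)
        t = cv.test_slope_equals(cv.sma_fit(x, y), 1.0)
        assert t.p_value < 0.001

    def test_isometry_retained_when_true(self):
        rng = np.random.default_rng(8)
        z1, z2, z3 = (rng.normal(size=300) for _ in range(3))
        t = cv.test_slope_equals(cv.sma_fit(z1 + z2, z1 + z3), 1.0)
        assert t.p_value > 0.05

    def test_exact_line_degenerate(self):
        x = np.arange(10.0)
        t = cv.test_slope_equals(cv.sma_fit(x, 2.0 * x), 2.0)
        assert t.degenerate and t.p_value == 1.0

    def test_zero_null_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            cv.test_slope_equals(cv.sma_fit(x, 2.0 * x + 0.01 * x**2), 0.0)

    def test_common_slope_retained_and_rejected(self):
        rng = np.random.default_rng(9)
        same = []
        for g in "ab":
            x = rng.normal(6, 0.8, 150)
            y = 1.2 * x + rng.normal(0, 0.15, 150)
            same.append(cv.sma_fit(x, y, group=g))
        t_same = cv.test_common_slope(same)
        assert t_same.p_value > 0.05

        x = rng.normal(6, 0.8, 150)
        diff = [same[0], cv.sma_fit(x, 2.5 * x + rng.normal(0, 0.15, 150), group="c")]
        t_diff = cv.test_common_slope(diff)
        assert t_diff.p_value < 0.001

    def test_permutation_agrees_with_lr(self):
        rng = np.random.default_rng(10)
        fits = []
        for g in "ab":
            x = rng.normal(6, 0.8, 60)
            y = 1.2 * x + rng.normal(0, 0.15, 60)
            fits.append(cv.sma_fit(x, y, group=g))
        p_lr = cv.test_common_slope(fits, method="lr").p_value
        p_perm = cv.test_common_slope(
            fits, method="permutation", n_permutations=300, seed=0
        ).p_value
        assert (p_lr > 0.05) == (p_perm > 0.05)

    def test_common_slope_validation(self):
        x = np.arange(10.0)
        f = cv.sma_fit(x, 2.0 * x + 0.01 * x**2)
        with pytest.raises(ValueError):
            cv.test_common_slope([f])


class TestSpeciesTables:
    @staticmethod
    def records():
        return pd.DataFrame(
            {
                "species": ["s1", "s1", "s2", "s2", "s3"],
                "caste": ["worker"] * 5,
                "cuticle_volume_um3": [10.0, 14.0, 100.0, 140.0, 1000.0],
                "body_volume_um3": [100.0, 140.0, 1000.0, 1400.0, 10000.0],
            }
        )

    def test_species_means_arithmetic(self):
        out = cv.species_means(self.records())
        s1 = out[out["species"] == "s1"].iloc[0]
        assert s1["cuticle_volume_um3"] == 12.0
        assert s1["n_specimens"] == 2

    def test_species_means_geometric(self):
        out = cv.species_means(self.records(), log_then_mean=True)
        s1 = out[out["species"] == "s1"].iloc[0]
        assert s1["cuticle_volume_um3"] == pytest.approx(np.sqrt(10.0 * 14.0))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cv.species_means(pd.DataFrame({"species": ["a"]}))

    def test_standardized_investment_residuals(self):
        means = cv.species_means(self.records())
        res, fit = cv.standardized_investment(means, "worker")
        assert set(res.index) == {"s1", "s2", "s3"}
        # Constant 10% ratio: isometric line, residuals all ~0.
        assert np.allclose(res.to_numpy(), 0.0, atol=1e-12)
        assert fit.slope == pytest.approx(1.0)

    def test_caste_correlation_perfect(self):
        a = pd.Series([0.1, -0.2, 0.05], index=["s1", "s2", "s3"])
        r2, slope, p, n = cv.caste_correlation(a, 2.0 * a)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert n == 3

    def test_caste_correlation_needs_overlap(self):
        a = pd.Series([0.1, 0.2, 0.3], index=["s1", "s2", "s3"])
        b = pd.Series([0.1, 0.2, 0.3], index=["s4", "s5", "s6"])
        with pytest.raises(ValueError, match="matched"):
            cv.caste_correlation(a, b)


class TestCompareToReference:
    def test_identical_tables_r2_one(self):
        df = pd.DataFrame(
            {
                "specimen_id": ["a", "b", "c"],
                "cuticle_volume_um3": [10.0, 20.0, 40.0],
                "body_volume_um3": [100.0, 150.0, 200.0],
            }
        )
        r2v, r2r, table = cv.compare_to_reference(df, df.copy())
        assert r2v == pytest.approx(1.0)
        assert r2r == pytest.approx(1.0)
        assert len(table) == 3
        assert np.allclose(table["cuticle_volume_delta"], 0.0)

    def test_no_match_rejected(self):
        a = pd.DataFrame(
            {"specimen_id": ["a"], "cuticle_volume_um3": [1.0],
             "body_volume_um3": [2.0]}
        )
        b = a.copy()
        b["specimen_id"] = ["z"]
        with pytest.raises(ValueError, match="matching"):
            cv.compare_to_reference(a, b)
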