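"""Correlation, regression and balanced factorial ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from weedcomp.stats import (
    UnbalancedDesignError,
    ZeroVarianceError,
    balanced_anova,
    linear_fit,
    pearson_r,
    significance_marker,
)


def brute_force_pearson(x, y):
    """Covariance / product of standard deviations, straight from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


def brute_force_anova(df, response, factors):
    """Marginal-means sums-of-squares decomposition for a balanced design.

    Every effect's SS is computed directly from cell/marginal means with
    inclusion-exclusion, independent of any regression machinery.
    """
    y = df[response].to_numpy(float)
    grand = y.mean()
    n = len(y)
    ss = {}
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            means = df.groupby(list(combo))[response].transform("mean").to_numpy()
            total = np.sum((means - grand) ** 2)
            lower = sum(ss[sub] for r in range(1, order)
                        for sub in itertools.combinations(combo, r))
            ss[combo] = total - lower
    ss_effects = sum(ss.values())
    ss_total = np.sum((y - grand) ** 2)
    out = {" x ".join(c): v for c, v in ss.items()}
    out["residual"] = ss_total - ss_effects
    return out


class TestPearson:
    def test_perfect_line(self):
        res = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.r == pytest.approx(1.0)

    def test_negation_flips_sign(self):
        x = [1.0, 2.0, 4.0, 7.0]
        assert pearson_r(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_against_definition_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 5]
        assert pearson_r(x, y).r == pytest.approx(brute_force_pearson(x, y),
                                                  rel=1e-12)

    def test_affine_invariance(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.1])
        y = np.array([2.1, 0.4, 3.3, 1.0, 4.2])
        base = pearson_r(x, y).r
        assert pearson_r(3.0 * x + 7.0, 0.5 * y - 2.0).r == pytest.approx(base)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestLinearFit:
    def test_exact_line_has_zero_residuals(self):
        res = linear_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert (res.slope, res.intercept) == pytest.approx((2.0, 1.0))
        assert res.r_squared == pytest.approx(1.0)

    def test_no_trend_gives_zero_slope(self):
        res = linear_fit([-2, -1, 1, 2], [5.0, 3.0, 3.0, 5.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_against_normal_equations_oracle(self):
        x = np.array([0.5, 1.1, 2.0, 3.7, 4.4])
        y = np.array([1.0, 0.4, 2.2, 2.9, 5.1])
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        res = linear_fit(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)


def balanced_frame(levels, reps, seed=0, effects=None):
    rng = np.random.default_rng(seed)
    rows = []
    for combo in itertools.product(*[range(k) for k in levels]):
        for _ in range(reps):
            y = rng.normal()
            if effects:
                y += effects(combo)
            rows.append({f"f{i}": f"l{v}" for i, v in enumerate(combo)} | {"y": y})
    return pd.DataFrame(rows)


class TestBalancedAnova:
    def test_flat_cells_have_zero_effect_ms(self):
        df = balanced_frame([2, 3], reps=2)
        df["y"] = 7.0
        table = balanced_anova(df, "y", ["f0", "f1"]).set_index("term")
        assert table.loc["f0", "mean_sq"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["f0 x f1", "mean_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_additive_effects_have_zero_interaction(self):
        df = balanced_frame([2, 2], reps=3)
        df["y"] = df["f0"].map({"l0": 0.0, "l1": 2.0}) + df["f1"].map(
            {"l0": 0.0, "l1": 5.0}
        )
        table = balanced_anova(df, "y", ["f0", "f1"]).set_index("term")
        assert table.loc["f0 x f1", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_marginal_means_oracle(self, seed):
        df = balanced_frame([2, 3, 2], reps=2, seed=seed,
                            effects=lambda c: 0.8 * c[0] - 0.5 * c[1] * c[2])
        table = balanced_anova(df, "y", ["f0", "f1", "f2"]).set_index("term")
        oracle = brute_force_anova(df, "y", ["f0", "f1", "f2"])
        for term, ss in oracle.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-9)
        assert table["sum_sq"].sum() == pytest.approx(
            np.sum((df["y"] - df["y"].mean()) ** 2), abs=1e-9
        )

    def test_df_partition(self):
        df = balanced_frame([2, 3], reps=4, seed=3)
        table = balanced_anova(df, "y", ["f0", "f1"])
        assert table["df"].sum() == len(df) - 1

    def test_single_factor_f_is_squared_t(self):
        df = balanced_frame([2], reps=8, seed=5,
                            effects=lambda c: 1.5 * c[0])
        table = balanced_anova(df, "y", ["f0"]).set_index("term")
        from scipy import stats as sps

        a = df[df["f0"] == "l0"]["y"]
        b = df[df["f0"] == "l1"]["y"]
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert table.loc["f0", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_unbalanced_design_rejected(self):
        df = balanced_frame([2, 2], reps=2)
        with pytest.raises(UnbalancedDesignError):
            balanced_anova(df.iloc[:-1], "y", ["f0", "f1"])

    def test_rank_transform_available(self):
        df = balanced_frame([2, 2], reps=3, seed=9)
        table = balanced_anova(df, "y", ["f0", "f1"], transform="rank")
        assert table["sum_sq"].sum() == pytest.approx(
            np.sum((np.arange(1, 13) - 6.5) ** 2), abs=1e-9
        )


def test_significance_markers():
    assert significance_marker(0.0004) == "***"
    assert significance_marker(0.004) == "**"
    assert significance_marker(0.04) == "*"
    assert significance_marker(0.4) == "ns"
    assert significance_marker(float("nan")) == "ns"
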