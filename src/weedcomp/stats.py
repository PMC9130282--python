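"""Association statistics: Pearson correlation, simple linear regression and
balanced fixed-effects factorial ANOVA.

The ANOVA supports fully crossed, balanced designs with up to three fixed
factors (the year x site and year x site x biotype layouts of a multi-site
replacement-series trial).  Sums of squares come from a type-I decomposition,
which on balanced data equals the classical marginal-means decomposition;
unbalanced designs are rejected explicitly rather than silently re-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class ZeroVarianceError(ValueError):
    """A correlation or regression input has no variance."""


class UnbalancedDesignError(ValueError):
    """The factorial design is not fully crossed with equal cell counts."""


@dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation with a two-sided t-based p-value (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a correlation, got n = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue),
                         n=int(x.size))


def linear_fit(x, y) -> LinearFitResult:
    """Ordinary least-squares line y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 2")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("regression undefined for constant x")
    res = sps.linregress(x, y)
    return LinearFitResult(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue) ** 2)


def _transform(y: pd.Series, transform: str | None) -> pd.Series:
    if transform is None:
        return y
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires a strictly positive response")
        return np.log(y)
    if transform == "rank":
        return pd.Series(sps.rankdata(y), index=y.index)
    raise ValueError(f"unknown transform {transform!r}")


def balanced_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    transform: str | None = None,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA table for a balanced crossed design.

    Returns a table with one row per main effect and interaction plus a
    residual row: columns ``term, df, sum_sq, mean_sq, F, p``.  ``transform``
    optionally applies a log or rank pre-step to the response (default off).

    Raises :class:`UnbalancedDesignError` unless every cell of the full cross
    is present with the same replicate count.
    """
    if not 1 <= len(factors) <= 3:
        raise ValueError("1 to 3 factors are supported")
    for col in [response, *factors]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    sub = data[[response, *factors]].dropna()
    if sub[response].isna().any() or not len(sub):
        raise ValueError("empty response after dropping missing values")

    counts = sub.groupby(factors, observed=True).size()
    levels = [sub[f].nunique() for f in factors]
    n_cells = int(np.prod(levels))
    if len(counts) != n_cells or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "design is not fully crossed with equal cell counts; "
            "only balanced designs are supported"
        )
    reps = int(counts.iloc[0])

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = sub.rename(columns={response: "_y", **{f: f"_f{i}" for i, f in enumerate(factors)}})
    work["_y"] = _transform(work["_y"], transform).to_numpy()
    formula = "_y ~ " + " * ".join(f"C(_f{i})" for i in range(len(factors)))
    model = smf.ols(formula, data=work).fit()
    table = sm.stats.anova_lm(model, typ=1)

    name_map = {}
    for term in table.index:
        if term == "Residual":
            name_map[term] = "residual"
            continue
        parts = [p.strip() for p in term.split(":")]
        pretty = []
        for part in parts:
            idx = int(part[len("C(_f"):-1])
            pretty.append(factors[idx])
        name_map[term] = " x ".join(pretty)

    out = pd.DataFrame(
        {
            "term": [name_map[t] for t in table.index],
            "df": table["df"].astype(int).to_numpy(),
            "sum_sq": table["sum_sq"].to_numpy(),
            "mean_sq": (table["sum_sq"] / table["df"]).to_numpy(),
            "F": table["F"].to_numpy(),
            "p": table["PR(>F)"].to_numpy(),
        }
    )
    if reps == 1:
        # saturated model: no residual df, F ratios are undefined
        out.loc[out["term"] != "residual", ["F", "p"]] = np.nan
    return out.reset_index(drop=True)


def significance_marker(p: float) -> str:
    """Conventional star markers: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
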