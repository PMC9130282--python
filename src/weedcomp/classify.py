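"""Classification of replacement series into the five competition models.

The replicate-averaged relative-yield curves of a series are compared with
the no-competition expectation (RY = sown fraction, TRY = 1) by a chi-square
goodness-of-fit.  Each component's curve is labelled straight (deviation not
significant), convex (significant, above the line: that component benefits)
or concave (significant, below: it loses); the TRY curve is tested against 1
the same way.  The taxonomy then reads:

    I    both components straight, TRY = 1 - full competition for the same
         resources, yields proportional to sowing fraction
    IIa  TRY = 1 but component B convex / component A concave - B gains what
         A loses
    IIb  the mirror image - A gains what B loses
    III  TRY significantly above 1 - demand does not exceed supply, partial
         niche separation or facilitation
    IV   TRY significantly below 1 - mutual antagonism, both lose

Relative yields are expressed in percent (x100) for the test so that the
statistic has usable resolution on replacement-series effect sizes; on the
raw 0-1 scale the TRY-vs-1 statistic is bounded above by the number of
mixture points, which puts model IV outside the critical region of any
conventional alpha.  See the methods note for the full argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODEL_LABELS = ("I", "IIa", "IIb", "III", "IV")

#: scale on which RY values enter the chi-square (1.0 = raw relative yields,
#: 100.0 = percentages, the default)
RY_SCALE = 100.0


@dataclass
class Chi2Result:
    chi2: float
    dof: int
    p_value: float
    n_points: int


@dataclass
class CompetitionModelFit:
    series_id: str
    chi2_a: float
    chi2_b: float
    chi2_try: float
    dof: int
    p_a: float
    p_b: float
    p_try: float
    curvature_a: str
    curvature_b: str
    try_regime: str
    model_label: str
    notes: list[str] = field(default_factory=list)


def expected_no_competition(p: float) -> float:
    """Expected relative yield under no competition: the sown fraction itself."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    return p


def chi2_gof(observed, expected) -> Chi2Result:
    """Pearson chi-square goodness of fit, sum((O - E)^2 / E), dof = n - 1 (floor 1).

    Points with expected value 0 are dropped with a warning.  The statistic
    is invariant to permutation of the points and additive over disjoint
    point sets.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same length")
    if obs.size == 0:
        raise ValueError("at least one point is required")
    keep = exp != 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} point(s) with expected = 0",
                      stacklevel=2)
        obs, exp = obs[keep], exp[keep]
    if obs.size == 0:
        raise ValueError("all points had expected = 0")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    dof = max(obs.size - 1, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return Chi2Result(chi2=chi2, dof=dof, p_value=p, n_points=int(obs.size))


def curvature(observed, expected, alpha: float = 0.05) -> str:
    """Straight / convex / concave label of an RY curve against its expectation."""
    res = chi2_gof(observed, expected)
    if res.p_value >= alpha:
        return "straight"
    mean_dev = float(np.mean(np.asarray(observed, float) - np.asarray(expected, float)))
    if mean_dev > 0:
        return "convex"
    if mean_dev < 0:
        return "concave"
    warnings.warn("significant chi-square with zero mean deviation; "
                  "labelling straight", stacklevel=2)
    return "straight"


def classify_series(
    points: pd.DataFrame,
    alpha: float = 0.05,
    series_id: str = "",
    scale: float = RY_SCALE,
) -> CompetitionModelFit:
    """Fit one series (one basis) to the five-model taxonomy.

    ``points`` needs columns ``proportion_a``, ``ry_a``, ``ry_b``; replicate
    rows (if a ``replicate`` column is present) are averaged per proportion
    before testing.  Only mixed proportions (0 < p < 1) enter the tests.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = points
    if "replicate" in df.columns:
        df = df.groupby("proportion_a", as_index=False)[["ry_a", "ry_b"]].mean()
    df = df[(df["proportion_a"] > 0) & (df["proportion_a"] < 1)]
    if df.empty:
        raise ValueError("no mixed proportions to classify")

    p = df["proportion_a"].to_numpy(float)
    ry_a = df["ry_a"].to_numpy(float)
    ry_b = df["ry_b"].to_numpy(float)
    try_obs = ry_a + ry_b

    res_a = chi2_gof(scale * ry_a, scale * p)
    res_b = chi2_gof(scale * ry_b, scale * (1.0 - p))
    res_t = chi2_gof(scale * try_obs, scale * np.ones_like(try_obs))

    curv_a = _curvature_from(res_a, ry_a - p, alpha)
    curv_b = _curvature_from(res_b, ry_b - (1.0 - p), alpha)

    if res_t.p_value >= alpha:
        regime = "equal_1"
    else:
        regime = "above_1" if float(np.mean(try_obs - 1.0)) > 0 else "below_1"

    notes: list[str] = []
    label = _model_label(curv_a, curv_b, regime, res_a.chi2, res_b.chi2, notes)

    return CompetitionModelFit(
        series_id=series_id,
        chi2_a=res_a.chi2,
        chi2_b=res_b.chi2,
        chi2_try=res_t.chi2,
        dof=res_a.dof,
        p_a=res_a.p_value,
        p_b=res_b.p_value,
        p_try=res_t.p_value,
        curvature_a=curv_a,
        curvature_b=curv_b,
        try_regime=regime,
        model_label=label,
        notes=notes,
    )


def _curvature_from(res: Chi2Result, deviations: np.ndarray, alpha: float) -> str:
    if res.p_value >= alpha:
        return "straight"
    mean_dev = float(np.mean(deviations))
    if mean_dev > 0:
        return "convex"
    if mean_dev < 0:
        return "concave"
    return "straight"


def _model_label(
    curv_a: str, curv_b: str, regime: str,
    chi2_a: float, chi2_b: float, notes: list[str],
) -> str:
    if regime == "above_1":
        return "III"
    if regime == "below_1":
        return "IV"
    # TRY consistent with 1
    if curv_a == "straight" and curv_b == "straight":
        return "I"
    if curv_b == "convex" and curv_a != "convex":
        return "IIa"
    if curv_a == "convex" and curv_b != "convex":
        return "IIb"
    if curv_a == "convex" and curv_b == "convex":
        notes.append("contradictory pattern: both components convex with TRY = 1; "
                     "labelled by the larger deviation")
        return "IIa" if chi2_b >= chi2_a else "IIb"
    # only concave curvature(s) with TRY = 1: the other component is
    # relatively favoured even if its own deviation is not significant
    if curv_a == "concave" and curv_b != "concave":
        notes.append("component A concave with TRY = 1; nearest model IIa")
        return "IIa"
    if curv_b == "concave" and curv_a != "concave":
        notes.append("component B concave with TRY = 1; nearest model IIb")
        return "IIb"
    notes.append("contradictory pattern: both components concave with TRY = 1; "
                 "nearest model IV")
    return "IV"


def classify_indices(
    indices: pd.DataFrame, alpha: float = 0.05, scale: float = RY_SCALE
) -> pd.DataFrame:
    """Classify every site x season x series x basis block of an index table."""
    rows = []
    for (site, season, series, basis), g in indices.groupby(
        ["site_id", "season", "series", "basis"]
    ):
        fit = classify_series(
            g, alpha=alpha, series_id=f"{site}|{season}|{series}|{basis}",
            scale=scale,
        )
        rows.append(
            {
                "site_id": site,
                "season": season,
                "series": series,
                "basis": basis,
                "chi2_a": fit.chi2_a,
                "chi2_b": fit.chi2_b,
                "chi2_try": fit.chi2_try,
                "dof": fit.dof,
                "p_a": fit.p_a,
                "p_b": fit.p_b,
                "p_try": fit.p_try,
                "curvature_a": fit.curvature_a,
                "curvature_b": fit.curvature_b,
                "try_regime": fit.try_regime,
                "model_label": fit.model_label,
                "notes": "; ".join(fit.notes),
            }
        )
    return pd.DataFrame(rows)
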