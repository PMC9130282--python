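"""Multivariate site grouping: correlation-matrix PCA, k-means and group means.

Rows of the trait matrix are site x biotype-mixture units; columns combine
environmental descriptors (sand, silt, clay, hydrothermal K) with winter
wheat performance (plant length, seed yield, thousand-grain weight, biomass,
seed number).  PCA is computed on the correlation matrix so that loadings
are correlations between variables and components (bounded by 1 in
magnitude); k-means (k = 2 by default) partitions the standardized rows, and
group means are reported on the raw scale with Welch two-sample significance
markers, rounded half-up to two decimals as in agronomic report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from ._util import round_half_up
from .stats import significance_marker

DEFAULT_KMEANS_SEED = 20180919
DEFAULT_RESTARTS = 50


class ConstantColumnError(ValueError):
    """A column has zero variance and cannot be standardized."""


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # variables x components, correlation scale
    variance_fraction: np.ndarray   # per component, sums to 1
    scores: pd.DataFrame            # rows x components
    rank_deficient: bool = False


@dataclass
class GroupingResult:
    assignments: pd.Series                 # row -> group id (1-based)
    group_means: pd.DataFrame              # variables x groups, rounded
    markers: dict[str, str] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, sample variance 1); idempotent."""
    df = matrix.astype(float)
    std = df.std(ddof=1)
    zero = std[std == 0].index.tolist()
    if zero:
        raise ConstantColumnError(f"constant column(s): {zero}")
    return (df - df.mean()) / std


def pca(z_matrix: pd.DataFrame) -> PcaResult:
    """Eigendecomposition of the correlation matrix of a standardized matrix.

    Loadings are eigenvectors scaled by the square root of their eigenvalue,
    i.e. correlations between the original variables and the components.
    Each component's sign is fixed so its largest-magnitude loading is
    positive.  Components beyond the matrix rank get a zero variance
    fraction and set the ``rank_deficient`` flag.
    """
    z = z_matrix.astype(float)
    n, m = z.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    rank_deficient = bool((eigval < 1e-10).any())
    eigval = np.clip(eigval, 0.0, None)

    loadings = eigvec * np.sqrt(eigval)
    for j in range(m):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            eigvec[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(m)]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comp_names),
        variance_fraction=eigval / eigval.sum(),
        scores=pd.DataFrame(z.to_numpy() @ eigvec, index=z.index, columns=comp_names),
        rank_deficient=rank_deficient,
    )


def kmeans(
    z_matrix: pd.DataFrame,
    k: int = 2,
    seed: int = DEFAULT_KMEANS_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
) -> pd.Series:
    """Lloyd k-means on standardized rows; best of ``n_restarts`` by within-
    cluster sum of squares, deterministic given ``seed``.

    Group ids are renumbered 1..k in order of first appearance down the rows
    so that labels are stable across runs.
    """
    if k > len(z_matrix):
        raise ValueError(f"k = {k} exceeds the number of rows {len(z_matrix)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    raw = km.fit_predict(z_matrix.to_numpy(float))
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return pd.Series([relabel[lab] for lab in raw], index=z_matrix.index,
                     name="group")


def group_means(
    raw_matrix: pd.DataFrame,
    assignments: pd.Series,
    variables: list[str] | None = None,
    ndigits: int = 2,
) -> GroupingResult:
    """Per-group arithmetic means on the raw scale with Welch-test markers.

    Means are rounded half-up to ``ndigits`` decimals for reporting.  The
    two-group significance marker per variable comes from Welch's t test
    (single-observation groups are reported as ns).
    """
    variables = list(variables) if variables is not None else list(raw_matrix.columns)
    groups = sorted(assignments.unique())
    if any((assignments == g).sum() < 1 for g in groups):
        raise ValueError("every group needs at least one row")

    means = pd.DataFrame(index=variables,
                         columns=[f"group_{g}" for g in groups], dtype=float)
    markers: dict[str, str] = {}
    p_values: dict[str, float] = {}
    for var in variables:
        per_group = []
        for g in groups:
            vals = raw_matrix.loc[assignments[assignments == g].index, var].dropna()
            means.loc[var, f"group_{g}"] = round_half_up(float(vals.mean()), ndigits)
            per_group.append(vals.to_numpy(float))
        if len(groups) == 2 and all(len(v) > 1 for v in per_group) and (
            np.ptp(np.concatenate(per_group)) > 0
        ):
            p = float(sps.ttest_ind(per_group[0], per_group[1], equal_var=False).pvalue)
        else:
            p = float("nan")
        p_values[var] = p
        markers[var] = significance_marker(p)

    return GroupingResult(assignments=assignments, group_means=means,
                          markers=markers, p_values=p_values)
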