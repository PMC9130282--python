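"""Environmental covariates: the Selyaninov hydrothermal coefficient and
USDA soil-texture classification.

The hydrothermal coefficient summarizes moisture supply over a growing
period as ``K = 10 * P / t`` where ``P`` is the precipitation total (mm) and
``t`` the sum of daily mean air temperatures (degC) over the same records;
the selection is conventionally restricted to months with mean temperature
above 0 degC (here the autumn and spring-summer windows of a winter-cereal
season).  Season labels follow the temperate-climate reading of K, with the
moderately-dry band split at 1.0 into "dry" and "relatively dry":

    K <= 1.0        dry
    1.0 < K < 1.3   relatively dry
    1.3 <= K <= 1.6 optimal
    K > 1.6         humid

Boundary membership (1.0 to "dry", 1.6 to "optimal") is a convention of this
package chosen for internal consistency of the packaged season table; it is
flagged as derived in :data:`K_BANDS_DERIVED`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up

#: the 1.0 dry / relatively-dry cut and the band-edge memberships are
#: reverse-engineered, not taken from a published definition
K_BANDS_DERIVED = True

K_LABELS = ("dry", "relatively_dry", "optimal", "humid")

TEXTURE_CLASSES = (
    "sand", "loamy sand", "sandy loam", "loam", "silt loam", "silt",
    "sandy clay loam", "clay loam", "silty clay loam", "sandy clay",
    "silty clay", "clay",
)


class UndefinedKError(ValueError):
    """K is undefined because the temperature sum is not positive."""


class CompositionError(ValueError):
    """A particle-size composition does not sum to ~100%."""


@dataclass
class HydrothermalResult:
    k: float
    precip_total_mm: float
    temp_sum_degc: float
    months_used: list[int]
    label: str


def hydrothermal_k(
    weather: pd.DataFrame,
    months: Sequence[int] = (10, 11, 4, 5, 6, 7),
) -> HydrothermalResult:
    """Hydrothermal coefficient over the selected months of a weather series.

    Parameters
    ----------
    weather
        Daily (or coarser) records with columns ``date``, ``precip_mm`` and
        ``tmean_c``; sums are associative, so splitting a month into days
        does not change K.
    months
        Calendar months to include (default: Oct-Nov and Apr-Jul, the
        above-zero window of a winter-cereal season).
    """
    if not len(months):
        raise ValueError("month selection is empty")
    dates = pd.to_datetime(weather["date"])
    sel = weather[dates.dt.month.isin(list(months))]
    if sel.empty:
        raise ValueError("no weather records in the selected months")
    p = float(sel["precip_mm"].sum())
    t = float(sel["tmean_c"].sum())
    if t <= 0:
        raise UndefinedKError(f"temperature sum {t:.1f} degC is not positive")
    k = 10.0 * p / t
    return HydrothermalResult(
        k=k,
        precip_total_mm=p,
        temp_sum_degc=t,
        months_used=sorted(set(int(m) for m in months)),
        label=classify_k(k),
    )


def classify_k(k: float) -> str:
    """Season moisture label for a hydrothermal coefficient value."""
    if k < 0:
        raise ValueError(f"K must be >= 0, got {k}")
    if k <= 1.0:
        return "dry"
    if k < 1.3:
        return "relatively_dry"
    if k <= 1.6:
        return "optimal"
    return "humid"


def classify_texture(sand_pct: float, silt_pct: float, clay_pct: float) -> str:
    """USDA 12-class texture-triangle assignment of a sand/silt/clay composition.

    Fractions must be non-negative and sum to within [99, 101] (they are
    renormalized to 100).  Compositions are rounded to the nearest whole
    percent before the class rules are applied, matching the reporting
    precision of routine particle-size analyses; this makes near-boundary
    lab values land in the class a soil surveyor would assign.
    """
    if min(sand_pct, silt_pct, clay_pct) < 0:
        raise CompositionError("particle fractions must be >= 0")
    total = sand_pct + silt_pct + clay_pct
    if not (99.0 <= total <= 101.0):
        raise CompositionError(f"sand+silt+clay = {total:.2f} outside [99, 101]")
    sand = round_half_up(sand_pct * 100.0 / total, 0)
    silt = round_half_up(silt_pct * 100.0 / total, 0)
    clay = round_half_up(clay_pct * 100.0 / total, 0)

    if silt + 1.5 * clay < 15:
        return "sand"
    if silt + 2.0 * clay < 30:
        return "loamy sand"
    if clay >= 40 and silt >= 40:
        return "silty clay"
    if clay >= 40 and sand <= 45:
        return "clay"
    if clay >= 35 and sand > 45:
        return "sandy clay"
    if clay >= 27 and sand <= 20:
        return "silty clay loam"
    if 27 <= clay < 40 and sand <= 45:
        return "clay loam"
    if 20 <= clay < 35 and silt < 28 and sand > 45:
        return "sandy clay loam"
    if silt >= 80 and clay < 12:
        return "silt"
    if silt >= 50:
        return "silt loam"
    if 7 <= clay < 27 and 28 <= silt < 50 and sand <= 52:
        return "loam"
    return "sandy loam"


def classify_sites(
    soils: Iterable, k_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Texture class per site plus (optionally) K labels per site x season."""
    rows = []
    for env in soils:
        texture = classify_texture(env.sand_pct, env.silt_pct, env.clay_pct)
        base = {
            "site_id": env.site_id,
            "sand_pct": env.sand_pct,
            "silt_pct": env.silt_pct,
            "clay_pct": env.clay_pct,
            "texture": texture,
        }
        seasons = env.k_by_season or {}
        if k_table is not None:
            sub = k_table[k_table["site_id"] == env.site_id]
            seasons = dict(zip(sub["season"], sub["k"]))
        if seasons:
            for season, k in seasons.items():
                rows.append({**base, "season": season, "k": k, "k_label": classify_k(k)})
        else:
            rows.append(base)
    return pd.DataFrame(rows)
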