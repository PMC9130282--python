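"""Replacement-series competition indices.

For a two-component de Wit replacement series sown at constant total density,
the relative yield of a component sown at fraction ``p`` is its per-plant
performance in mixture relative to its own monoculture, scaled by ``p``:

    RY_a = p * (mix_per_plant_a / mono_per_plant_a)
    RY_b = (1 - p) * (mix_per_plant_b / mono_per_plant_b)
    TRY  = RY_a + RY_b

Under no competition each RY falls on the straight line RY = sown fraction
and TRY = 1.  The competitive ratio of the component in the numerator is the
Willey-Rao index

    CR = (RY_num / RY_den) * ((1 - p_num) / p_num)

oriented so that CR > 1 means the numerator component is the stronger
competitor.  Field convention for this design: the biotype-biotype ratio BCR
takes the susceptible biotype as numerator (BCR > 1: S out-competes R), the
wheat-blackgrass ratio WBCR takes wheat (WBCR > 1: wheat out-competes B);
both are computed on a fresh-biomass and a grain-number basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PotObservation, SERIES_COMPONENTS

BASES = {"fresh_biomass_g": "biomass", "grain_count": "grain_number"}


class InconsistentPotError(ValueError):
    """A pot records positive yield with zero plants."""


class UndefinedRelativeYieldError(ValueError):
    """A monoculture per-plant value of zero makes RY undefined."""


class MissingMonocultureError(ValueError):
    """A series lacks the monoculture of one of its components."""


@dataclass
class RelativeYieldPoint:
    proportion_a: float
    ry_a: float
    ry_b: float

    @property
    def try_total(self) -> float:
        return self.ry_a + self.ry_b


@dataclass
class CompetitiveRatio:
    value: float
    numerator_component: str
    basis: str
    proportion_numerator: float
    complete_dominance: bool = False


def per_plant(value_per_pot: float, n_plants: int) -> float:
    """Per-plant mean of a per-pot total; 0/0 is 0 with a warning."""
    if n_plants == 0:
        if value_per_pot == 0:
            warnings.warn("0 yield over 0 plants treated as 0 per plant",
                          stacklevel=2)
            return 0.0
        raise InconsistentPotError(
            f"positive per-pot value {value_per_pot} with n_plants = 0"
        )
    if n_plants < 0:
        raise ValueError("n_plants must be >= 0")
    return value_per_pot / n_plants


def relative_yield(mix_per_plant: float, mono_per_plant: float, p: float) -> float:
    """Relative yield of the component sown at fraction ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0.0:
        return 0.0
    if mono_per_plant <= 0:
        raise UndefinedRelativeYieldError(
            "monoculture per-plant value must be > 0 to define RY"
        )
    return p * (mix_per_plant / mono_per_plant)


def total_relative_yield(ry_a: float, ry_b: float) -> float:
    if ry_a < 0 or ry_b < 0:
        raise ValueError("relative yields must be >= 0")
    return ry_a + ry_b


def competitive_ratio(
    ry_num: float,
    ry_den: float,
    p_num: float,
    numerator_component: str = "a",
    basis: str = "biomass",
) -> CompetitiveRatio:
    """Willey-Rao competitive ratio of the numerator component.

    A zero denominator RY marks complete dominance of the numerator
    component; the result carries an infinite sentinel value and the
    ``complete_dominance`` flag instead of raising, so callers can exclude
    it from means while still reporting it.
    """
    if not (0.0 < p_num < 1.0):
        raise ValueError(f"p_num must be in (0, 1), got {p_num}")
    if ry_num < 0 or ry_den < 0:
        raise ValueError("relative yields must be >= 0")
    if ry_den == 0:
        return CompetitiveRatio(
            value=math.inf,
            numerator_component=numerator_component,
            basis=basis,
            proportion_numerator=p_num,
            complete_dominance=True,
        )
    value = (ry_num / ry_den) * ((1.0 - p_num) / p_num)
    return CompetitiveRatio(
        value=value,
        numerator_component=numerator_component,
        basis=basis,
        proportion_numerator=p_num,
    )


# ---------------------------------------------------------------------------
# series-level computation


def _per_plant_map(
    observations: Iterable[PotObservation], value_field: str
) -> dict[tuple[float, int, str], float]:
    """(proportion_a, replicate, component) -> per-plant value."""
    out = {}
    for o in observations:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[(round(o.proportion_a, 6), o.replicate, o.component)] = per_plant(
                getattr(o, value_field), o.n_plants
            )
    return out


def series_indices(
    observations: Sequence[PotObservation],
    monocultures: Sequence[PotObservation] | None = None,
    bases: Sequence[str] = ("fresh_biomass_g", "grain_count"),
) -> pd.DataFrame:
    """Relative yields, TRY and competitive ratios for one site x season x series.

    One row per mixed proportion x replicate x basis.  Monoculture per-plant
    denominators are replicate-matched (randomized-block pairing) when the
    monoculture replicate exists, otherwise the replicate mean is used.  The
    biotype-biotype series is sown only at mixed proportions; its blackgrass
    monocultures come from the wheat-blackgrass series at the same site and
    are passed via ``monocultures``.

    Raises :class:`MissingMonocultureError` when either component has no
    monoculture pots at all.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    keys = {(o.site_id, o.season, o.series) for o in obs}
    if len(keys) != 1:
        raise ValueError(f"observations span several series: {sorted(keys)}")
    site_id, season, series = keys.pop()
    comp_a, comp_b = SERIES_COMPONENTS[series]

    mono_pool = list(monocultures) if monocultures else []
    rows = []
    for value_field in bases:
        basis = BASES.get(value_field, value_field)
        pp = _per_plant_map(obs, value_field)

        # monoculture per-plant values per component per replicate
        mono: dict[str, dict[int, float]] = {comp_a: {}, comp_b: {}}
        for (p, rep, comp), v in pp.items():
            if comp == comp_a and p == 1.0:
                mono[comp_a][rep] = v
            elif comp == comp_b and p == 0.0:
                mono[comp_b][rep] = v
        for o in mono_pool:
            if o.component not in (comp_a, comp_b):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = per_plant(getattr(o, value_field), o.n_plants)
            mono[o.component].setdefault(o.replicate, v)
        for comp in (comp_a, comp_b):
            if not mono[comp]:
                raise MissingMonocultureError(
                    f"{site_id} {season} {series}: no monoculture of {comp}"
                )

        mono_mean = {c: float(np.mean(list(mono[c].values()))) for c in mono}

        mixed = sorted({p for (p, _, c) in pp if 0.0 < p < 1.0})
        reps = sorted({rep for (p, rep, c) in pp if 0.0 < p < 1.0})
        for p in mixed:
            for rep in reps:
                if (p, rep, comp_a) not in pp or (p, rep, comp_b) not in pp:
                    continue
                den_a = mono[comp_a].get(rep, mono_mean[comp_a])
                den_b = mono[comp_b].get(rep, mono_mean[comp_b])
                ry_a = relative_yield(pp[(p, rep, comp_a)], den_a, p)
                ry_b = relative_yield(pp[(p, rep, comp_b)], den_b, 1.0 - p)
                cr = competitive_ratio(ry_a, ry_b, p, comp_a, basis)
                rows.append(
                    {
                        "site_id": site_id,
                        "season": season,
                        "series": series,
                        "basis": basis,
                        "proportion_a": p,
                        "replicate": rep,
                        "ry_a": ry_a,
                        "ry_b": ry_b,
                        "try_total": ry_a + ry_b,
                        "cr_value": np.nan if cr.complete_dominance else cr.value,
                        "cr_numerator": comp_a,
                        "cr_dominance": cr.complete_dominance,
                    }
                )
    return pd.DataFrame(rows)


def summarize_indices(indices: pd.DataFrame) -> pd.DataFrame:
    """Replicate x mixed-proportion mean +/- standard error of the competitive
    ratio per site x season x series x basis (dominance sentinels excluded)."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        vals = g.loc[~g["cr_dominance"], "cr_value"].dropna()
        n = len(vals)
        return pd.Series(
            {
                "cr_mean": vals.mean() if n else np.nan,
                "cr_se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
                "n_dominance": int(g["cr_dominance"].sum()),
            }
        )

    grouped = (
        indices.groupby(["site_id", "season", "series", "basis"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    grouped["n"] = grouped["n"].astype(int)
    grouped["n_dominance"] = grouped["n_dominance"].astype(int)
    return grouped


def mean_ry_curve(indices: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged RY / TRY per mixed proportion (one series x basis)."""
    return (
        indices.groupby("proportion_a")[["ry_a", "ry_b", "try_total"]]
        .mean()
        .reset_index()
    )
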