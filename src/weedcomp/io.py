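"""Domain types, validation and file I/O for replacement-series competition data.

The central record is the :class:`PotObservation`: one pot x component
measurement from a de Wit replacement series, in which two components (winter
wheat and a blackgrass biotype, or the two blackgrass biotypes) are sown at a
constant total density while their proportions vary.  Per-pot raw values are
stored; per-plant values are always derived downstream, never stored, so that
normalization happens exactly once.

Dates in interchange files are ISO-8601; the packaged fixture loader
(:mod:`weedcomp.fixtures`) additionally accepts the dotted DD.MM.YYYY notation
used in agronomic field tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

SERIES_TYPES = ("BB", "WB_R", "WB_S")
COMPONENTS = ("wheat", "blackgrass_R", "blackgrass_S")

#: sown proportions of component A allowed per series design
WB_PROPORTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
BB_PROPORTIONS = (0.4, 0.6)

#: component A is the one whose competitive-ratio numerator the field
#: convention fixes: the susceptible biotype in the biotype-biotype series
#: (BCR > 1 means S out-competes R) and wheat in the wheat-blackgrass series
#: (WBCR > 1 means wheat out-competes blackgrass).
SERIES_COMPONENTS: dict[str, tuple[str, str]] = {
    "BB": ("blackgrass_S", "blackgrass_R"),
    "WB_R": ("wheat", "blackgrass_R"),
    "WB_S": ("wheat", "blackgrass_S"),
}

POT_COLUMNS = [
    "site_id", "season", "series", "proportion_a", "replicate", "component",
    "n_plants", "fresh_biomass_g", "grain_count",
]
POT_OPTIONAL_COLUMNS = ["height_cm", "tgw_g"]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class PotDataError(ValueError):
    """One or more rows violate the pot-observation invariants."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid pot observations:\n" + "\n".join(self.problems))


class DateFormatError(ValueError):
    """A date string could not be parsed."""


@dataclass
class PotObservation:
    """One pot x component record from a replacement-series experiment."""

    site_id: str
    season: str
    series: str
    proportion_a: float
    replicate: int
    component: str
    n_plants: int
    fresh_biomass_g: float
    grain_count: float
    height_cm: float | None = None
    tgw_g: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        issues: list[str] = []
        if self.series not in SERIES_TYPES:
            issues.append(f"unknown series {self.series!r}")
        else:
            allowed = BB_PROPORTIONS if self.series == "BB" else WB_PROPORTIONS
            if not any(abs(self.proportion_a - p) < 1e-9 for p in allowed):
                issues.append(
                    f"proportion_a={self.proportion_a} not in {allowed} "
                    f"for series {self.series}"
                )
        if self.component not in COMPONENTS:
            issues.append(f"unknown component {self.component!r}")
        if self.replicate < 1:
            issues.append(f"replicate must be >= 1, got {self.replicate}")
        if self.n_plants < 0:
            issues.append(f"n_plants must be >= 0, got {self.n_plants}")
        if self.fresh_biomass_g < 0:
            issues.append(f"fresh_biomass_g must be >= 0, got {self.fresh_biomass_g}")
        if self.grain_count < 0:
            issues.append(f"grain_count must be >= 0, got {self.grain_count}")
        if self.n_plants == 0 and (self.fresh_biomass_g > 0 or self.grain_count > 0):
            issues.append("positive yield recorded in a pot with n_plants = 0")
        return issues


@dataclass
class SiteEnvironment:
    """Soil composition, texture and per-season hydrothermal conditions of a site."""

    site_id: str
    latitude: str | float | None = None
    longitude: str | float | None = None
    sand_pct: float = 0.0
    silt_pct: float = 0.0
    clay_pct: float = 0.0
    n_pct: float | None = None
    p_mgkg: float | None = None
    k_mgkg: float | None = None
    om_pct: float | None = None
    ph: float | None = None
    texture_label: str | None = None
    k_by_season: dict[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        issues = []
        total = self.sand_pct + self.silt_pct + self.clay_pct
        if not (99.0 <= total <= 101.0):
            issues.append(f"sand+silt+clay = {total:.2f} outside [99, 101]")
        for name in ("sand_pct", "silt_pct", "clay_pct"):
            if getattr(self, name) < 0:
                issues.append(f"{name} must be >= 0")
        return issues


@dataclass
class EventCalendar:
    """Sowing, emergence and harvest dates for one site x season."""

    site_id: str
    season: str
    sowing_date: dt.date | None = None
    wheat_emergence_date: dt.date | None = None
    blackgrass_emergence_date: dt.date | None = None
    harvest_date: dt.date | None = None

    def validate(self) -> list[str]:
        issues = []
        if (
            self.sowing_date is not None
            and self.wheat_emergence_date is not None
            and self.sowing_date > self.wheat_emergence_date
        ):
            issues.append("sowing after wheat emergence")
        if (
            self.wheat_emergence_date is not None
            and self.harvest_date is not None
            and self.wheat_emergence_date > self.harvest_date
        ):
            issues.append("wheat emergence after harvest")
        return issues


@dataclass
class GeneScreenInput:
    """A template sequence plus the reference frame needed to screen it."""

    gene: str
    template_seq: str
    reference_cds: str
    numbering_offset: int
    primer_fwd: str
    primer_rev: str

    def validate(self) -> list[str]:
        issues = []
        if self.gene not in ("ALS", "ACCase"):
            issues.append(f"unknown gene {self.gene!r}")
        if len(self.reference_cds) % 3 != 0:
            issues.append("reference_cds length not divisible by 3")
        for name in ("primer_fwd", "primer_rev"):
            p = getattr(self, name)
            if not p or set(p.upper()) - set("ACGT"):
                issues.append(f"{name} empty or not plain ACGT")
        return issues


# ---------------------------------------------------------------------------
# date arithmetic


def parse_date(value: str | dt.date | dt.datetime, dotted: bool = False) -> dt.date:
    """Parse an ISO-8601 date (or DD.MM.YYYY when ``dotted``)."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    try:
        if dotted:
            return dt.datetime.strptime(text, "%d.%m.%Y").date()
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise DateFormatError(f"unparseable date {text!r}") from exc


def days_between(d1: str | dt.date, d2: str | dt.date) -> int:
    """Exact calendar-day difference ``d2 - d1`` (negative when d2 is earlier).

    Pure calendar arithmetic: no timezone or daylight-saving effects.
    """
    return (parse_date(d2) - parse_date(d1)).days


def phenology_intervals(cal: EventCalendar) -> dict[str, int | None]:
    """Days from sowing to wheat emergence and the blackgrass emergence delay.

    Missing dates propagate as ``None`` (absent, never silently 0).
    """
    d2w = None
    if cal.sowing_date is not None and cal.wheat_emergence_date is not None:
        d2w = days_between(cal.sowing_date, cal.wheat_emergence_date)
    delay = None
    if cal.wheat_emergence_date is not None and cal.blackgrass_emergence_date is not None:
        delay = days_between(cal.wheat_emergence_date, cal.blackgrass_emergence_date)
    return {"days_to_wheat_emergence": d2w, "blackgrass_delay_days": delay}


# ---------------------------------------------------------------------------
# CSV readers / writers


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_pot_observations(path) -> list[PotObservation]:
    """Read a tidy pot-observation CSV.

    Every row is parsed; rows that fail type conversion or invariant checks
    are collected and reported together (with 1-based data row numbers) in a
    :class:`PotDataError`.  An empty file with a valid header yields an empty
    list.
    """
    df = pd.read_csv(path)
    _check_columns(df, POT_COLUMNS, "pot observations")
    problems: list[str] = []
    out: list[PotObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            obs = PotObservation(
                site_id=str(row.site_id),
                season=str(row.season),
                series=str(row.series),
                proportion_a=float(row.proportion_a),
                replicate=int(row.replicate),
                component=str(row.component),
                n_plants=int(row.n_plants),
                fresh_biomass_g=float(row.fresh_biomass_g),
                grain_count=float(row.grain_count),
                height_cm=_opt_float(getattr(row, "height_cm", None)),
                tgw_g=_opt_float(getattr(row, "tgw_g", None)),
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        issues = obs.validate()
        if issues:
            problems.extend(f"row {i}: {msg}" for msg in issues)
        else:
            out.append(obs)
    if problems:
        raise PotDataError(problems)
    return out


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def write_pot_observations(observations: Iterable[PotObservation], path) -> None:
    """Write pot observations to CSV (round-trips with :func:`read_pot_observations`)."""
    cols = [f.name for f in fields(PotObservation)]
    df = pd.DataFrame([{c: getattr(o, c) for c in cols} for o in observations],
                      columns=cols)
    df.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    """Read a daily weather CSV: date, precip_mm, tmean_c (+ optional site_id, season)."""
    df = pd.read_csv(path)
    _check_columns(df, ["date", "precip_mm", "tmean_c"], "weather")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_soils(path) -> list[SiteEnvironment]:
    """Read a site soil table CSV (schema of the packaged soils fixture)."""
    df = pd.read_csv(path)
    _check_columns(df, ["site_id", "sand_pct", "silt_pct", "clay_pct"], "soils")
    sites = []
    for row in df.to_dict("records"):
        env = SiteEnvironment(
            site_id=str(row["site_id"]),
            latitude=row.get("latitude"),
            longitude=row.get("longitude"),
            sand_pct=float(row["sand_pct"]),
            silt_pct=float(row["silt_pct"]),
            clay_pct=float(row["clay_pct"]),
            n_pct=_opt_float(row.get("n_pct")),
            p_mgkg=_opt_float(row.get("p_mgkg")),
            k_mgkg=_opt_float(row.get("k_mgkg")),
            om_pct=_opt_float(row.get("om_pct")),
            ph=_opt_float(row.get("ph")),
            texture_label=row.get("texture_printed") or row.get("texture_label"),
        )
        issues = env.validate()
        if issues:
            raise PotDataError([f"site {env.site_id}: {m}" for m in issues])
        sites.append(env)
    return sites


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
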