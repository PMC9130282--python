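"""Packaged reference tables for the seven-site Polish field trial.

These small fixtures carry the published site metadata the analysis needs
without the (unreleased) raw pot data: soil composition and texture labels,
per-season hydrothermal coefficients with their printed season labels, the
sowing/emergence/harvest calendar (including the day counts as printed, which
occasionally disagree with their own dates), the PCR primer pairs for the ALS
and ACCase screens, and the greenhouse dose-response ratings kept as metadata.

Dates in the calendar fixture use the dotted DD.MM.YYYY field-notebook
notation; they are parsed here and exposed as proper dates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .io import EventCalendar, SiteEnvironment, parse_date, phenology_intervals

#: k-means site grouping reported for the trait + environment matrix
#: (group 1: sandy, drier sites; group 2: heavier, moister sites).
GROUP1_SITES = ("Lipnik", "Mochełek", "Winna Góra", "Swojczyce")
GROUP2_SITES = ("Czesławice", "Wrocław", "Mydlniki")


def _data_path(name: str):
    return resources.files("weedcomp").joinpath("data", name)


def soil_table() -> pd.DataFrame:
    """Site coordinates, particle-size fractions, texture labels and chemistry."""
    return pd.read_csv(_data_path("soils.csv"))


def site_environments() -> list[SiteEnvironment]:
    """Soil table joined with per-season hydrothermal coefficients."""
    from .io import read_soils

    sites = read_soils(_data_path("soils.csv"))
    k = hydrothermal_table()
    for env in sites:
        rows = k[k["site_id"] == env.site_id]
        env.k_by_season = dict(zip(rows["season"], rows["k"]))
    return sites


def hydrothermal_table() -> pd.DataFrame:
    """Per-site, per-season hydrothermal coefficient K with printed labels."""
    return pd.read_csv(_data_path("hydrothermal.csv"))


def event_table() -> pd.DataFrame:
    """Calendar fixture with printed day counts, dates parsed to ``datetime.date``."""
    df = pd.read_csv(_data_path("events.csv"))
    for col in ("sowing_date", "harvest_date", "wheat_emergence_date",
                "blackgrass_emergence_date"):
        df[col] = df[col].map(lambda v: parse_date(v, dotted=True))
    return df


def event_calendars() -> list[EventCalendar]:
    return [
        EventCalendar(
            site_id=row.site_id,
            season=row.season,
            sowing_date=row.sowing_date,
            wheat_emergence_date=row.wheat_emergence_date,
            blackgrass_emergence_date=row.blackgrass_emergence_date,
            harvest_date=row.harvest_date,
        )
        for row in event_table().itertuples(index=False)
    ]


def phenology_report() -> pd.DataFrame:
    """Derived phenology intervals next to the printed values, with flags.

    The packaged calendar stores the printed dates; day counts are always
    recomputed from them.  Where a printed count disagrees with its own dates
    the row is flagged rather than silently matched — several such internal
    inconsistencies exist in the source tables.
    """
    rows = []
    for row in event_table().itertuples(index=False):
        cal = EventCalendar(
            site_id=row.site_id,
            season=row.season,
            sowing_date=row.sowing_date,
            wheat_emergence_date=row.wheat_emergence_date,
            blackgrass_emergence_date=row.blackgrass_emergence_date,
            harvest_date=row.harvest_date,
        )
        derived = phenology_intervals(cal)
        rows.append(
            {
                "site_id": row.site_id,
                "season": row.season,
                "days_to_wheat_emergence": derived["days_to_wheat_emergence"],
                "printed_days_to_wheat": row.printed_days_to_wheat,
                "blackgrass_delay_days": derived["blackgrass_delay_days"],
                "printed_blackgrass_delay": row.printed_blackgrass_delay,
                "days_to_wheat_flag": derived["days_to_wheat_emergence"]
                != row.printed_days_to_wheat,
                "delay_flag": derived["blackgrass_delay_days"]
                != row.printed_blackgrass_delay,
            }
        )
    return pd.DataFrame(rows)


def primer_table() -> pd.DataFrame:
    """PCR primer pairs, product sizes and annealing temperatures per gene."""
    return pd.read_csv(_data_path("primers.csv"))


def dose_response_table() -> pd.DataFrame:
    """Greenhouse ED50 resistance ratings of the two biotypes (metadata only)."""
    return pd.read_csv(_data_path("dose_response.csv"))


def gene_config(path=None) -> dict:
    """Gene screen configuration: offsets, canonical codons, known resistance positions."""
    source = path if path is not None else _data_path("genes.yaml")
    with open(source) as fh:
        return yaml.safe_load(fh)


def known_resistance_table(path=None) -> dict[str, dict[int, list[str]]]:
    """gene -> {standard position: [resistance-conferring replacement residues]}."""
    cfg = gene_config(path)
    return {
        gene: {int(pos): list(alts) for pos, alts in spec["known_resistance_positions"].items()}
        for gene, spec in cfg.items()
    }
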