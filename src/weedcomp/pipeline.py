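"""End-to-end orchestration: indices -> model classification -> environment ->
associations -> multivariate grouping, with CSV report tables and a
machine-readable run summary."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_indices
from .environment import classify_sites, hydrothermal_k
from .grouping import DEFAULT_KMEANS_SEED, DEFAULT_RESTARTS, group_means, kmeans, pca, standardize
from .indices import MissingMonocultureError, series_indices, summarize_indices
from .io import SERIES_COMPONENTS, read_pot_observations, read_soils, read_weather
from .stats import UnbalancedDesignError, balanced_anova, pearson_r

log = logging.getLogger("weedcomp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    pots_path: str
    out_dir: str
    weather_path: str | None = None
    soils_path: str | None = None
    alpha: float = 0.05
    k_clusters: int = 2
    seed: int = DEFAULT_KMEANS_SEED
    n_restarts: int = DEFAULT_RESTARTS
    months: tuple = (10, 11, 4, 5, 6, 7)
    ndigits: int = 2
    known_resistance_path: str | None = None

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("pots_path", "weather_path", "soils_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} not found")


def _wheat_trait_rows(pots_df: pd.DataFrame) -> pd.DataFrame:
    """Per site x season x biotype-mixture wheat trait means over mixed pots."""
    wheat = pots_df[
        (pots_df["component"] == "wheat")
        & (pots_df["proportion_a"] > 0)
        & (pots_df["proportion_a"] < 1)
    ].copy()
    wheat["length"] = wheat["height_cm"]
    wheat["biomass"] = wheat["fresh_biomass_g"] / wheat["n_plants"]
    wheat["seed_number"] = wheat["grain_count"] / wheat["n_plants"]
    wheat["tgw"] = wheat["tgw_g"]
    wheat["seed_yield"] = wheat["seed_number"] * wheat["tgw_g"] / 1000.0
    agg = (
        wheat.groupby(["site_id", "season", "series"])[
            ["length", "seed_yield", "tgw", "biomass", "seed_number"]
        ]
        .mean()
        .reset_index()
    )
    agg["biotype"] = agg["series"].map({"WB_R": "R", "WB_S": "S"})
    return agg.drop(columns="series")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all report tables.

    Returns the machine-readable summary (also written as summary.json).
    Any stage failure aborts with a stage-scoped :class:`PipelineError`;
    partial outputs written before the failure are recorded in
    ``partial_outputs.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "k_clusters": config.k_clusters,
        "months": list(config.months),
        "decisions": {
            "ry_scale_for_chi2": "percent",
            "k_band_edges": "K<=1.0 dry; <1.3 relatively_dry; <=1.6 optimal; else humid",
            "texture_rounding": "whole-percent before USDA rules",
            "ratio_aggregation": "per replicate then averaged",
        },
        "stages": {},
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(name)

    def _fail(stage: str, message: str):
        (out / "partial_outputs.json").write_text(
            json.dumps({"completed": written, "failed_stage": stage}, indent=2)
        )
        raise PipelineError(stage, message)

    # stage 1: indices ------------------------------------------------------
    log.info("stage indices: reading %s", config.pots_path)
    try:
        pots = read_pot_observations(config.pots_path)
    except Exception as exc:
        _fail("indices", str(exc))
    pots_df = pd.DataFrame([vars(o) for o in pots])

    groups: dict[tuple, list] = {}
    for o in pots:
        groups.setdefault((o.site_id, o.season, o.series), []).append(o)
    mono_pool: dict[tuple, list] = {}
    for o in pots:
        if o.series in ("WB_R", "WB_S") and o.proportion_a == 0.0:
            mono_pool.setdefault((o.site_id, o.season), []).append(o)

    frames, skipped = [], []
    for (site, season, series), obs in sorted(groups.items()):
        monos = mono_pool.get((site, season), []) if series == "BB" else None
        try:
            frames.append(series_indices(obs, monocultures=monos))
        except MissingMonocultureError as exc:
            skipped.append({"site_id": site, "season": season,
                            "series": series, "reason": str(exc)})
    if not frames:
        _fail("indices", "no series could be computed")
    indices = pd.concat(frames, ignore_index=True)
    _write(indices, "indices.csv")
    _write(summarize_indices(indices), "indices_summary.csv")
    summary["stages"]["indices"] = {"n_rows": len(indices), "skipped": skipped}

    # stage 2: model classification ----------------------------------------
    try:
        models = classify_indices(indices, alpha=config.alpha)
    except Exception as exc:
        _fail("classification", str(exc))
    _write(models, "models.csv")
    summary["stages"]["classification"] = {
        "n_series": len(models),
        "label_counts": {str(k): int(v) for k, v
                         in models["model_label"].value_counts().items()},
    }

    # stage 3: environment --------------------------------------------------
    env_df = None
    if config.soils_path:
        try:
            soils = read_soils(config.soils_path)
            k_table = None
            if config.weather_path:
                wx = read_weather(config.weather_path)
                k_rows = []
                for (site, season), g in wx.groupby(["site_id", "season"]):
                    res = hydrothermal_k(g, months=config.months)
                    k_rows.append({"site_id": site, "season": season,
                                   "k": res.k, "k_label": res.label})
                k_table = pd.DataFrame(k_rows)
            env_df = classify_sites(soils, k_table)
        except Exception as exc:
            _fail("environment", str(exc))
        _write(env_df, "environment.csv")
        summary["stages"]["environment"] = {"n_rows": len(env_df)}

    # stage 4: associations -------------------------------------------------
    site_means = (
        indices[~indices["cr_dominance"]]
        .groupby(["site_id", "season", "series", "basis"])["cr_value"]
        .mean()
        .reset_index(name="cr_mean")
    )
    corr_rows = []
    if env_df is not None and "k" in env_df.columns:
        env_cov = env_df[["site_id", "season", "sand_pct", "k"]].drop_duplicates()
        merged = site_means.merge(env_cov, on=["site_id", "season"])
        for (season, series, basis), g in merged.groupby(["season", "series", "basis"]):
            for covariate in ("k", "sand_pct"):
                if len(g) < 3 or g[covariate].nunique() < 2 or g["cr_mean"].nunique() < 2:
                    continue
                res = pearson_r(g[covariate], g["cr_mean"])
                corr_rows.append({"season": season, "series": series,
                                  "basis": basis, "covariate": covariate,
                                  "r": res.r, "p": res.p_value, "n": res.n})
    corr = pd.DataFrame(corr_rows)
    _write(corr, "correlations.csv")

    anova_tables = {}
    per_rep = indices[~indices["cr_dominance"]].copy()
    per_rep["year"] = per_rep["season"]
    bb = per_rep[per_rep["series"] == "BB"]
    wb = per_rep[per_rep["series"].isin(["WB_R", "WB_S"])].copy()
    wb["biotype"] = wb["series"].str[-1]
    for name, (df, factors) in {
        "anova_bcr": (bb, ["year", "site_id"]),
        "anova_wbcr": (wb, ["year", "site_id", "biotype"]),
    }.items():
        for basis, g in df.groupby("basis"):
            try:
                table = balanced_anova(g, "cr_value", factors)
            except UnbalancedDesignError as exc:
                summary["stages"].setdefault("associations", {}).setdefault(
                    "anova_skipped", []
                ).append({"table": f"{name}_{basis}", "reason": str(exc)})
                continue
            anova_tables[f"{name}_{basis}"] = table
            _write(table, f"{name}_{basis}.csv")
    summary["stages"].setdefault("associations", {})["n_correlations"] = len(corr)
    summary["stages"]["associations"]["anova_tables"] = sorted(anova_tables)

    # stage 5: multivariate grouping ---------------------------------------
    grouping_summary = {}
    if env_df is not None and "k" in env_df.columns and "height_cm" in pots_df.columns:
        try:
            traits = _wheat_trait_rows(pots_df)
            env_cov = env_df[
                ["site_id", "season", "sand_pct", "silt_pct", "clay_pct", "k"]
            ].drop_duplicates()
            for season, tg in traits.groupby("season"):
                matrix = tg.merge(env_cov, on=["site_id", "season"])
                matrix = matrix.set_index(
                    matrix["site_id"] + " " + matrix["biotype"]
                )
                cols = ["sand_pct", "silt_pct", "clay_pct", "k",
                        "length", "seed_yield", "tgw", "biomass", "seed_number"]
                matrix = matrix[cols].dropna()
                if len(matrix) <= config.k_clusters:
                    continue
                z = standardize(matrix)
                pca_res = pca(z)
                assign = kmeans(z, k=config.k_clusters, seed=config.seed,
                                n_restarts=config.n_restarts)
                gm = group_means(matrix, assign, ndigits=config.ndigits)
                tag = season.replace("/", "-")
                _write(pca_res.loadings.reset_index(names="variable"),
                       f"pca_loadings_{tag}.csv")
                _write(assign.rename_axis("unit").reset_index(),
                       f"groups_{tag}.csv")
                gm_out = gm.group_means.reset_index(names="variable")
                gm_out["marker"] = gm_out["variable"].map(gm.markers)
                _write(gm_out, f"group_means_{tag}.csv")
                grouping_summary[season] = {
                    "variance_fraction_pc1": float(pca_res.variance_fraction[0]),
                    "variance_fraction_pc2": float(pca_res.variance_fraction[1]),
                    "group_sizes": {str(k): int(v) for k, v
                                    in assign.value_counts().items()},
                }
        except Exception as exc:
            _fail("grouping", str(exc))
    summary["stages"]["grouping"] = grouping_summary

    summary["outputs"] = written
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete: %d tables in %s", len(written), out)
    return summary


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
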