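"""Synthetic-data generators for every input the pipeline consumes.

Replacement-series pot data are generated from a reciprocal-yield
(hyperbolic) competition kernel: the per-plant yield of component ``i``
grown with ``N_i`` conspecifics and ``N_j`` heterospecifics in a pot is

    y_i = Y_i / (1 + b_ii * N_i + b_ij * N_j)

where ``Y_i`` is the intrinsic (crowding-free) per-plant yield and the
``b`` coefficients are per-plant crowding pressures.  Equal inter- and
intraspecific pressure reproduces the no-competition replacement-series
geometry exactly (RY = sown fraction, TRY = 1); asymmetric pressures give
the one-sided-benefit patterns; mild mutual facilitation (negative
interspecific coefficients, denominators bounded away from zero) inflates
TRY above 1; mutual antagonism depresses it below 1.  All five competition
model labels are therefore reachable by coefficient choice, and the
generating label is exposed as ground truth for recovery tests.

Measurement noise is multiplicative lognormal with mean 1 and a coefficient
of variation ``noise_cv`` (yields are positive and right-skewed).  Every
generator is fully deterministic given its seed.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import PotObservation, SERIES_COMPONENTS
from .markers import translate_codon

_STANDARD_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_BY_AA: dict[str, list[str]] = {}
for _codon in _STANDARD_CODONS:
    _BY_AA.setdefault(translate_codon(_codon), []).append(_codon)

#: coefficient presets that generate each of the five competition models
#: under the default design (documented in the methods note)
MODEL_PRESETS: dict[str, dict[str, float]] = {
    "I": dict(b_aa=0.15, b_ab=0.15, b_bb=0.15, b_ba=0.15),
    "IIa": dict(b_aa=0.15, b_ab=0.35, b_bb=0.30, b_ba=0.10),
    "IIb": dict(b_aa=0.30, b_ab=0.10, b_bb=0.15, b_ba=0.35),
    "III": dict(b_aa=0.15, b_ab=-0.05, b_bb=0.15, b_ba=-0.05),
    "IV": dict(b_aa=0.10, b_ab=0.40, b_bb=0.10, b_ba=0.40),
}

MIN_DENOMINATOR = 0.1  # facilitation bound: kernel denominators stay >= this


@dataclass
class SimulationParams:
    """Parameters of one simulated replacement series.

    Intrinsic per-plant yields are crowding-free: the monoculture per-plant
    yield at total density ``density`` is ``Y / (1 + b_ii * density)``.
    Defaults emulate a winter wheat x blackgrass pot series (10 plants per
    pot, six sowing proportions, three replicates, ~5% measurement CV).
    """

    site_id: str = "SIM"
    season: str = "2018/19"
    series: str = "WB_R"
    y_a_biomass: float = 50.0    # g/plant intrinsic (wheat-like)
    y_b_biomass: float = 25.0    # g/plant intrinsic (blackgrass-like)
    y_a_grain: float = 500.0     # grains/plant intrinsic
    y_b_grain: float = 1000.0
    b_aa: float = 0.15
    b_ab: float = 0.15
    b_bb: float = 0.15
    b_ba: float = 0.15
    density: int = 10
    proportions: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    height_a_cm: float = 70.0    # wheat plant length scale
    tgw_a_g: float = 42.0        # wheat thousand-grain weight scale

    def validate(self) -> None:
        if min(self.y_a_biomass, self.y_b_biomass, self.y_a_grain, self.y_b_grain) <= 0:
            raise ValueError("intrinsic yields must be > 0")
        if self.density < 1:
            raise ValueError("density must be a positive integer")
        if not (0.0 <= self.noise_cv < 1.0):
            raise ValueError("noise_cv must be in [0, 1)")
        if self.series not in SERIES_COMPONENTS:
            raise ValueError(f"unknown series {self.series!r}")
        for p in self.proportions:
            n_a = p * self.density
            if abs(n_a - round(n_a)) > 1e-9:
                raise ValueError(f"proportion {p} not realizable at density {self.density}")


def kernel_per_plant(y: float, b_self: float, b_other: float,
                     n_self: int, n_other: int) -> float:
    """Per-plant yield under the reciprocal-yield crowding kernel."""
    denom = max(1.0 + b_self * n_self + b_other * n_other, MIN_DENOMINATOR)
    return y / denom


def closed_form_ry(params: SimulationParams, p: float, component: str = "a",
                   basis: str = "biomass") -> float:
    """Noise-free relative yield of one component at sown fraction p (of A)."""
    d = params.density
    n_a, n_b = round(p * d), d - round(p * d)
    if component == "a":
        y = params.y_a_biomass if basis == "biomass" else params.y_a_grain
        mono = kernel_per_plant(y, params.b_aa, params.b_ab, d, 0)
        if n_a == 0:
            return 0.0
        mix = kernel_per_plant(y, params.b_aa, params.b_ab, n_a, n_b)
        return p * mix / mono
    y = params.y_b_biomass if basis == "biomass" else params.y_b_grain
    mono = kernel_per_plant(y, params.b_bb, params.b_ba, d, 0)
    if n_b == 0:
        return 0.0
    mix = kernel_per_plant(y, params.b_bb, params.b_ba, n_b, n_a)
    return (1.0 - p) * mix / mono


def closed_form_cr(params: SimulationParams, p: float,
                   basis: str = "biomass") -> float:
    """Noise-free competitive ratio (numerator = component A) at mixed p."""
    ry_a = closed_form_ry(params, p, "a", basis)
    ry_b = closed_form_ry(params, p, "b", basis)
    return (ry_a / ry_b) * ((1.0 - p) / p)


def implied_model_label(params: SimulationParams) -> str:
    """Competition-model label the coefficients generate (ground truth)."""
    da = params.b_ab - params.b_aa   # > 0: A suffers more in mixture
    db = params.b_ba - params.b_bb   # > 0: B suffers more in mixture
    if da == 0 and db == 0:
        return "I"
    if da <= 0 and db <= 0:
        return "III"
    if da >= 0 and db >= 0:
        return "IV"
    return "IIa" if da > 0 else "IIb"


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_series(params: SimulationParams) -> tuple[list[PotObservation], dict]:
    """Generate one replacement series plus its ground-truth record.

    Returns pot observations (per-pot totals, one row per pot x component
    actually sown) and a truth dict with the generating parameters, the
    implied model label and the noise-free RY curves.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    comp_a, comp_b = SERIES_COMPONENTS[params.series]
    d = params.density
    obs: list[PotObservation] = []
    for p in params.proportions:
        n_a = round(p * d)
        n_b = d - n_a
        for rep in range(1, params.replicates + 1):
            for comp, n, n_other, is_a in (
                (comp_a, n_a, n_b, True),
                (comp_b, n_b, n_a, False),
            ):
                if n == 0:
                    continue
                if is_a:
                    bm = kernel_per_plant(params.y_a_biomass, params.b_aa,
                                          params.b_ab, n, n_other)
                    gr = kernel_per_plant(params.y_a_grain, params.b_aa,
                                          params.b_ab, n, n_other)
                else:
                    bm = kernel_per_plant(params.y_b_biomass, params.b_bb,
                                          params.b_ba, n, n_other)
                    gr = kernel_per_plant(params.y_b_grain, params.b_bb,
                                          params.b_ba, n, n_other)
                noise = _lognormal_factor(rng, params.noise_cv, 2)
                extras = {}
                if comp == "wheat":
                    hn = _lognormal_factor(rng, params.noise_cv, 2)
                    extras = {
                        "height_cm": round(params.height_a_cm * hn[0], 1),
                        "tgw_g": round(params.tgw_a_g * hn[1], 2),
                    }
                obs.append(
                    PotObservation(
                        site_id=params.site_id,
                        season=params.season,
                        series=params.series,
                        proportion_a=p,
                        replicate=rep,
                        component=comp,
                        n_plants=n,
                        fresh_biomass_g=round(bm * n * noise[0], 4),
                        grain_count=round(gr * n * noise[1], 2),
                        **extras,
                    )
                )
    mixed = [p for p in params.proportions if 0.0 < p < 1.0]
    truth = {
        "params": params,
        "model_label": implied_model_label(params),
        "ry_curves": pd.DataFrame(
            {
                "proportion_a": mixed,
                "ry_a": [closed_form_ry(params, p, "a") for p in mixed],
                "ry_b": [closed_form_ry(params, p, "b") for p in mixed],
                "cr_biomass": [closed_form_cr(params, p, "biomass") for p in mixed],
                "cr_grain": [closed_form_cr(params, p, "grain") for p in mixed],
            }
        ),
    }
    return obs, truth


# ---------------------------------------------------------------------------
# weather


#: typical monthly mean temperatures (degC) for the above-zero window of a
#: Polish winter-cereal season, keyed by calendar month
DEFAULT_MONTH_TEMPS = {10: 9.0, 11: 4.0, 4: 9.0, 5: 13.0, 6: 17.0, 7: 19.0}


def monthly_spec_for_k(
    k_target: float,
    season: str = "2018/19",
    month_temps: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Monthly precipitation/temperature spec whose noise-free daily series
    recovers exactly the requested hydrothermal coefficient."""
    temps = month_temps or DEFAULT_MONTH_TEMPS
    first_year = int(season.split("/")[0])
    rows = []
    t_sum_total = 0.0
    for month, tmean in temps.items():
        year = first_year if month >= 8 else first_year + 1
        ndays = calendar.monthrange(year, month)[1]
        t_sum_total += tmean * ndays
        rows.append({"year": year, "month": month, "tmean_c": tmean, "ndays": ndays})
    p_total = k_target * t_sum_total / 10.0
    for row in rows:
        row["precip_mm"] = p_total * (row["tmean_c"] * row["ndays"]) / t_sum_total
        del row["ndays"]
    return pd.DataFrame(rows)


def simulate_weather(
    monthly: pd.DataFrame,
    precip_cv: float = 0.0,
    temp_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily weather records from a monthly spec (columns year, month,
    precip_mm = monthly total, tmean_c = monthly mean daily temperature).

    With zero dispersion the monthly totals and means are met exactly, so
    the hydrothermal coefficient of the output equals the configured value;
    with dispersion the totals are met in expectation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in monthly.itertuples(index=False):
        year, month = int(spec.year), int(spec.month)
        ndays = calendar.monthrange(year, month)[1]
        base_p = float(spec.precip_mm) / ndays
        p_factors = _lognormal_factor(rng, precip_cv, ndays)
        t_noise = rng.normal(0.0, temp_sd, ndays) if temp_sd > 0 else np.zeros(ndays)
        for day in range(1, ndays + 1):
            rows.append(
                {
                    "date": dt.date(year, month, day),
                    "precip_mm": base_p * p_factors[day - 1],
                    "tmean_c": float(spec.tmean_c) + t_noise[day - 1],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene sequences


def reference_cds(gene: str, seed: int = 42, config: dict | None = None) -> tuple[str, int]:
    """Deterministic synthetic reference CDS for a gene plus its numbering offset.

    The sequence is random coding sequence (no in-frame stops) except that
    the canonical residue of the configured resistance codon is planted at
    the right local position (Pro at standard 197 for ALS, Trp at standard
    1999 for ACCase under the packaged offsets).  Synthetic stand-in for the
    real genes, which are not distributed here.
    """
    from . import fixtures

    cfg = (config or fixtures.gene_config())[gene]
    n_codons = int(cfg["cds_codons"])
    offset = int(cfg["numbering_offset"])
    rng = np.random.default_rng(seed)
    sense = [c for c in _STANDARD_CODONS if translate_codon(c) != "*"]
    codons = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
    for local, aa in cfg.get("canonical", {}).items():
        codons[int(local) - 1] = _BY_AA[aa][0]
    return "".join(codons), offset


def simulate_sequences(
    ref_cds: str,
    n_substitutions: int,
    fraction_silent: float,
    numbering_offset: int = 0,
    plant: list[tuple[int, str]] | None = None,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Mutated copy of a reference CDS with exactly the requested changes.

    ``n_substitutions`` changed codons in total, of which
    ``round(fraction_silent * n_substitutions)`` are synonymous.  ``plant``
    lists (standard position, replacement residue) pairs that must be
    present — e.g. ``[(197, "A")]`` for a Pro197Ala — and count toward the
    nonsynonymous budget.  Returns the query sequence and a truth list that
    matches the substitution caller's output on the pair.
    """
    ref = ref_cds.upper()
    if len(ref) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    n_codons = len(ref) // 3
    if n_substitutions > n_codons:
        raise ValueError("more substitutions requested than codons available")
    n_silent = round(fraction_silent * n_substitutions)
    planted = list(plant or [])
    if len(planted) > n_substitutions - n_silent:
        raise ValueError("planted nonsynonymous changes exceed the nonsynonymous budget")

    rng = np.random.default_rng(seed)
    codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    truth: list[dict] = []
    used: set[int] = set()

    def record(local: int, alt: str) -> None:
        ref_codon = codons[local - 1]
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt)
        codons[local - 1] = alt
        used.add(local)
        truth.append(
            {
                "codon_index_local": local,
                "position_standard": local + numbering_offset,
                "ref_codon": ref_codon,
                "alt_codon": alt,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "kind": "synonymous" if ref_aa == alt_aa else "nonsynonymous",
            }
        )

    for position_standard, residue in planted:
        local = position_standard - numbering_offset
        if not (1 <= local <= n_codons):
            raise ValueError(f"standard position {position_standard} outside the CDS")
        ref_aa = translate_codon(codons[local - 1])
        if residue == ref_aa:
            raise ValueError(f"planted residue {residue} equals the reference at "
                             f"position {position_standard}")
        record(local, _BY_AA[residue][0])

    def draw_codon(want_silent: bool) -> None:
        while True:
            local = int(rng.integers(1, n_codons + 1))
            if local in used:
                continue
            ref_codon = codons[local - 1]
            aa = translate_codon(ref_codon)
            if want_silent:
                options = [c for c in _BY_AA[aa] if c != ref_codon]
            else:
                options = [c for c in _STANDARD_CODONS
                           if translate_codon(c) not in (aa, "*")]
            if not options:
                continue  # e.g. Met/Trp have no synonym
            record(local, options[int(rng.integers(0, len(options)))])
            return

    for _ in range(n_silent):
        draw_codon(want_silent=True)
    for _ in range(n_substitutions - n_silent - len(planted)):
        draw_codon(want_silent=False)

    truth.sort(key=lambda c: c["codon_index_local"])
    return "".join(codons), truth


def template_from_cds(
    cds: str, primer_fwd: str, primer_rev: str,
    amplicon_bp: int | None = None, flank: int = 40, seed: int = 0,
) -> tuple[str, int]:
    """Embed a CDS in a synthetic template so the primer pair amplifies it.

    The amplicon is fwd + pad + cds + pad + revcomp(rev); ``amplicon_bp``
    (when given, must accommodate primers and CDS) sets the exact product
    size via padding, mirroring a configured product length.  Random flanks
    are added outside the primer sites.  Returns the template and the
    0-based offset of the CDS start inside the amplicon.
    """
    from .markers import revcomp

    rng = np.random.default_rng(seed)

    def rand_nt(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    rev_site = revcomp(primer_rev)
    core_min = len(primer_fwd) + len(cds) + len(rev_site)
    if amplicon_bp is None:
        amplicon_bp = core_min
    pad_total = amplicon_bp - core_min
    if pad_total < 0:
        raise ValueError("amplicon_bp too small for primers plus CDS")
    pad_left = pad_total // 2
    # avoid accidentally recreating primer sites in the pads
    def safe(n: int) -> str:
        while True:
            s = rand_nt(n)
            probe = primer_fwd + s
            if primer_fwd not in probe[1:] and rev_site not in s:
                return s
    left = safe(pad_left)
    right = safe(pad_total - pad_left)
    amplicon = primer_fwd + left + cds + right + rev_site
    template = safe(flank) + amplicon + safe(flank)
    return template, len(primer_fwd) + pad_left


# ---------------------------------------------------------------------------
# multi-site scenarios


@dataclass
class LinkScenario:
    """A multi-site biotype-biotype experiment with an environmental link.

    The log competitive advantage of the susceptible biotype over the
    resistant one varies linearly with the standardized site sand content
    (slope ``link_strength``; negative means higher sand favours the
    resistant biotype, depressing the BCR).
    """

    n_sites: int = 12
    link_strength: float = -0.5
    k_link_strength: float = 0.0
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0
    base: SimulationParams = field(default_factory=lambda: SimulationParams(
        series="BB", proportions=(0.4, 0.6),
        # the two biotypes share intrinsic yields and self-crowding, so the
        # wheat-series blackgrass monocultures are valid references for both
        y_a_biomass=25.0, y_b_biomass=25.0,
        y_a_grain=1000.0, y_b_grain=1000.0))


def environment_link_scenario(scenario: LinkScenario) -> dict:
    """Generate per-site biotype-biotype series whose generating competitive
    ratio trends with sand (and optionally K) as configured.

    Returns observations per site, blackgrass monoculture pots (taken from
    wheat-series layouts, as in the field design), a site environment table
    and the ground-truth per-site closed-form BCR.
    """
    rng = np.random.default_rng(scenario.seed)
    sand = rng.uniform(5.0, 90.0, scenario.n_sites)
    k_vals = rng.uniform(0.6, 3.5, scenario.n_sites)
    def _z(v: np.ndarray) -> np.ndarray:
        s = v.std(ddof=1) if len(v) > 1 else 0.0
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    z_sand = _z(sand)
    z_k = _z(k_vals)

    sites = {}
    env_rows = []
    for i in range(scenario.n_sites):
        # c > 0 favours the susceptible biotype (component A of a BB series)
        c = scenario.link_strength * z_sand[i] + scenario.k_link_strength * z_k[i]
        params = replace(
            scenario.base,
            site_id=f"site{i + 1:02d}",
            b_ab=scenario.base.b_ab * float(np.exp(-c)),   # pressure of R on S
            b_ba=scenario.base.b_ba * float(np.exp(+c)),   # pressure of S on R
            noise_cv=scenario.noise_cv,
            replicates=scenario.replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series_obs, truth = simulate_series(params)
        # blackgrass monocultures from wheat-series layouts at this site
        mono_obs = []
        for wb_series in ("WB_S", "WB_R"):
            mono_params = replace(params, series=wb_series, proportions=(0.0,),
                                  seed=int(rng.integers(0, 2**31 - 1)))
            mono, _ = simulate_series(mono_params)
            mono_obs.extend(mono)
        mean_bcr = float(np.mean([closed_form_cr(params, p)
                                  for p in params.proportions]))
        sites[params.site_id] = {"observations": series_obs,
                                 "monocultures": mono_obs, "truth": truth}
        env_rows.append({"site_id": params.site_id, "sand_pct": sand[i],
                         "k": k_vals[i], "true_mean_bcr": mean_bcr})
    return {"sites": sites, "environment": pd.DataFrame(env_rows),
            "scenario": scenario}


def simulate_experiment(
    n_sites: int = 7,
    seasons: tuple[str, ...] = ("2018/19", "2019/20"),
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    model_by_series: dict[str, str] | None = None,
) -> dict:
    """A full multi-site, multi-season demo dataset for the pipeline.

    Per site x season: the two wheat-blackgrass series over the full
    proportion grid and the biotype-biotype series at its two mixed
    proportions, plus a daily weather series built around a site- and
    season-specific hydrothermal target (wet/dry contrasts across sites)
    and a soil table with a sand gradient.  ``model_by_series`` picks the
    generating competition-model preset per series type (default: IIb for
    the wheat series — wheat the stronger competitor — and I for the
    biotype series).
    """
    presets = {"WB_R": "IIb", "WB_S": "IIb", "BB": "I"}
    presets.update(model_by_series or {})
    rng = np.random.default_rng(seed)
    sand = np.linspace(15.0, 86.0, n_sites)
    clay = np.linspace(20.0, 1.0, n_sites)
    silt = 100.0 - sand - clay

    pots: list[PotObservation] = []
    weather_frames = []
    soil_rows = []
    k_rows = []
    for i in range(n_sites):
        site = f"site{i + 1:02d}"
        soil_rows.append({"site_id": site, "sand_pct": round(sand[i], 1),
                          "silt_pct": round(silt[i], 1),
                          "clay_pct": round(clay[i], 1)})
        for j, season in enumerate(seasons):
            k_target = float(rng.uniform(0.6, 1.6) if j == 0
                             else rng.uniform(1.7, 3.5))  # dry then humid year
            wx = simulate_weather(monthly_spec_for_k(k_target, season),
                                  precip_cv=0.0, temp_sd=0.0,
                                  seed=int(rng.integers(0, 2**31 - 1)))
            wx.insert(0, "site_id", site)
            wx.insert(1, "season", season)
            weather_frames.append(wx)
            k_rows.append({"site_id": site, "season": season, "k": k_target})
            for series in ("WB_R", "WB_S", "BB"):
                coeffs = MODEL_PRESETS[presets[series]]
                kwargs = dict(site_id=site, season=season, series=series,
                              replicates=replicates, noise_cv=noise_cv,
                              seed=int(rng.integers(0, 2**31 - 1)), **coeffs)
                if series == "BB":
                    kwargs.update(proportions=(0.4, 0.6),
                                  y_a_biomass=25.0, y_b_biomass=25.0,
                                  y_a_grain=1000.0, y_b_grain=1000.0)
                obs, _ = simulate_series(SimulationParams(**kwargs))
                pots.extend(obs)
    return {
        "pots": pots,
        "weather": pd.concat(weather_frames, ignore_index=True),
        "soils": pd.DataFrame(soil_rows),
        "k_targets": pd.DataFrame(k_rows),
    }


def recovered_site_bcr(result: dict, basis: str = "biomass") -> pd.DataFrame:
    """Pipeline-recovered mean BCR per site of a link scenario."""
    from .indices import series_indices

    rows = []
    for site_id, payload in result["sites"].items():
        idx = series_indices(payload["observations"], payload["monocultures"],
                             bases=("fresh_biomass_g",) if basis == "biomass"
                             else ("grain_count",))
        rows.append({"site_id": site_id,
                     "mean_bcr": float(idx["cr_value"].mean())})
    out = pd.DataFrame(rows)
    return out.merge(result["environment"], on="site_id")
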