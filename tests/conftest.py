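"""Shared fixtures: small in-memory replacement-series datasets."""

import pytest

from weedcomp.io import PotObservation


def make_series(
    site="S1",
    season="2018/19",
    series="WB_R",
    proportions=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    replicates=2,
    per_plant_a=2.5,
    per_plant_b=1.5,
    grain_a=200.0,
    grain_b=400.0,
    density=10,
):
    """A null-competition series: per-plant values identical in mixture and
    monoculture, so RY_a = p, RY_b = 1 - p, TRY = 1 and every ratio is 1."""
    comp_a, comp_b = ("wheat", "blackgrass_R") if series == "WB_R" else (
        ("wheat", "blackgrass_S") if series == "WB_S" else
        ("blackgrass_S", "blackgrass_R")
    )
    obs = []
    for p in proportions:
        n_a = round(p * density)
        n_b = density - n_a
        for rep in range(1, replicates + 1):
            if n_a:
                obs.append(PotObservation(site, season, series, p, rep, comp_a,
                                          n_a, per_plant_a * n_a, grain_a * n_a))
            if n_b:
                obs.append(PotObservation(site, season, series, p, rep, comp_b,
                                          n_b, per_plant_b * n_b, grain_b * n_b))
    return obs


@pytest.fixture
def null_series():
    return make_series()
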