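"""Synthetic-data generators: determinism, null construction, inversion and
ground-truth consistency."""

import numpy as np
import pytest

from weedcomp.environment import hydrothermal_k
from weedcomp.indices import series_indices
from weedcomp.io import write_pot_observations
from weedcomp.markers import call_substitutions
from weedcomp.simulate import (
    MODEL_PRESETS,
    LinkScenario,
    SimulationParams,
    closed_form_cr,
    closed_form_ry,
    environment_link_scenario,
    implied_model_label,
    monthly_spec_for_k,
    recovered_site_bcr,
    reference_cds,
    simulate_experiment,
    simulate_sequences,
    simulate_series,
    simulate_weather,
)
from weedcomp.stats import pearson_r


class TestSimulateSeries:
    def test_null_coefficients_give_straight_lines(self):
        params = SimulationParams(noise_cv=0.0, **MODEL_PRESETS["I"])
        obs, truth = simulate_series(params)
        idx = series_indices(obs)
        assert np.allclose(idx["ry_a"], idx["proportion_a"], atol=1e-12)
        assert np.allclose(idx["try_total"], 1.0, atol=1e-12)
        assert truth["model_label"] == "I"

    def test_asymmetry_gives_dominant_component_a(self):
        # component A suppresses B much harder than B suppresses itself
        params = SimulationParams(b_aa=0.30, b_ab=0.10, b_bb=0.15, b_ba=0.55,
                                  noise_cv=0.0)
        obs, _ = simulate_series(params)
        idx = series_indices(obs, bases=("fresh_biomass_g",))
        for p in (0.2, 0.4, 0.6, 0.8):
            expected = closed_form_cr(params, p)
            got = idx.loc[idx["proportion_a"] == p, "cr_value"]
            assert expected > 1
            # per-pot totals are emitted rounded to 4 decimals
            assert np.allclose(got, expected, rtol=1e-4)

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        out = []
        for run in range(2):
            obs, _ = simulate_series(SimulationParams(seed=99))
            path = tmp_path / f"run{run}.csv"
            write_pot_observations(obs, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_implied_labels(self):
        for label, coef in MODEL_PRESETS.items():
            assert implied_model_label(SimulationParams(**coef)) == label

    def test_parameter_recovery_within_ten_percent(self):
        # noisy estimates of the mean competitive ratio stay near the
        # kernel's closed form (CV 5%, 3 replicates, many runs)
        params = SimulationParams(**MODEL_PRESETS["IIb"])
        target = np.mean([closed_form_cr(params, p)
                          for p in (0.2, 0.4, 0.6, 0.8)])
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(200):
            obs, _ = simulate_series(
                SimulationParams(noise_cv=0.05, seed=int(rng.integers(2**31)),
                                 **MODEL_PRESETS["IIb"])
            )
            idx = series_indices(obs, bases=("fresh_biomass_g",))
            estimates.append(idx["cr_value"].mean())
        assert np.mean(estimates) == pytest.approx(target, rel=0.10)


class TestSimulateWeather:
    def test_noise_free_inversion(self):
        wx = simulate_weather(monthly_spec_for_k(1.5), precip_cv=0.0, temp_sd=0.0)
        assert hydrothermal_k(wx).k == pytest.approx(1.5, rel=1e-12)

    def test_precipitation_scaling(self):
        spec = monthly_spec_for_k(1.2)
        wx = simulate_weather(spec)
        spec2 = spec.assign(precip_mm=spec["precip_mm"] * 2)
        wx2 = simulate_weather(spec2)
        assert hydrothermal_k(wx2).k == pytest.approx(2 * hydrothermal_k(wx).k)

    def test_stochastic_mean_recovers_target(self):
        ks = []
        for seed in range(200):
            wx = simulate_weather(monthly_spec_for_k(1.5), precip_cv=0.3,
                                  temp_sd=0.0, seed=seed)
            ks.append(hydrothermal_k(wx).k)
        assert np.mean(ks) == pytest.approx(1.5, rel=0.02)

    def test_deterministic_under_seed(self):
        a = simulate_weather(monthly_spec_for_k(2.0), precip_cv=0.2, seed=5)
        b = simulate_weather(monthly_spec_for_k(2.0), precip_cv=0.2, seed=5)
        assert a.equals(b)


class TestSimulateSequences:
    def test_truth_matches_caller(self):
        ref, offset = reference_cds("ALS", seed=8)
        query, truth = simulate_sequences(ref, 12, 0.5,
                                          numbering_offset=offset, seed=21)
        calls = call_substitutions(ref, query, offset)
        got = [
            {k: getattr(c, k) for k in ("codon_index_local", "position_standard",
                                        "ref_codon", "alt_codon", "ref_aa",
                                        "alt_aa", "kind")}
            for c in calls
        ]
        assert got == truth

    def test_all_silent_when_fraction_is_one(self):
        ref, offset = reference_cds("ALS", seed=8)
        _, truth = simulate_sequences(ref, 10, 1.0, numbering_offset=offset,
                                      seed=3)
        assert all(t["kind"] == "synonymous" for t in truth)

    def test_planted_resistance_codon_present(self):
        ref, offset = reference_cds("ALS")
        query, truth = simulate_sequences(ref, 3, 2 / 3,
                                          numbering_offset=offset,
                                          plant=[(197, "T")], seed=1)
        planted = [t for t in truth if t["position_standard"] == 197]
        assert planted and planted[0]["alt_aa"] == "T"

    def test_deterministic_under_seed(self):
        ref, offset = reference_cds("ACCase")
        q1, t1 = simulate_sequences(ref, 6, 0.5, numbering_offset=offset, seed=77)
        q2, t2 = simulate_sequences(ref, 6, 0.5, numbering_offset=offset, seed=77)
        assert q1 == q2 and t1 == t2

    def test_budget_validation(self):
        ref, offset = reference_cds("ALS")
        with pytest.raises(ValueError):
            simulate_sequences(ref, 1, 1.0, numbering_offset=offset,
                               plant=[(197, "A")], seed=0)


class TestLinkScenario:
    def test_negative_link_recovers_negative_r(self):
        res = environment_link_scenario(LinkScenario(seed=5, link_strength=-0.5))
        df = recovered_site_bcr(res)
        assert pearson_r(df["sand_pct"], df["mean_bcr"]).r < 0
        # and the generating truth itself trends the same way
        assert pearson_r(df["sand_pct"], df["true_mean_bcr"]).r < 0

    def test_zero_link_mostly_non_significant(self):
        non_sig = 0
        runs = 40
        for seed in range(runs):
            res = environment_link_scenario(
                LinkScenario(seed=seed, link_strength=0.0, n_sites=10)
            )
            df = recovered_site_bcr(res)
            if pearson_r(df["sand_pct"], df["mean_bcr"]).p_value >= 0.05:
                non_sig += 1
        assert non_sig / runs >= 0.9

    def test_single_site_refuses_correlation(self):
        res = environment_link_scenario(LinkScenario(seed=1, n_sites=1))
        df = recovered_site_bcr(res)
        with pytest.raises(ValueError):
            pearson_r(df["sand_pct"], df["mean_bcr"])


class TestSimulateExperiment:
    def test_shapes_and_determinism(self):
        a = simulate_experiment(n_sites=3, seed=4)
        b = simulate_experiment(n_sites=3, seed=4)
        assert a["pots"] == b["pots"]
        assert a["soils"].shape[0] == 3
        assert set(a["k_targets"]["season"]) == {"2018/19", "2019/20"}
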