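import math

import numpy as np
import pandas as pd
import pytest

from anemecon.economics import run_cea
from anemecon.parameters import (ConfigurationError, DistributionSpec,
                                 default_parameters, with_overrides)
from anemecon.uncertainty import (
    default_distribution_specs,
    default_dsa_ranges,
    one_way_dsa,
    run_psa,
    sample_parameter_set,
    sample_value,
    tornado_to_frame,
)

N_MOMENTS = 100_000


def draw_many(spec, n, seed=0):
    rng = np.random.default_rng(seed)
    return np.array([sample_value(spec, rng) for _ in range(n)])


class TestSampling:
    def test_fixed(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("fixed", {"value": 3.5})
        assert all(sample_value(spec, rng) == 3.5 for _ in range(5))

    def test_beta_utility_moments(self):
        a, b = 50.737, 22.795
        x = draw_many(DistributionSpec("beta", {"alpha": a, "beta": b}), N_MOMENTS)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.690, abs=5e-4)
        assert abs(x.mean() - mean) < 3 * math.sqrt(var / N_MOMENTS)

    def test_gamma_hosp_cost_moments(self):
        k, theta = 1002.0, 18.23
        x = draw_many(DistributionSpec("gamma", {"shape": k, "scale": theta}), N_MOMENTS)
        sd = theta * math.sqrt(k)
        assert abs(x.mean() - k * theta) < 3 * sd / math.sqrt(N_MOMENTS)

    def test_uniform_midpoint(self):
        x = draw_many(DistributionSpec("uniform", {"low": 0.5, "high": 0.6}), N_MOMENTS)
        sd = 0.1 / math.sqrt(12)
        assert abs(x.mean() - 0.55) < 3 * sd / math.sqrt(N_MOMENTS)
        assert x.min() >= 0.5 and x.max() <= 0.6

    def test_lognormal_mortality_hr_mean(self):
        mu, sigma = 0.086, 0.040
        x = draw_many(DistributionSpec("lognormal",
                                       {"ln_mu": mu, "ln_sigma": sigma}), N_MOMENTS)
        mean = math.exp(mu + sigma ** 2 / 2)
        assert mean == pytest.approx(1.0908, abs=5e-4)
        var = (math.exp(sigma ** 2) - 1) * math.exp(2 * mu + sigma ** 2)
        assert abs(x.mean() - mean) < 3 * math.sqrt(var / N_MOMENTS)

    def test_beta_pert_support_and_mean(self):
        spec = DistributionSpec(
            "beta_pert", {"minimum": 0.04, "mode": 0.2, "maximum": 0.3},
            support=(0.04, 0.3))
        x = draw_many(spec, N_MOMENTS)
        assert x.min() >= 0.04 and x.max() <= 0.3
        # PERT mean = (min + 4 mode + max) / 6
        mean = (0.04 + 4 * 0.2 + 0.3) / 6
        assert abs(x.mean() - mean) < 3 * x.std() / math.sqrt(N_MOMENTS)

    def test_normal_esa_dose_can_go_negative(self):
        x = draw_many(DistributionSpec("normal", {"mu": 0.4, "sigma": 0.2296}), 5000)
        assert (x < 0).any()


class TestSampleParameterSet:
    def test_all_fixed_returns_base(self, base_params):
        specs = {"utility_hd": DistributionSpec("fixed", {"value": 0.69})}
        rng = np.random.default_rng(1)
        sampled, draws = sample_parameter_set(base_params, specs, rng)
        assert sampled == with_overrides(base_params, utility_hd=0.69)
        assert draws == {"utility_hd": 0.69}

    def test_default_specs_cover_uncertain_inputs(self, base_params):
        specs = default_distribution_specs(base_params)
        assert set(specs) == {
            "hb_sd_reduction", "hr_mortality_per_sd", "rr_hospitalization",
            "utility_hd", "hospitalization_cost", "medicare_share_under65",
            "patient_weight_kg", "esa_dose_reduction"}

    def test_sampled_set_valid_and_in_support(self, base_params):
        specs = default_distribution_specs(base_params)
        rng = np.random.default_rng(2)
        for _ in range(50):
            sampled, _ = sample_parameter_set(base_params, specs, rng)
            assert 0.04 <= sampled.clinical.hb_sd_reduction <= 0.3
            assert 0 <= sampled.economic.utility_hd <= 1
            assert sampled.clinical.rr_hosp_direct is not None

    def test_unknown_parameter_rejected(self, base_params):
        with pytest.raises(ConfigurationError):
            sample_parameter_set(
                base_params, {"phlogiston": DistributionSpec("fixed", {"value": 1})},
                np.random.default_rng(0))

    def test_seed_determinism(self, base_params):
        specs = default_distribution_specs(base_params)
        _, d1 = sample_parameter_set(base_params, specs, np.random.default_rng(9))
        _, d2 = sample_parameter_set(base_params, specs, np.random.default_rng(9))
        assert d1 == d2


@pytest.fixture(scope="module")
def entries():
    return one_way_dsa(default_parameters())


class TestDsa:
    def test_sorted_by_spread(self, entries):
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_sd_reduction_most_influential(self, entries):
        assert entries[0].parameter == "hb_sd_reduction"

    def test_zero_width_range(self, base_params):
        entries = one_way_dsa(base_params, ranges={"utility_hd": (0.69, 0.69)})
        assert entries[0].spread == pytest.approx(0.0, abs=1e-9)

    def test_monotone_parameters_bracket_base(self, base_params):
        base = run_cea(base_params).result.nmb_lifetime
        for e in one_way_dsa(base_params):
            lo, hi = sorted((e.nmb_at_low, e.nmb_at_high))
            assert lo <= base + 1e-6 and hi >= base - 1e-6

    def test_linear_parameter_spread(self, base_params):
        # hospitalization cost enters the NMB linearly: the midpoint NMB is
        # the mean of the endpoint NMBs, and the spread is slope x width
        lo, hi = 16160.0, 17226.0
        entries = one_way_dsa(base_params, ranges={"hospitalization_cost": (lo, hi)})
        mid = one_way_dsa(base_params,
                          ranges={"hospitalization_cost": ((lo + hi) / 2,) * 2})
        assert mid[0].nmb_at_low == pytest.approx(
            (entries[0].nmb_at_low + entries[0].nmb_at_high) / 2, rel=1e-9)

    def test_invalid_range_order(self, base_params):
        with pytest.raises(ValueError):
            one_way_dsa(base_params, ranges={"utility_hd": (0.8, 0.59)})

    def test_frame_export(self, entries):
        frame = tornado_to_frame(entries)
        assert list(frame.columns) == ["parameter", "low", "high",
                                       "nmb_at_low", "nmb_at_high", "spread"]
        assert len(frame) == len(default_dsa_ranges(default_parameters()))


class TestPsa:
    def test_single_draw_reproducible(self, base_params):
        s1, d1 = run_psa(base_params, n=1, seed=42)
        s2, d2 = run_psa(base_params, n=1, seed=42)
        pd.testing.assert_frame_equal(d1, d2)
        assert s1 == s2

    def test_all_fixed_specs_constant_nmb(self, base_params):
        base_nmb = run_cea(base_params).result.nmb_lifetime
        specs = {"utility_hd": DistributionSpec("fixed", {"value": 0.69})}
        summary, draws = run_psa(base_params, n=8, seed=0, specs=specs)
        assert np.allclose(draws["nmb"], base_nmb)
        assert summary.prob_nmb_nonneg == 1.0

    def test_draw_table_shape(self, base_params):
        summary, draws = run_psa(base_params, n=10, seed=3)
        assert len(draws) == 10
        assert {"delta_cost", "delta_qalys", "nmb"} <= set(draws.columns)
        assert summary.n == 10 and summary.seed == 3

    def test_percentiles_from_draws(self, base_params):
        summary, draws = run_psa(base_params, n=200, seed=5)
        lo, hi = np.percentile(draws["nmb"], [2.5, 97.5])
        assert summary.nmb_ci == (pytest.approx(lo), pytest.approx(hi))
        assert summary.nmb_ci[0] < summary.mean_nmb < summary.nmb_ci[1]

    def test_n_below_one_rejected(self, base_params):
        with pytest.raises(ValueError):
            run_psa(base_params, n=0)
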