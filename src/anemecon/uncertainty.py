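"""Deterministic (tornado) and probabilistic sensitivity analysis.

The PSA doubles as the package's synthetic-input generator: it draws full
:class:`~anemecon.parameters.ParameterSet` instances from the published
distribution families (Beta-PERT, lognormal, beta, gamma, uniform, normal)
with a seeded ``numpy`` generator, then pushes every draw through the full
effects -> Markov -> cost-utility pipeline.

Conventions:
* parameters are sampled independently (no correlation structure is
  published);
* the hospitalization relative risk is sampled directly from its published
  lognormal rather than re-running the variability chain per draw — the
  chain defines the base case, the published distribution defines the PSA;
* the willingness-to-pay threshold is computed once from the base-case
  standard-of-care arm and held fixed across all DSA/PSA evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import economics
from .markov import CohortSpec
from .parameters import (ConfigurationError, DistributionSpec, ParameterSet,
                         lognormal_params_from_quartiles, normal_sigma_from_ci,
                         pert_shape_params, with_overrides)

__all__ = [
    "TornadoEntry",
    "PsaSummary",
    "default_distribution_specs",
    "default_dsa_ranges",
    "sample_value",
    "sample_parameter_set",
    "one_way_dsa",
    "run_psa",
    "DEFAULT_PSA_N",
    "DEFAULT_PSA_SEED",
]

DEFAULT_PSA_N = 1000
DEFAULT_PSA_SEED = 20260103

#: PSA/DSA parameter name -> flat configuration key
_PARAM_KEYS: dict[str, str] = {
    "hb_sd_reduction": "hb_sd_reduction",
    "hr_mortality_per_sd": "hr_mortality_per_sd",
    "rr_hospitalization": "rr_hosp_direct",
    "utility_hd": "utility_hd",
    "hospitalization_cost": "hospitalization_cost",
    "discount_rate": "discount_rate",
    "medicare_share_under65": "medicare_share_under65",
    "patient_weight_kg": "patient_weight_kg",
    "esa_dose_reduction": "esa_dose_reduction",
}

# Published lognormal parameters for the two ratio inputs; these are the
# sampling source of truth (the CI calibrator is used for validation and
# for inputs where only summaries are published).
_LN_HR_MORTALITY = (0.086, 0.040)
_LN_RR_HOSP = (-0.092, 0.014)
_BETA_UTILITY = (50.737, 22.795)
_GAMMA_HOSP_COST = (1002.0, 18.23)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float
    spread: float


@dataclass(frozen=True)
class PsaSummary:
    n: int
    seed: int
    wtp: float
    mean_nmb: float
    nmb_ci: tuple[float, float]          # percentile (2.5%, 97.5%)
    prob_nmb_nonneg: float
    mean_delta_cost: float
    mean_delta_qalys: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_nmb": self.mean_nmb,
            "nmb_ci_low": self.nmb_ci[0],
            "nmb_ci_high": self.nmb_ci[1],
            "prob_nmb_nonneg": self.prob_nmb_nonneg,
            "mean_delta_cost": self.mean_delta_cost,
            "mean_delta_qalys": self.mean_delta_qalys,
        }


def default_distribution_specs(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Published PSA distributions for every uncertain input."""
    clin, econ, prov, epi = (params.clinical, params.economic,
                             params.provider, params.epidemiology)
    sd_lo, sd_hi = clin.hb_sd_reduction_ci
    alpha, beta = pert_shape_params(sd_lo, clin.hb_sd_reduction, sd_hi)
    wt_mu, wt_sigma = lognormal_params_from_quartiles(
        prov.patient_weight_kg, *prov.patient_weight_iqr)
    dose_sigma = normal_sigma_from_ci(*prov.esa_dose_reduction_ci)
    return {
        "hb_sd_reduction": DistributionSpec(
            "beta_pert",
            {"minimum": sd_lo, "mode": clin.hb_sd_reduction, "maximum": sd_hi},
            support=(sd_lo, sd_hi)),
        "hr_mortality_per_sd": DistributionSpec(
            "lognormal", {"ln_mu": _LN_HR_MORTALITY[0], "ln_sigma": _LN_HR_MORTALITY[1]}),
        "rr_hospitalization": DistributionSpec(
            "lognormal", {"ln_mu": _LN_RR_HOSP[0], "ln_sigma": _LN_RR_HOSP[1]}),
        "utility_hd": DistributionSpec(
            "beta", {"alpha": _BETA_UTILITY[0], "beta": _BETA_UTILITY[1]},
            support=(0.0, 1.0)),
        "hospitalization_cost": DistributionSpec(
            "gamma", {"shape": _GAMMA_HOSP_COST[0], "scale": _GAMMA_HOSP_COST[1]}),
        "medicare_share_under65": DistributionSpec(
            "uniform", {"low": epi.medicare_share_range[0],
                        "high": epi.medicare_share_range[1]}),
        "patient_weight_kg": DistributionSpec(
            "lognormal", {"ln_mu": wt_mu, "ln_sigma": wt_sigma}),
        "esa_dose_reduction": DistributionSpec(
            "normal", {"mu": prov.esa_dose_reduction, "sigma": dose_sigma}),
    }


def default_dsa_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Published one-way ranges (parameters without a range are excluded)."""
    clin, econ, epi = params.clinical, params.economic, params.epidemiology
    return {
        "hb_sd_reduction": clin.hb_sd_reduction_ci,
        "hr_mortality_per_sd": clin.hr_mortality_ci,
        "rr_hospitalization": clin.rr_hosp_ci,
        "utility_hd": econ.utility_hd_ci,
        "hospitalization_cost": econ.hospitalization_cost_range,
        "discount_rate": econ.discount_rate_range,
        "medicare_share_under65": epi.medicare_share_range,
    }


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a distribution spec, clipped to its support if any."""
    p = spec.params
    if spec.family == "fixed":
        value = float(p["value"])
    elif spec.family == "beta":
        value = float(rng.beta(p["alpha"], p["beta"]))
    elif spec.family == "gamma":
        value = float(rng.gamma(p["shape"], p["scale"]))
    elif spec.family == "lognormal":
        value = float(rng.lognormal(p["ln_mu"], p["ln_sigma"]))
    elif spec.family == "uniform":
        value = float(rng.uniform(p["low"], p["high"]))
    elif spec.family == "normal":
        value = float(rng.normal(p["mu"], p["sigma"]))
    elif spec.family == "beta_pert":
        lo, mode, hi = p["minimum"], p["mode"], p["maximum"]
        alpha, beta = pert_shape_params(lo, mode, hi)
        value = float(lo + (hi - lo) * rng.beta(alpha, beta))
    else:  # pragma: no cover - families validated at construction
        raise ConfigurationError(f"unknown family {spec.family!r}")
    if spec.support is not None:
        value = float(np.clip(value, spec.support[0], spec.support[1]))
    return value


def sample_parameter_set(
    params: ParameterSet,
    specs: Mapping[str, DistributionSpec],
    rng: np.random.Generator,
) -> tuple[ParameterSet, dict[str, float]]:
    """Draw one full parameter set; returns (sampled set, raw draws).

    Draws are made in sorted parameter-name order so results depend only on
    the seed, not on mapping insertion order.
    """
    unknown = set(specs) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown PSA parameter(s): {sorted(unknown)}")
    draws = {name: sample_value(specs[name], rng) for name in sorted(specs)}
    overrides = {_PARAM_KEYS[name]: value for name, value in draws.items()}
    return with_overrides(params, **overrides), draws


def _fix_wtp(params: ParameterSet, cohort: Optional[CohortSpec]) -> tuple[ParameterSet, float]:
    """Resolve the WTP threshold once (base case) and pin it."""
    if params.economic.wtp_threshold is not None:
        return params, params.economic.wtp_threshold
    wtp = economics.run_cea(params, cohort).result.wtp
    return with_overrides(params, wtp_threshold=wtp), wtp


def one_way_dsa(
    params: ParameterSet,
    ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    cohort: Optional[CohortSpec] = None,
) -> list[TornadoEntry]:
    """One-at-a-time sensitivity of lifetime NMB, sorted by spread."""
    if ranges is None:
        ranges = default_dsa_ranges(params)
    unknown = set(ranges) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown DSA parameter(s): {sorted(unknown)}")
    params, _ = _fix_wtp(params, cohort)

    entries = []
    for name, (low, high) in ranges.items():
        if low > high:
            raise ValueError(f"{name}: low ({low}) must be <= high ({high})")
        key = _PARAM_KEYS[name]
        nmb_low = economics.run_cea(
            with_overrides(params, **{key: low}), cohort).result.nmb_lifetime
        nmb_high = economics.run_cea(
            with_overrides(params, **{key: high}), cohort).result.nmb_lifetime
        entries.append(TornadoEntry(
            parameter=name, low=low, high=high,
            nmb_at_low=nmb_low, nmb_at_high=nmb_high,
            spread=abs(nmb_high - nmb_low)))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def run_psa(
    params: ParameterSet,
    n: int = DEFAULT_PSA_N,
    seed: int = DEFAULT_PSA_SEED,
    specs: Optional[Mapping[str, DistributionSpec]] = None,
    cohort: Optional[CohortSpec] = None,
) -> tuple[PsaSummary, pd.DataFrame]:
    """Seeded Monte Carlo PSA: ``n`` full pipeline evaluations.

    Returns a summary plus a per-draw table with every sampled value and
    the resulting (delta_cost, delta_qalys, nmb) — enough to re-plot the
    cost-effectiveness plane.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = default_distribution_specs(params)
    params, wtp = _fix_wtp(params, cohort)
    rng = np.random.default_rng(seed)

    records = []
    for i in range(n):
        sampled, draws = sample_parameter_set(params, specs, rng)
        result = economics.run_cea(sampled, cohort).result
        records.append({
            "draw": i,
            **draws,
            "delta_cost": result.delta_cost,
            "delta_qalys": result.delta_qalys,
            "nmb": result.nmb_lifetime,
        })
    frame = pd.DataFrame.from_records(records)

    nmb = frame["nmb"].to_numpy()
    lo, hi = np.percentile(nmb, [2.5, 97.5])
    summary = PsaSummary(
        n=n,
        seed=seed,
        wtp=wtp,
        mean_nmb=float(nmb.mean()),
        nmb_ci=(float(lo), float(hi)),
        prob_nmb_nonneg=float((nmb >= 0).mean()),
        mean_delta_cost=float(frame["delta_cost"].mean()),
        mean_delta_qalys=float(frame["delta_qalys"].mean()),
    )
    return summary, frame
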