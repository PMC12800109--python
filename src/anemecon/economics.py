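"""Cost-utility arithmetic: ICERs, net monetary benefit, the
willingness-to-pay proxy, and the full treated-vs-control pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

from .effects import DerivedEffects, derive_effects
from .markov import (ArmConfig, ArmOutcomes, CohortSpec, CohortTrace,
                     default_cohort, lifetime_outcomes, run_cohort)
from .parameters import ParameterSet

__all__ = ["IcerResult", "CEResult", "CEAOutput", "icer", "nmb",
           "wtp_proxy", "annualize_nmb", "run_cea"]

AMT_LABEL = "AMT"
SOC_LABEL = "SOC"


@dataclass(frozen=True)
class IcerResult:
    per_qaly: Optional[float]
    per_ly: Optional[float]
    #: "dominant" | "dominated" | "indeterminate" | None (plain ratio)
    flag: Optional[str]


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-utility summary of treatment vs comparator."""

    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    dominance: Optional[str]
    wtp: float
    nmb_lifetime: float
    nmb_annual: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "delta_life_years": self.delta_life_years,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "dominance": self.dominance,
            "wtp": self.wtp,
            "nmb_lifetime": self.nmb_lifetime,
            "nmb_annual": self.nmb_annual,
        }


@dataclass(frozen=True)
class CEAOutput:
    """Everything one base-case evaluation produces."""

    result: CEResult
    effects: DerivedEffects
    amt: ArmOutcomes
    soc: ArmOutcomes
    amt_trace: CohortTrace
    soc_trace: CohortTrace


def icer(treatment: ArmOutcomes, comparator: ArmOutcomes) -> IcerResult:
    """Incremental cost-effectiveness ratios, with dominance handling.

    A ratio is only returned on the ordinary trade-off quadrants; when the
    treatment is cheaper and more effective ("dominant"), costlier and less
    effective ("dominated"), or identical ("indeterminate"), a flag is
    returned instead of a ratio.
    """
    d_cost = treatment.cost - comparator.cost
    d_qaly = treatment.qalys - comparator.qalys
    d_ly = treatment.life_years - comparator.life_years

    if d_cost == 0 and d_qaly == 0:
        return IcerResult(None, None, "indeterminate")
    if d_cost <= 0 and d_qaly >= 0:
        return IcerResult(None, None, "dominant")
    if d_cost >= 0 and d_qaly <= 0:
        return IcerResult(None, None, "dominated")
    return IcerResult(
        per_qaly=d_cost / d_qaly,
        per_ly=d_cost / d_ly if d_ly != 0 else None,
        flag=None,
    )


def nmb(wtp: float, delta_effect: float, delta_cost: float) -> float:
    """Net monetary benefit: ``wtp * delta_effect - delta_cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_effect - delta_cost


def wtp_proxy(soc: ArmOutcomes) -> float:
    """Willingness-to-pay proxied by the cost-utility ratio of the standard
    of care versus a zero-cost, zero-benefit comparator."""
    if soc.qalys <= 0:
        raise ValueError("SOC QALYs must be > 0 to form the WTP proxy")
    return soc.cost / soc.qalys


def annualize_nmb(nmb_lifetime: float, life_expectancy: float) -> float:
    """Spread a lifetime NMB over the treated arm's (discounted) life
    expectancy."""
    if life_expectancy <= 0:
        raise ValueError("life expectancy must be > 0")
    return nmb_lifetime / life_expectancy


def run_cea(params: ParameterSet, cohort: Optional[CohortSpec] = None) -> CEAOutput:
    """Full pipeline: effect chain -> two Markov arms -> cost-utility summary.

    The treated arm applies the derived mortality HR, subtracts the derived
    hospitalization reduction from the baseline rate (floored at zero), and
    adds the in-range utility premium when the scenario flag is enabled.
    """
    fx = derive_effects(params)
    clin = params.clinical
    if cohort is None:
        cohort = default_cohort(params.epidemiology)

    soc_arm = ArmConfig(SOC_LABEL, mortality_hr=1.0,
                        hosp_rate=clin.baseline_hosp_rate)
    extra_u = fx.in_range_qaly_gain_per_year if params.utility_premium_enabled else 0.0
    amt_arm = ArmConfig(
        AMT_LABEL,
        mortality_hr=fx.hr_mortality_amt,
        hosp_rate=max(clin.baseline_hosp_rate - fx.hosp_rate_reduction, 0.0),
        extra_utility_per_year=extra_u,
    )

    soc_trace = run_cohort(params, soc_arm, cohort)
    amt_trace = run_cohort(params, amt_arm, cohort)
    soc_out = lifetime_outcomes(soc_trace)
    amt_out = lifetime_outcomes(amt_trace)

    wtp = params.economic.wtp_threshold
    if wtp is None:
        wtp = wtp_proxy(soc_out)

    d_cost = amt_out.cost - soc_out.cost
    d_qaly = amt_out.qalys - soc_out.qalys
    d_ly = amt_out.life_years - soc_out.life_years
    ratios = icer(amt_out, soc_out)
    nmb_life = nmb(wtp, d_qaly, d_cost)

    result = CEResult(
        delta_cost=d_cost,
        delta_qalys=d_qaly,
        delta_life_years=d_ly,
        icer_per_qaly=ratios.per_qaly,
        icer_per_ly=ratios.per_ly,
        dominance=ratios.flag,
        wtp=wtp,
        nmb_lifetime=nmb_life,
        nmb_annual=annualize_nmb(nmb_life, amt_out.life_years),
    )
    return CEAOutput(result=result, effects=fx, amt=amt_out, soc=soc_out,
                     amt_trace=amt_trace, soc_trace=soc_trace)
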