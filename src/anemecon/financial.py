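"""Provider net financial impact (NFIA) and payer budget impact (BIA).

NFIA, per patient-year, from a dialysis provider's perspective:
ESA drug savings + avoided quality-program payment reduction - the cost of
implementing the monitoring hardware, consumables, and software fee.
BIA multiplies the annual number of (Medicare-covered) incident cases by
the lifetime cost difference per case; negative values are payer savings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

from .parameters import ConfigurationError, ParameterSet, ProviderInputs

__all__ = [
    "COST_SCENARIOS",
    "NfiaResult",
    "BiaResult",
    "esa_annual_savings",
    "qip_avoided_reduction",
    "implementation_cost_per_patient_year",
    "nfia",
    "incident_cases",
    "budget_impact",
]

#: full = device + consumables + software fee; the other two assume the
#: hardware (and, for amt_only, the consumables) are already in place.
COST_SCENARIOS = ("full", "consumables_amt", "amt_only")

DAYS_PER_YEAR = 365.0
DOSE_WINDOW_DAYS = 30.0


@dataclass(frozen=True)
class NfiaResult:
    esa_savings: float            # USD / patient-year
    qip_revenue: float            # USD / patient-year
    implementation_cost: float    # USD / patient-year
    net_per_patient: float        # USD / patient-year
    facility_profit: float        # USD / facility-year
    cost_scenario: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "esa_savings": self.esa_savings,
            "qip_revenue": self.qip_revenue,
            "implementation_cost": self.implementation_cost,
            "net_per_patient": self.net_per_patient,
            "facility_profit": self.facility_profit,
            "cost_scenario": self.cost_scenario,
        }


@dataclass(frozen=True)
class BiaResult:
    incident_cases: float
    lifetime_cost_difference: float  # USD / person; negative = savings
    budget_impact: float             # USD / year

    def to_dict(self) -> dict[str, Any]:
        return {
            "incident_cases": self.incident_cases,
            "lifetime_cost_difference": self.lifetime_cost_difference,
            "budget_impact": self.budget_impact,
        }


def esa_annual_savings(dose_reduction: float, weight: float, price: float) -> float:
    """Annual ESA cost savings per patient.

    ``dose_reduction`` is in microgram/kg per 30 days; annualized with
    365/30 dosing windows per year.  A negative reduction yields negative
    savings by design (the dose CI crosses zero).
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if price < 0:
        raise ValueError("price must be >= 0")
    return dose_reduction * weight * (DAYS_PER_YEAR / DOSE_WINDOW_DAYS) * price


def qip_avoided_reduction(session_cost: float, sessions_per_year: int,
                          reduction_fraction: float) -> float:
    """Revenue retained by avoiding a fractional payment reduction across a
    year of bundled session payments."""
    if min(session_cost, sessions_per_year, reduction_fraction) < 0:
        raise ValueError("all inputs must be >= 0")
    return session_cost * sessions_per_year * reduction_fraction


def implementation_cost_per_patient_year(
    scenario: str,
    components: ProviderInputs,
    use_aggregate: bool = True,
) -> float:
    """Annual per-patient implementation cost under a cost scenario.

    ``full`` uses the published aggregate annual figure when
    ``use_aggregate`` is set (the component split is not published),
    otherwise the per-session component sum times sessions/year.  The
    reduced scenarios always build from components.
    """
    if scenario not in COST_SCENARIOS:
        raise ConfigurationError(
            f"unknown cost scenario {scenario!r}; expected one of {COST_SCENARIOS}")
    sessions = components.sessions_per_year
    if scenario == "full":
        if use_aggregate:
            return components.combined_cost_per_patient_year
        per_session = (components.amt_fee_per_treatment
                       + components.consumable_cost_per_session
                       + components.device_cost_per_session)
    elif scenario == "consumables_amt":
        per_session = (components.amt_fee_per_treatment
                       + components.consumable_cost_per_session)
    else:  # amt_only
        per_session = components.amt_fee_per_treatment
    return per_session * sessions


def nfia(params: ParameterSet, scenario: str = "full",
         use_aggregate: bool = True) -> NfiaResult:
    """Compose ESA savings, avoided QIP reduction and implementation cost
    into the provider's net financial impact."""
    prov = params.provider
    savings = esa_annual_savings(prov.esa_dose_reduction, prov.patient_weight_kg,
                                 prov.esa_price_per_ug)
    qip = qip_avoided_reduction(params.economic.dialysis_session_cost,
                                prov.sessions_per_year, prov.qip_reduction_fraction)
    cost = implementation_cost_per_patient_year(scenario, prov, use_aggregate)
    net = savings + qip - cost
    return NfiaResult(
        esa_savings=savings,
        qip_revenue=qip,
        implementation_cost=cost,
        net_per_patient=net,
        facility_profit=net * prov.facility_patient_count,
        cost_scenario=scenario,
    )


def incident_cases(params: ParameterSet, include_under65: bool = False) -> float:
    """Annual Medicare-covered incident caseload.

    65+ bands count in full; under-65 bands, when included, are weighted by
    the Medicare coverage share.
    """
    epi = params.epidemiology
    total = 0.0
    for band in epi.age_bands:
        if band.lower_age >= 65:
            total += band.incident_count
        elif include_under65:
            total += band.incident_count * epi.medicare_share_under65
    return total


def budget_impact(params: ParameterSet, lifetime_cost_difference: float,
                  include_under65: bool = False,
                  cases: Optional[float] = None) -> BiaResult:
    """Annual payer budget impact for the incident cohort.

    ``budget_impact = incident_cases * lifetime_cost_difference``; negative
    means savings to the payer.
    """
    n = incident_cases(params, include_under65) if cases is None else cases
    return BiaResult(
        incident_cases=n,
        lifetime_cost_difference=lifetime_cost_difference,
        budget_impact=n * lifetime_cost_difference,
    )
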