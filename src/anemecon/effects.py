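"""Evidence-synthesis chain: from a hemoglobin-variability reduction to
mortality and hospitalization effects.

The chain has two branches:

* **Mortality** — the per-1 g/dL hazard ratio for all-cause mortality is
  exponentiated to the achieved reduction in intrapatient Hb standard
  deviation: ``HR_treated = hr_per_unit ** (-delta_sd)``.

* **Hospitalization** — the odds ratio comparing low- vs high-variability
  patients is first expressed as a standardized mean difference via Chinn's
  approximation (``ln OR / (pi / sqrt(3))``), the achieved SD reduction is
  expressed as a fraction of that SMD magnitude, the OR is raised to this
  scaling exponent, converted to a relative risk at the baseline annual
  hospitalization probability, and finally turned into an absolute avoided
  event rate.

All intermediates are carried at full precision; printed two-decimal values
are reproduced by rounding the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .parameters import ParameterSet

__all__ = [
    "DerivedEffects",
    "mortality_hr_from_sd",
    "chinn_smd",
    "scale_odds_ratio",
    "rate_to_prob",
    "or_to_rr",
    "avoided_hospitalization_rate",
    "in_range_utility_gain",
    "derive_effects",
    "CHINN_CONSTANT",
]

#: Chinn's logistic-to-normal conversion constant, pi / sqrt(3) (~1.8138).
CHINN_CONSTANT: float = math.pi / math.sqrt(3.0)


@dataclass(frozen=True)
class DerivedEffects:
    """Outputs of the effect chain for one parameter set."""

    hr_mortality_amt: float            # treated-vs-control mortality HR
    smd: float                         # SMD implied by the source OR
    scaling_exponent: float            # delta_sd / |smd|
    or_adjusted: float
    or_adjusted_ci: tuple[float, float]
    rr_adjusted: float
    rr_adjusted_ci: tuple[float, float]
    hosp_rate_reduction: float         # events avoided / patient-year
    in_range_qaly_gain_per_year: float  # scenario only; 0 unless premium set


def mortality_hr_from_sd(hr_per_unit: float, delta_sd: float) -> float:
    """Mortality HR for a ``delta_sd`` g/dL *reduction* in Hb SD.

    Returns ``hr_per_unit ** (-delta_sd)``.
    """
    if hr_per_unit <= 0:
        raise ValueError("hr_per_unit must be > 0")
    if delta_sd < 0:
        raise ValueError("delta_sd is a reduction and must be >= 0")
    return hr_per_unit ** (-delta_sd)


def chinn_smd(odds_ratio: float) -> float:
    """Standardized mean difference implied by an odds ratio.

    Chinn's approximation: ``ln(OR) / (pi / sqrt(3))``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    return math.log(odds_ratio) / CHINN_CONSTANT


def scale_odds_ratio(
    odds_ratio: float,
    target_sd: float,
    source_smd_magnitude: float,
    ci: Optional[tuple[float, float]] = None,
) -> float | tuple[float, tuple[float, float]]:
    """Rescale an OR from its source SD contrast to a smaller/larger one.

    The OR is raised to ``target_sd / source_smd_magnitude``.  When ``ci``
    is given, the same exponent is applied to both bounds and
    ``(point, (lo, hi))`` is returned.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if source_smd_magnitude <= 0:
        raise ValueError("source_smd_magnitude must be > 0")
    exponent = target_sd / source_smd_magnitude
    point = odds_ratio ** exponent
    if ci is None:
        return point
    return point, (ci[0] ** exponent, ci[1] ** exponent)


def rate_to_prob(rate: float) -> float:
    """Annual event probability from a constant event rate: ``1 - exp(-rate)``."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-rate)


def or_to_rr(odds_ratio: float, baseline_prob: float) -> float:
    """Convert an odds ratio to a relative risk at a baseline risk.

    ``RR = OR / (1 - p0 * (1 - OR))`` with ``p0`` the comparator-group
    event probability.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not (0.0 <= baseline_prob < 1.0):
        raise ValueError("baseline_prob must be in [0, 1)")
    return odds_ratio / (1.0 - baseline_prob * (1.0 - odds_ratio))


def avoided_hospitalization_rate(rr_adjusted: float, baseline_rate: float) -> float:
    """Absolute avoided events per patient-year: ``(1 - RR) * baseline_rate``."""
    if rr_adjusted <= 0:
        raise ValueError("rr_adjusted must be > 0")
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    return (1.0 - rr_adjusted) * baseline_rate


def in_range_utility_gain(delta_u: float, in_range_increase: float) -> float:
    """QALY gain per patient-year from an in-range utility premium."""
    if not (0.0 <= in_range_increase <= 1.0):
        raise ValueError("in_range_increase must be in [0, 1]")
    return delta_u * in_range_increase


def derive_effects(params: ParameterSet) -> DerivedEffects:
    """Run the full chain on a parameter set, carrying unrounded intermediates.

    The hospitalization branch normally runs the variability chain from the
    source OR.  When ``clinical.rr_hosp_direct`` is set (as in probabilistic
    sampling, where the RR is drawn from its own distribution), that value
    replaces the chain's RR; the chain intermediates are still reported.
    """
    clin = params.clinical
    hr = mortality_hr_from_sd(clin.hr_mortality_per_sd, clin.hb_sd_reduction)

    smd = chinn_smd(clin.or_hosp_low_vs_high_variability)
    magnitude = abs(smd)
    if clin.hb_sd_reduction > 0:
        or_adj, or_ci = scale_odds_ratio(
            clin.or_hosp_low_vs_high_variability, clin.hb_sd_reduction,
            magnitude, ci=clin.or_hosp_ci)
        exponent = clin.hb_sd_reduction / magnitude
    else:
        or_adj, or_ci, exponent = 1.0, (1.0, 1.0), 0.0

    p0 = rate_to_prob(clin.baseline_hosp_rate)
    rr = or_to_rr(or_adj, p0)
    rr_ci = (or_to_rr(or_ci[0], p0), or_to_rr(or_ci[1], p0))
    if clin.rr_hosp_direct is not None:
        rr = clin.rr_hosp_direct
    reduction = avoided_hospitalization_rate(rr, clin.baseline_hosp_rate)

    gain = in_range_utility_gain(params.utility_premium, clin.hb_in_range_increase)

    return DerivedEffects(
        hr_mortality_amt=hr,
        smd=smd,
        scaling_exponent=exponent,
        or_adjusted=or_adj,
        or_adjusted_ci=or_ci,
        rr_adjusted=rr,
        rr_adjusted_ci=rr_ci,
        hosp_rate_reduction=reduction,
        in_range_qaly_gain_per_year=gain,
    )
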