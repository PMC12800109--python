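"""Two-state (alive/dead) Markov cohort engine.

A cohort is a set of weighted sub-cohorts (starting age, weight).  Each
cycle is one year: every sub-cohort draws the annual mortality of the age
band containing its current integer age (hazard-scaled for the treated
arm), person-time is counted with the life-table half-cycle correction
``(alive_start + alive_end) / 2``, hospitalizations accrue as rate events
among the alive, and both costs and effects are discounted at mid-cycle.
Simulation stops at the first cycle after which fewer than 0.1% of the
cohort remains alive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import ConfigurationError, EpidemiologyInputs, ParameterSet

__all__ = [
    "CohortSpec",
    "ArmConfig",
    "CohortTrace",
    "ArmOutcomes",
    "default_cohort",
    "mid_cycle_discount",
    "adjust_mortality",
    "run_cohort",
    "lifetime_outcomes",
]

#: stop once the alive fraction drops below this
ALIVE_THRESHOLD = 1e-3
#: hard cap to guarantee termination with pathological inputs
MAX_CYCLES = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Weighted starting-age mixture; weights must sum to 1."""

    members: tuple[tuple[float, float], ...]  # (starting_age, weight)

    def __post_init__(self) -> None:
        weights = [w for _, w in self.members]
        if any(w < 0 for w in weights):
            raise ValueError("CohortSpec weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError(f"CohortSpec weights must sum to 1 (got {sum(weights)})")


@dataclass(frozen=True)
class ArmConfig:
    """Arm-level knobs: mortality hazard ratio vs control, hospitalization
    rate, and any extra per-year utility (scenario hook)."""

    label: str
    mortality_hr: float = 1.0
    hosp_rate: float = 0.0           # events / patient-year
    extra_utility_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.mortality_hr <= 0:
            raise ValueError("mortality_hr must be > 0")
        if self.hosp_rate < 0:
            raise ValueError("hosp_rate must be >= 0")


@dataclass
class CohortTrace:
    """Per-cycle aggregate record of one simulated arm."""

    arm: str
    discount_rate: float
    utility: float
    cycle: np.ndarray = field(default_factory=lambda: np.empty(0))
    age: np.ndarray = field(default_factory=lambda: np.empty(0))  # mean age, alive-weighted
    alive_start: np.ndarray = field(default_factory=lambda: np.empty(0))
    alive_end: np.ndarray = field(default_factory=lambda: np.empty(0))
    life_years: np.ndarray = field(default_factory=lambda: np.empty(0))
    disc_life_years: np.ndarray = field(default_factory=lambda: np.empty(0))
    qalys: np.ndarray = field(default_factory=lambda: np.empty(0))  # discounted
    maintenance_cost: np.ndarray = field(default_factory=lambda: np.empty(0))
    hospitalization_cost: np.ndarray = field(default_factory=lambda: np.empty(0))
    disc_total_cost: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "arm": self.arm,
            "cycle": self.cycle.astype(int),
            "mean_age": self.age,
            "alive_start": self.alive_start,
            "alive_end": self.alive_end,
            "life_years": self.life_years,
            "disc_life_years": self.disc_life_years,
            "disc_qalys": self.qalys,
            "maintenance_cost": self.maintenance_cost,
            "hospitalization_cost": self.hospitalization_cost,
            "disc_total_cost": self.disc_total_cost,
        })


@dataclass(frozen=True)
class ArmOutcomes:
    """Lifetime discounted totals for one arm."""

    cost: float
    life_years: float
    qalys: float


def mid_cycle_discount(cycle_index: int, rate: float) -> float:
    """Discount factor at the middle of 1-based cycle ``cycle_index``:
    ``(1 + rate) ** -(cycle_index - 0.5)``."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based and must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return (1.0 + rate) ** -(cycle_index - 0.5)


def adjust_mortality(prob: float, hr: float) -> float:
    """Apply a hazard ratio to an annual death probability.

    Probability -> rate -> scale -> probability: ``1 - (1 - p) ** hr``.
    ``p = 1`` maps to 1 for any HR.
    """
    if not (0.0 <= prob <= 1.0):
        raise ValueError("prob must be in [0, 1]")
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if prob == 1.0:
        return 1.0
    return 1.0 - (1.0 - prob) ** hr


def default_cohort(epi: EpidemiologyInputs) -> CohortSpec:
    """Incident Medicare mixture from the age-band incidence counts.

    Under-65 bands are down-weighted by the Medicare coverage share; each
    sub-cohort starts at its band midpoint (open-ended top band at
    lower_age + 5).
    """
    ages, weights = [], []
    for band in epi.age_bands:
        share = 1.0 if band.lower_age >= 65 else epi.medicare_share_under65
        upper = band.upper_age if band.upper_age is not None else band.lower_age + 10
        ages.append((band.lower_age + upper) / 2.0)
        weights.append(band.incident_count * share)
    total = sum(weights)
    if total <= 0:
        raise ConfigurationError("cohort weights sum to zero; check incidence counts")
    members = tuple((a, w / total) for a, w in zip(ages, weights))
    return CohortSpec(members=members)


def run_cohort(
    params: ParameterSet,
    arm: ArmConfig,
    cohort: Optional[CohortSpec] = None,
) -> CohortTrace:
    """Simulate one arm until fewer than 0.1% of the cohort remains alive."""
    epi = params.epidemiology
    econ = params.economic
    if cohort is None:
        cohort = default_cohort(epi)

    ages = np.array([a for a, _ in cohort.members], dtype=float)
    alive = np.array([w for _, w in cohort.members], dtype=float)

    # validate band coverage up front for every reachable starting age
    for a in ages:
        epi.band_for_age(a)

    utility = econ.utility_hd + arm.extra_utility_per_year
    rows: list[tuple[float, ...]] = []

    t = 0
    while t < MAX_CYCLES:
        t += 1
        bands = [epi.band_for_age(a) for a in ages]
        q = np.array([adjust_mortality(b.annual_mortality_prob, arm.mortality_hr)
                      for b in bands])
        costs = np.array([b.annual_cost if b.annual_cost is not None else 0.0
                          for b in bands])

        alive_end = alive * (1.0 - q)
        ly_i = 0.5 * (alive + alive_end)
        ly = float(ly_i.sum())
        df = mid_cycle_discount(t, econ.discount_rate)

        maint = float((ly_i * costs).sum())
        hosp = ly * arm.hosp_rate * econ.hospitalization_cost
        total_alive = float(alive.sum())
        mean_age = float((alive * ages).sum() / total_alive) if total_alive > 0 else math.nan

        rows.append((
            t, mean_age, total_alive, float(alive_end.sum()),
            ly, ly * df, ly * df * utility,
            maint, hosp, (maint + hosp) * df,
        ))

        alive = alive_end
        ages = ages + 1.0
        if float(alive.sum()) < ALIVE_THRESHOLD:
            break

    cols = list(zip(*rows))
    return CohortTrace(
        arm=arm.label,
        discount_rate=econ.discount_rate,
        utility=utility,
        cycle=np.array(cols[0]),
        age=np.array(cols[1]),
        alive_start=np.array(cols[2]),
        alive_end=np.array(cols[3]),
        life_years=np.array(cols[4]),
        disc_life_years=np.array(cols[5]),
        qalys=np.array(cols[6]),
        maintenance_cost=np.array(cols[7]),
        hospitalization_cost=np.array(cols[8]),
        disc_total_cost=np.array(cols[9]),
    )


def lifetime_outcomes(trace: CohortTrace) -> ArmOutcomes:
    """Sum the discounted columns of a trace."""
    if len(trace.cycle) == 0:
        raise ValueError("empty trace")
    return ArmOutcomes(
        cost=float(trace.disc_total_cost.sum()),
        life_years=float(trace.disc_life_years.sum()),
        qalys=float(trace.qalys.sum()),
    )
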