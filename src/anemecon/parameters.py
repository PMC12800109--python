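"""Model input registry: typed parameter containers, embedded defaults, and
distribution calibrators.

Every quantity the model consumes lives in a :class:`ParameterSet`, an
immutable snapshot of clinical, economic, provider and epidemiological
inputs.  Defaults are embedded so the package runs with no configuration
file at all; a flat YAML/dict overlay can override any field by name.

The calibrators (:func:`pert_shape_params`, :func:`lognormal_params_from_ci`,
:func:`lognormal_params_from_quartiles`, :func:`normal_sigma_from_ci`) turn
printed summaries (95% CI, IQR, min/mode/max) into distribution parameters
for the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "AgeBand",
    "ClinicalEffectInputs",
    "EconomicInputs",
    "ProviderInputs",
    "EpidemiologyInputs",
    "DistributionSpec",
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "pert_shape_params",
    "lognormal_params_from_ci",
    "lognormal_params_from_quartiles",
    "normal_sigma_from_ci",
]


class ConfigurationError(ValueError):
    """Unknown configuration key or malformed configuration document."""


class ValidationError(ValueError):
    """A parameter value violates its documented bound."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Calibrators
# ---------------------------------------------------------------------------

def pert_shape_params(minimum: float, mode: float, maximum: float) -> tuple[float, float]:
    """Beta-PERT shape parameters (alpha, beta) from (min, mode, max).

    alpha = 1 + 4 (mode - min) / (max - min)
    beta  = 1 + 4 (max - mode) / (max - min)
    """
    if minimum >= maximum:
        raise ValueError(f"pert_shape_params: min ({minimum}) must be < max ({maximum})")
    if not (minimum <= mode <= maximum):
        raise ValueError(f"pert_shape_params: mode ({mode}) must lie in [min, max]")
    span = maximum - minimum
    return 1.0 + 4.0 * (mode - minimum) / span, 1.0 + 4.0 * (maximum - mode) / span


def lognormal_params_from_ci(point: float, lo: float, hi: float) -> tuple[float, float]:
    """Lognormal (ln_mu, ln_sigma) from a ratio estimate and its 95% CI.

    ln_mu = ln(point); ln_sigma = (ln(hi) - ln(lo)) / (2 * 1.96).
    """
    if min(point, lo, hi) <= 0:
        raise ValueError("lognormal_params_from_ci: all inputs must be positive")
    if not (lo <= point <= hi):
        raise ValueError("lognormal_params_from_ci: require lo <= point <= hi")
    return math.log(point), (math.log(hi) - math.log(lo)) / (2.0 * 1.96)


def lognormal_params_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Lognormal (ln_mu, ln_sigma) from a median and interquartile range.

    ln_sigma uses the standard-normal quartile 0.6745:
    ln_sigma = (ln(q3) - ln(q1)) / (2 * 0.6745).
    """
    if min(median, q1, q3) <= 0:
        raise ValueError("lognormal_params_from_quartiles: all inputs must be positive")
    if not (q1 <= median <= q3):
        raise ValueError("lognormal_params_from_quartiles: require q1 <= median <= q3")
    return math.log(median), (math.log(q3) - math.log(q1)) / (2.0 * 0.6745)


def normal_sigma_from_ci(lo: float, hi: float) -> float:
    """Normal standard deviation implied by a 95% CI: (hi - lo) / (2 * 1.96)."""
    if lo > hi:
        raise ValueError(f"normal_sigma_from_ci: lo ({lo}) must be <= hi ({hi})")
    return (hi - lo) / (2.0 * 1.96)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBand:
    """One age stratum with its annual mortality, annual cost and incidence."""

    label: str
    lower_age: float
    upper_age: Optional[float]  # None = open-ended
    annual_mortality_prob: float
    annual_cost: Optional[float]
    incident_count: float

    def __post_init__(self) -> None:
        _require(0.0 <= self.annual_mortality_prob <= 1.0,
                 f"age_band[{self.label}].annual_mortality_prob", "must be in [0, 1]")
        _require(self.incident_count >= 0,
                 f"age_band[{self.label}].incident_count", "must be >= 0")
        if self.upper_age is not None:
            _require(self.lower_age <= self.upper_age,
                     f"age_band[{self.label}]", "lower_age must be <= upper_age")
        if self.annual_cost is not None:
            _require(self.annual_cost >= 0,
                     f"age_band[{self.label}].annual_cost", "must be >= 0")

    def contains(self, age: float) -> bool:
        intage = math.floor(age)
        if intage < self.lower_age:
            return False
        return self.upper_age is None or intage <= self.upper_age


@dataclass(frozen=True)
class ClinicalEffectInputs:
    hb_sd_reduction: float = 0.2                       # g/dL
    hb_sd_reduction_ci: tuple[float, float] = (0.04, 0.3)
    hb_in_range_increase: float = 0.10                 # proportion points
    hr_mortality_per_sd: float = 1.09                  # per 1 g/dL Hb-SD
    hr_mortality_ci: tuple[float, float] = (1.01, 1.18)
    or_hosp_low_vs_high_variability: float = 0.53
    or_hosp_ci: tuple[float, float] = (0.45, 0.62)
    baseline_hosp_rate: float = 1.49                   # events / patient-year
    rr_hosp_derived: float = 0.91
    rr_hosp_ci: tuple[float, float] = (0.88, 0.93)
    #: when set, bypasses the variability chain (used by PSA/DSA sampling)
    rr_hosp_direct: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.hr_mortality_per_sd > 0, "hr_mortality_per_sd", "must be > 0")
        _require(self.or_hosp_low_vs_high_variability > 0,
                 "or_hosp_low_vs_high_variability", "must be > 0")
        _require(self.rr_hosp_derived > 0, "rr_hosp_derived", "must be > 0")
        _require(self.baseline_hosp_rate >= 0, "baseline_hosp_rate", "must be >= 0")
        _require(0.0 <= self.hb_in_range_increase <= 1.0,
                 "hb_in_range_increase", "must be in [0, 1]")
        if self.rr_hosp_direct is not None:
            _require(self.rr_hosp_direct > 0, "rr_hosp_direct", "must be > 0")


@dataclass(frozen=True)
class EconomicInputs:
    utility_hd: float = 0.69
    utility_hd_ci: tuple[float, float] = (0.59, 0.80)
    hospitalization_cost: float = 17226.0              # USD per event
    hospitalization_cost_range: tuple[float, float] = (16160.0, 17226.0)
    dialysis_session_cost: float = 265.57              # USD, bundled payment
    discount_rate: float = 0.03
    discount_rate_range: tuple[float, float] = (0.02, 0.09)
    #: None = derive from the standard-of-care arm (cost per QALY vs nothing)
    wtp_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        _require(0.0 <= self.utility_hd <= 1.0, "utility_hd", "must be in [0, 1]")
        _require(self.hospitalization_cost >= 0, "hospitalization_cost", "must be >= 0")
        _require(self.dialysis_session_cost >= 0, "dialysis_session_cost", "must be >= 0")
        _require(0.0 <= self.discount_rate < 1.0, "discount_rate", "must be in [0, 1)")
        if self.wtp_threshold is not None:
            _require(self.wtp_threshold >= 0, "wtp_threshold", "must be >= 0")


@dataclass(frozen=True)
class ProviderInputs:
    esa_price_per_ug: float = 1.3                      # USD / microgram
    esa_price_range: tuple[float, float] = (1.3, 1.5)
    patient_weight_kg: float = 81.4
    patient_weight_iqr: tuple[float, float] = (68.1, 98.0)
    esa_dose_reduction: float = 0.4                    # microgram/kg per 30 days
    esa_dose_reduction_ci: tuple[float, float] = (-0.1, 0.8)
    amt_fee_per_treatment: float = 0.29
    amt_fee_range: tuple[float, float] = (0.29, 0.41)
    consumable_cost_per_session: float = 1.35
    consumable_cost_range: tuple[float, float] = (1.35, 2.00)
    device_cost_per_session: float = 0.49
    #: printed aggregate annual implementation cost for the full scenario
    combined_cost_per_patient_year: float = 347.0
    qip_reduction_fraction: float = 0.0012
    sessions_per_week: int = 3
    facility_patient_count: int = 70

    def __post_init__(self) -> None:
        for name in ("esa_price_per_ug", "patient_weight_kg", "amt_fee_per_treatment",
                     "consumable_cost_per_session", "device_cost_per_session",
                     "combined_cost_per_patient_year", "qip_reduction_fraction"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.patient_weight_kg > 0, "patient_weight_kg", "must be > 0")
        _require(isinstance(self.sessions_per_week, int) and self.sessions_per_week > 0,
                 "sessions_per_week", "must be a positive integer")
        _require(self.facility_patient_count >= 0, "facility_patient_count", "must be >= 0")

    @property
    def sessions_per_year(self) -> int:
        return self.sessions_per_week * 52


def _default_age_bands() -> tuple[AgeBand, ...]:
    # Under-65 annual cost is not published; default to the 65-74 figure
    # (overridable via configuration).
    return (
        AgeBand("18-44", 18, 44, 0.0963, 102206.0, 12252),
        AgeBand("45-64", 45, 64, 0.1536, 102206.0, 40998),
        AgeBand("65-74", 65, 74, 0.2326, 102206.0, 31775),
        AgeBand("75+", 75, None, 0.3303, 99307.0, 27855),
    )


@dataclass(frozen=True)
class EpidemiologyInputs:
    age_bands: tuple[AgeBand, ...] = field(default_factory=_default_age_bands)
    medicare_share_under65: float = 0.55
    medicare_share_range: tuple[float, float] = (0.50, 0.60)

    def __post_init__(self) -> None:
        _require(0.0 <= self.medicare_share_under65 <= 1.0,
                 "medicare_share_under65", "must be in [0, 1]")
        _require(len(self.age_bands) > 0, "age_bands", "must not be empty")
        bands = sorted(self.age_bands, key=lambda b: b.lower_age)
        for prev, nxt in zip(bands, bands[1:]):
            _require(prev.upper_age is not None and nxt.lower_age == prev.upper_age + 1,
                     "age_bands", "must partition ages without gaps or overlap")
        _require(bands[-1].upper_age is None, "age_bands", "last band must be open-ended")

    def band_for_age(self, age: float) -> AgeBand:
        for band in self.age_bands:
            if band.contains(age):
                return band
        raise ConfigurationError(f"no age band covers age {age}")


_FAMILIES = {"fixed", "beta", "gamma", "lognormal", "uniform", "beta_pert", "normal"}

_REQUIRED_PARAMS = {
    "fixed": {"value"},
    "beta": {"alpha", "beta"},
    "gamma": {"shape", "scale"},
    "lognormal": {"ln_mu", "ln_sigma"},
    "uniform": {"low", "high"},
    "beta_pert": {"minimum", "mode", "maximum"},
    "normal": {"mu", "sigma"},
}


@dataclass(frozen=True)
class DistributionSpec:
    """Family + named parameters + optional support for one uncertain input."""

    family: str
    params: Mapping[str, float]
    support: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        missing = _REQUIRED_PARAMS[self.family] - set(self.params)
        if missing:
            raise ConfigurationError(
                f"{self.family} distribution missing parameters: {sorted(missing)}")
        p = self.params
        if self.family == "beta" and (p["alpha"] <= 0 or p["beta"] <= 0):
            raise ConfigurationError("beta shapes must be > 0")
        if self.family == "gamma" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise ConfigurationError("gamma shape and scale must be > 0")
        if self.family == "lognormal" and p["ln_sigma"] < 0:
            raise ConfigurationError("lognormal ln_sigma must be >= 0")
        if self.family == "normal" and p["sigma"] < 0:
            raise ConfigurationError("normal sigma must be >= 0")
        if self.family == "uniform" and p["low"] > p["high"]:
            raise ConfigurationError("uniform low must be <= high")
        if self.family == "beta_pert":
            if not (p["minimum"] <= p["mode"] <= p["maximum"]):
                raise ConfigurationError("beta_pert requires minimum <= mode <= maximum")
            if p["minimum"] >= p["maximum"]:
                raise ConfigurationError("beta_pert requires minimum < maximum")
        if self.support is not None and self.support[0] > self.support[1]:
            raise ConfigurationError("support min must be <= max")


@dataclass(frozen=True)
class ParameterSet:
    """One complete, immutable snapshot of every model input."""

    clinical: ClinicalEffectInputs = field(default_factory=ClinicalEffectInputs)
    economic: EconomicInputs = field(default_factory=EconomicInputs)
    provider: ProviderInputs = field(default_factory=ProviderInputs)
    epidemiology: EpidemiologyInputs = field(default_factory=EpidemiologyInputs)
    utility_premium_enabled: bool = False
    utility_premium: float = 0.005                     # delta-u per in-range unit

    def __post_init__(self) -> None:
        _require(0.0 <= self.utility_premium <= 1.0, "utility_premium", "must be in [0, 1]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj

        return {
            "clinical": convert(self.clinical),
            "economic": convert(self.economic),
            "provider": convert(self.provider),
            "epidemiology": convert(self.epidemiology),
            "utility_premium_enabled": self.utility_premium_enabled,
            "utility_premium": self.utility_premium,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        def tup(value: Any) -> Any:
            return tuple(value) if isinstance(value, (list, tuple)) else value

        clin = {k: tup(v) for k, v in data["clinical"].items()}
        econ = {k: tup(v) for k, v in data["economic"].items()}
        prov = {k: tup(v) for k, v in data["provider"].items()}
        epi_raw = dict(data["epidemiology"])
        bands = tuple(AgeBand(**b) for b in epi_raw.pop("age_bands"))
        epi = {"age_bands": bands, **{k: tup(v) for k, v in epi_raw.items()}}
        return cls(
            clinical=ClinicalEffectInputs(**clin),
            economic=EconomicInputs(**econ),
            provider=ProviderInputs(**prov),
            epidemiology=EpidemiologyInputs(**epi),
            utility_premium_enabled=data.get("utility_premium_enabled", False),
            utility_premium=data.get("utility_premium", 0.005),
        )


# ---------------------------------------------------------------------------
# Flat configuration overlay
# ---------------------------------------------------------------------------

_SECTION_FIELDS: dict[str, tuple[str, type]] = {}
for _section, _cls in (("clinical", ClinicalEffectInputs),
                       ("economic", EconomicInputs),
                       ("provider", ProviderInputs)):
    for _f in dataclasses.fields(_cls):
        _SECTION_FIELDS[_f.name] = (_section, _cls)
for _f in dataclasses.fields(EpidemiologyInputs):
    if _f.name != "age_bands":
        _SECTION_FIELDS[_f.name] = ("epidemiology", EpidemiologyInputs)

_TOP_LEVEL_KEYS = {"utility_premium_enabled", "utility_premium"}


def default_parameters() -> ParameterSet:
    """The embedded base-case parameter set."""
    return ParameterSet()


def load_parameters(
    config_source: str | Path | Mapping[str, Any] | None = None,
) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults plus an optional overlay.

    ``config_source`` may be a path to a flat YAML document, a mapping, or
    ``None`` (pure defaults).  Recognized keys are the field names of the
    input dataclasses plus ``age_bands`` (a list of band mappings) and the
    two scenario flags.  Unknown keys raise :class:`ConfigurationError`;
    invalid values raise :class:`ValidationError`.
    """
    if config_source is None:
        return ParameterSet()

    if isinstance(config_source, (str, Path)):
        text = Path(config_source).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, Mapping):
            raise ConfigurationError("configuration document must be a mapping")
    else:
        overrides = dict(config_source)

    sections: dict[str, dict[str, Any]] = {
        "clinical": {}, "economic": {}, "provider": {}, "epidemiology": {}}
    top: dict[str, Any] = {}

    for key, value in overrides.items():
        if key in _TOP_LEVEL_KEYS:
            top[key] = value
        elif key == "age_bands":
            sections["epidemiology"]["age_bands"] = tuple(
                AgeBand(**dict(b)) for b in value)
        elif key in _SECTION_FIELDS:
            section, _ = _SECTION_FIELDS[key]
            if isinstance(value, (list, tuple)):
                value = tuple(value)
            sections[section][key] = value
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")

    return ParameterSet(
        clinical=ClinicalEffectInputs(**sections["clinical"]),
        economic=EconomicInputs(**sections["economic"]),
        provider=ProviderInputs(**sections["provider"]),
        epidemiology=EpidemiologyInputs(**sections["epidemiology"]),
        **top,
    )


def with_overrides(params: ParameterSet, **flat: Any) -> ParameterSet:
    """Return a copy of ``params`` with flat-key overrides applied."""
    merged = params.to_dict()
    for key, value in flat.items():
        if key in _TOP_LEVEL_KEYS:
            merged[key] = value
        elif key == "age_bands":
            merged["epidemiology"]["age_bands"] = [
                dataclasses.asdict(b) if dataclasses.is_dataclass(b) else dict(b)
                for b in value]
        elif key in _SECTION_FIELDS:
            section, _ = _SECTION_FIELDS[key]
            merged[section][key] = value
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    return ParameterSet.from_dict(merged)
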