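"""Configuration objects and demographic constants.

Age bands follow the reporting bands used throughout the package
(0-9, 10-17, 18-26, 27-35, 36-45, >=46 years).  Default demographic mixes
mirror a commercially insured, genetically screened carrier population:
predominantly adult women screened during reproductive care, against a CF
population skewed much younger and balanced by sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

# (label, low, high) in years; the top band is open-ended, capped for sampling.
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("0-9", 0, 9),
    ("10-17", 10, 17),
    ("18-26", 18, 26),
    ("27-35", 27, 35),
    ("36-45", 36, 45),
    ("46+", 46, 64),
)
AGE_BAND_LABELS: tuple[str, ...] = tuple(b[0] for b in AGE_BANDS)

DEFAULT_ORGAN_SYSTEMS: tuple[str, ...] = (
    "respiratory",
    "gastrointestinal",
    "endocrine",
    "hepatobiliary",
    "reproductive",
    "musculoskeletal",
    "infectious",
    "metabolic",
)

# Age mix of a screened carrier cohort (mass on reproductive-age women) and of a
# CF cohort (mass on children); probabilities over AGE_BAND_LABELS.
CARRIER_AGE_DIST: dict[str, float] = {
    "0-9": 0.084, "10-17": 0.036, "18-26": 0.243,
    "27-35": 0.497, "36-45": 0.123, "46+": 0.017,
}
CF_AGE_DIST: dict[str, float] = {
    "0-9": 0.271, "10-17": 0.196, "18-26": 0.205,
    "27-35": 0.135, "36-45": 0.092, "46+": 0.101,
}
CARRIER_SEX_DIST: dict[str, float] = {"F": 0.814, "M": 0.186}
CF_SEX_DIST: dict[str, float] = {"F": 0.514, "M": 0.486}

MAX_ENROLL_MONTHS = 204


def age_band_of(ages) -> np.ndarray:
    """Map integer ages (years) to reporting band labels."""
    ages = np.asarray(ages)
    edges = [b[2] for b in AGE_BANDS[:-1]]  # upper edges of closed bands
    idx = np.searchsorted(edges, ages, side="left")
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def _check_dist(name: str, dist: Mapping[str, float], labels: Sequence[str]) -> None:
    if set(dist) != set(labels):
        raise ConfigurationError(f"{name}: categories {sorted(dist)} != {sorted(labels)}")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {total}, not 1")
    if any(v < 0 for v in dist.values()):
        raise ConfigurationError(f"{name}: negative probability")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic catalog / population generator.

    Condition occurrence is a single ever-diagnosed Bernoulli per subject and
    condition, with log-odds
    ``logit(p0) + beta*carrier + gamma*cf + frailty + delta*log(months/median)``.
    Carrier effects are an attenuated noisy copy of CF effects:
    ``beta = attenuation_lambda * gamma + Normal(0, attenuation_noise_sd)``.
    """

    n_carriers: int = 2000
    n_cf: int = 2000
    n_control_pool: int = 60000
    n_conditions: int = 59
    organ_systems: tuple[str, ...] = DEFAULT_ORGAN_SYSTEMS
    p0_range: tuple[float, float] = (0.0005, 0.15)
    beta_cf_range: tuple[float, float] = (0.5, 3.0)
    attenuation_lambda: float = 0.22
    attenuation_noise_sd: float = 0.15
    frailty_sd: float = 0.5
    enroll_exposure_coef: float = 0.5  # delta on log(months / median months)
    contamination_count: int = 0  # latent-CF subjects labelled group=carrier
    n_female_only: int = 2
    n_male_only: int = 2
    n_adult_only: int = 4  # conditions with min_age_years = 18
    family_link_rate: float = 0.01  # controls sharing a family with a carrier/CF subject
    suspicion_base: float = 0.05
    suspicion_extra: float = 0.0  # added for carriers with a condition in suspicion_system
    suspicion_system: str = "respiratory"
    sex_distribution: dict[str, float] = field(default_factory=lambda: dict(CARRIER_SEX_DIST))
    age_distribution: dict[str, float] = field(default_factory=lambda: dict(CARRIER_AGE_DIST))
    cf_sex_distribution: dict[str, float] = field(default_factory=lambda: dict(CF_SEX_DIST))
    cf_age_distribution: dict[str, float] = field(default_factory=lambda: dict(CF_AGE_DIST))
    enroll_median_months: float = 42.0
    enroll_log_sd: float = 0.63
    cf_enroll_median_months: float = 33.0
    cf_enroll_log_sd: float = 0.758
    n_family_pairs: int = 2185
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        for fld in ("n_carriers", "n_cf", "n_control_pool", "n_conditions"):
            if int(getattr(self, fld)) < 1:
                raise ConfigurationError(f"{fld} must be a positive integer")
        lo, hi = self.p0_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("p0_range must satisfy 0 < lo <= hi < 1")
        if self.beta_cf_range[0] < 0:
            raise ConfigurationError("beta_cf_range must be nonnegative (risk-increasing)")
        if self.attenuation_noise_sd < 0:
            raise ConfigurationError("attenuation_noise_sd must be nonnegative")
        if self.frailty_sd < 0:
            raise ConfigurationError("frailty_sd must be nonnegative")
        if self.contamination_count < 0 or self.contamination_count > self.n_carriers:
            raise ConfigurationError("contamination_count must lie in [0, n_carriers]")
        if not 0.0 <= self.family_link_rate < 1.0:
            raise ConfigurationError("family_link_rate must lie in [0, 1)")
        if self.n_female_only + self.n_male_only > self.n_conditions:
            raise ConfigurationError("n_female_only + n_male_only exceeds n_conditions")
        _check_dist("sex_distribution", self.sex_distribution, ("F", "M"))
        _check_dist("age_distribution", self.age_distribution, AGE_BAND_LABELS)
        _check_dist("cf_sex_distribution", self.cf_sex_distribution, ("F", "M"))
        _check_dist("cf_age_distribution", self.cf_age_distribution, AGE_BAND_LABELS)
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["organ_systems"] = list(self.organ_systems)
        d["p0_range"] = list(self.p0_range)
        d["beta_cf_range"] = list(self.beta_cf_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("organ_systems",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("p0_range", "beta_cf_range"):
            if key in kwargs:
                kwargs[key] = tuple(float(x) for x in kwargs[key])
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()


@dataclass(frozen=True)
class MatchPolicy:
    """Eligibility policy for control selection.

    Matching keys are sex, age band and months of enrollment; enrollment is
    matched exactly by default with an optional +/- tolerance in months.
    Controls from families that contain a carrier or CF subject are excluded.
    """

    months_tolerance: int = 0
    exclude_linked_families: bool = True

    def __post_init__(self):
        if self.months_tolerance < 0:
            raise ConfigurationError("months_tolerance must be nonnegative")
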