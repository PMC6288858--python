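"""Configuration objects for the synthetic world, the linkage engine, and experiments.

All dates are integer days since an arbitrary epoch (day 0 = 2010-01-01); the
epoch is never interpreted, only differences in days matter.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

# day indices of the enrolment window (~Dec 2014 .. Oct 2017 on the nominal epoch)
STUDY_START_DAY = 1800
STUDY_END_DAY = 2860
EPOCH_YEAR = 2010

SOURCES = ("sero_survey", "HTC", "ANC")

#: identifier fields scored by the linkage engine
NAME_FIELDS = ("name", "tcl_name", "hh_member_name")
EXACT_FIELDS = ("sex", "birth_year", "birth_month", "birth_day", "village", "sub_village")
ALL_FIELDS = NAME_FIELDS + EXACT_FIELDS


class ConfigurationError(ValueError):
    """Raised when a config value is out of range; the message names the field."""


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigurationError(message)


@dataclass
class PopulationConfig:
    """Shape of the synthetic HDSS registry.

    Households are grouped into ten-cell-leader clusters; every member of a
    household shares household id, sub-village, leader names and coordinates.
    """

    n_people: int = 4000
    mean_household_size: float = 3.5
    households_per_tcl: int = 10
    name_zipf_exponent: float = 1.0
    #: fraction of persons with a second (non-overlapping) residency episode
    two_episode_rate: float = 0.05
    #: fraction whose single episode does not span the whole study window
    partial_residency_rate: float = 0.08
    # registry-side identifier completeness (the surveillance database itself
    # has small amounts of missingness)
    registry_completeness: dict = field(
        default_factory=lambda: {
            "birth_year": 0.994,
            "birth_month": 0.99,
            "birth_day": 0.99,
            "tcl_name": 0.994,
            "hh_member_name": 0.999,
        }
    )

    def validate(self) -> "PopulationConfig":
        _check(self.n_people > 0, f"n_people must be positive, got {self.n_people}")
        _check(self.mean_household_size > 0, "mean_household_size must be positive")
        _check(self.households_per_tcl > 0, "households_per_tcl must be positive")
        for k, v in self.registry_completeness.items():
            _check(0.0 <= v <= 1.0, f"registry_completeness[{k}] not in [0, 1]")
        return self


def _default_completeness() -> dict:
    # Per-source probability that each identifier is present on an encounter.
    # Sero-survey and clinic profiles reflect the observed completeness of
    # matching identifiers in community-survey vs clinic paper registers;
    # month/day of birth are free parameters (not tabulated anywhere).
    sero = {
        "name_1": 1.0, "name_2": 1.0, "name_3": 0.133,
        "birth_year": 1.0, "birth_month": 0.70, "birth_day": 0.70,
        "sex": 1.0, "village": 1.0, "sub_village": 1.0,
        "tcl_name_1": 0.483, "tcl_name_2": 0.483,
        "hh_member_name_1": 0.715, "hh_member_name_2": 0.715,
    }
    clinic = {
        "name_1": 1.0, "name_2": 1.0, "name_3": 0.887,
        "birth_year": 1.0, "birth_month": 0.70, "birth_day": 0.70,
        "sex": 1.0, "village": 0.993, "sub_village": 0.993,
        "tcl_name_1": 0.915, "tcl_name_2": 0.746,
        "hh_member_name_1": 0.113, "hh_member_name_2": 0.113,
    }
    return {"sero_survey": sero, "HTC": dict(clinic), "ANC": dict(clinic)}


@dataclass
class CorruptionConfig:
    """Error model applied when a person's identity is transcribed onto an encounter.

    ``typo_rate`` is the per-name probability of a single random character
    substitution, transposition or deletion; ``name_swap_rate`` exchanges the
    first two personal names; birth year receives a discrete-normal shift with
    probability ``birth_year_error_rate``.
    """

    field_completeness: dict = field(default_factory=_default_completeness)
    typo_rate: float = 0.20
    name_swap_rate: float = 0.10
    birth_year_error_rate: float = 0.65
    birth_year_error_sd: float = 5.0
    # wrong-value ("identity drift") rates: the recorded value is a different
    # value entirely — an alias name, a guessed birth date, an out-of-date
    # residence. These, not typos, are what drags true-match scores down in
    # low-data-quality settings (a single-edit typo usually still clears the
    # Jaro-Winkler agreement bar).
    name_replace_rate: float = 0.45
    tcl_replace_rate: float = 0.55
    hh_member_replace_rate: float = 0.45
    birth_month_day_error_rate: float = 0.40
    geography_error_rate: float = 0.30
    sex_error_rate: float = 0.02

    def validate(self) -> "CorruptionConfig":
        for p, name in (
            (self.typo_rate, "typo_rate"),
            (self.name_swap_rate, "name_swap_rate"),
            (self.birth_year_error_rate, "birth_year_error_rate"),
            (self.name_replace_rate, "name_replace_rate"),
            (self.tcl_replace_rate, "tcl_replace_rate"),
            (self.hh_member_replace_rate, "hh_member_replace_rate"),
            (self.birth_month_day_error_rate, "birth_month_day_error_rate"),
            (self.geography_error_rate, "geography_error_rate"),
            (self.sex_error_rate, "sex_error_rate"),
        ):
            _check(0.0 <= p <= 1.0, f"{name} not in [0, 1], got {p}")
        _check(self.birth_year_error_sd >= 0, "birth_year_error_sd must be >= 0")
        for source, fields_ in self.field_completeness.items():
            _check(source in SOURCES, f"unknown source {source!r} in field_completeness")
            for f, p in fields_.items():
                _check(0.0 <= p <= 1.0, f"field_completeness[{source}][{f}] not in [0, 1]")
        return self

    @classmethod
    def perfect(cls) -> "CorruptionConfig":
        """No missingness, no errors — encounters copy identities verbatim."""
        comp = {s: {k: 1.0 for k in f} for s, f in _default_completeness().items()}
        return cls(field_completeness=comp, typo_rate=0.0, name_swap_rate=0.0,
                   birth_year_error_rate=0.0, name_replace_rate=0.0,
                   tcl_replace_rate=0.0, hh_member_replace_rate=0.0,
                   birth_month_day_error_rate=0.0, geography_error_rate=0.0,
                   sex_error_rate=0.0)


@dataclass
class OutcomeConfig:
    """Proportional-hazards generator for time from HIV diagnosis to care registration.

    The exposure is testing modality: community sero-survey (reference) vs
    walk-in clinic (HTC or ANC pooled). The baseline daily hazard of 0.0019
    gives ~16% of sero-survey diagnoses registering within the 90-day
    administrative horizon, matching the reference cohort's gold-standard
    registration proportion.
    """

    cohort_size: int = 405
    #: fraction of diagnoses made in the sero-survey (263 of 405 in the reference cohort)
    sero_fraction: float = 263 / 405
    #: fraction of clinic diagnoses made at the HTC rather than the ANC (126/142)
    htc_fraction: float = 126 / 142
    true_log_hr_modality: float = math.log(5.0)
    covariate_log_hrs: dict = field(
        default_factory=lambda: {
            ("sex", "M"): 0.10,
            ("age_group", "30-39"): 0.00,
            ("age_group", "40-49"): -0.10,
            ("age_group", "50+"): -0.20,
            ("rurality", "peri_urban"): 0.10,
            ("rurality", "urban"): 0.20,
            ("paved_road", True): 0.10,
            ("distance_band", "1-1.9"): -0.05,
            ("distance_band", "2-4.9"): -0.10,
            ("distance_band", "5-11"): -0.20,
        }
    )
    baseline_hazard_rate: float = 0.0019  # events/day
    death_rate: float = 2e-4  # events/day after diagnosis
    admin_censor_days: int = 90
    #: probability an undiagnosed registry person nevertheless has a CTC
    #: registration date inside the study window (background clinic traffic —
    #: what a falsely linked encounter can inherit)
    background_registration_prob: float = 0.03
    # rates of deliberately ineligible extra encounters, relative to cohort_size
    under15_rate: float = 0.05
    repeat_tester_rate: float = 0.05
    nonresident_rate: float = 0.05

    def validate(self) -> "OutcomeConfig":
        _check(self.cohort_size > 0, f"cohort_size must be positive, got {self.cohort_size}")
        _check(0.0 <= self.sero_fraction <= 1.0, "sero_fraction not in [0, 1]")
        _check(0.0 <= self.htc_fraction <= 1.0, "htc_fraction not in [0, 1]")
        for r, name in (
            (self.baseline_hazard_rate, "baseline_hazard_rate"),
            (self.death_rate, "death_rate"),
        ):
            _check(r >= 0, f"{name} must be nonnegative")
        _check(self.admin_censor_days > 0, "admin_censor_days must be positive")
        return self


# fallback u-probabilities (field agreement rate among non-matches) used when
# no empirical estimate is requested; rough magnitudes for a finite name pool
DEFAULT_U = {
    "name": 0.05,
    "tcl_name": 0.08,
    "hh_member_name": 0.05,
    "sex": 0.5,
    "birth_year": 0.02,
    "birth_month": 1 / 12,
    "birth_day": 1 / 30,
    "village": 0.2,
    "sub_village": 0.05,
}

DEFAULT_M = {
    "name": 0.9,
    "tcl_name": 0.9,
    "hh_member_name": 0.9,
    "sex": 0.95,
    "birth_year": 0.9,
    "birth_month": 0.9,
    "birth_day": 0.9,
    "village": 0.95,
    "sub_village": 0.95,
}


@dataclass
class MatchParams:
    """Fellegi–Sunter parameters: per-field m/u probabilities and the name comparator."""

    m: dict = field(default_factory=lambda: dict(DEFAULT_M))
    u: dict = field(default_factory=lambda: dict(DEFAULT_U))
    jw_agreement_threshold: float = 0.85
    winkler_prefix_scale: float = 0.1
    winkler_max_prefix: int = 4
    log_base: float = 2.0

    def validate(self) -> "MatchParams":
        for f in ALL_FIELDS:
            _check(f in self.m, f"missing m probability for field {f}")
            _check(f in self.u, f"missing u probability for field {f}")
            m, u = self.m[f], self.u[f]
            _check(0.0 < u < 1.0, f"u[{f}] must be in (0, 1), got {u}")
            _check(0.0 < m < 1.0, f"m[{f}] must be in (0, 1), got {m}")
            _check(m > u, f"m[{f}]={m} must exceed u[{f}]={u}: agreement must be evidence for a match")
        _check(0.0 <= self.jw_agreement_threshold <= 1.0, "jw_agreement_threshold not in [0, 1]")
        _check(self.log_base > 1.0, "log_base must exceed 1")
        return self


#: threshold labels by percentile of the true-match score distribution
THRESHOLD_PERCENTILES = {"minimum": 0, "low": 25, "medium": 50, "high": 75}


@dataclass
class ExperimentConfig:
    """Everything needed to re-run a generate → link → evaluate → analyse experiment."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    match: MatchParams = field(default_factory=MatchParams)
    percentiles: dict = field(default_factory=lambda: dict(THRESHOLD_PERCENTILES))
    #: estimate u probabilities empirically from random record pairs
    estimate_u: bool = True
    adjusters: Sequence[str] = ("age_group", "sex", "rurality", "paved_road", "distance_band")
    blocking: bool = False
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        self.population.validate()
        self.corruption.validate()
        self.outcome.validate()
        self.match.validate()
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        return self

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuple-keyed covariate_log_hrs -> "covariate:level" strings for YAML
        d["outcome"]["covariate_log_hrs"] = {
            f"{k[0]}:{k[1]}": v for k, v in self.outcome.covariate_log_hrs.items()
        }
        d["adjusters"] = list(self.adjusters)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        pop = PopulationConfig(**d.get("population", {}))
        cor = CorruptionConfig(**d.get("corruption", {}))
        out_d = dict(d.get("outcome", {}))
        if "covariate_log_hrs" in out_d:
            parsed = {}
            for k, v in out_d["covariate_log_hrs"].items():
                cov, level = k.split(":", 1)
                if cov == "paved_road":
                    level = level in ("True", "true", "1")
                parsed[(cov, level)] = v
            out_d["covariate_log_hrs"] = parsed
        out = OutcomeConfig(**out_d)
        match = MatchParams(**d.get("match", {}))
        kwargs = {
            k: d[k]
            for k in ("percentiles", "estimate_u", "adjusters", "blocking", "n_replicates", "seed")
            if k in d
        }
        return cls(population=pop, corruption=cor, outcome=out, match=match, **kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
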