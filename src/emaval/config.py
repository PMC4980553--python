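"""Configuration objects for the cohort generator and the analysis filters.

Two dataclasses live here: :class:`CohortConfig`, which fixes the study
conditions the synthetic cohort emulates (prompt schedule, eating process,
recall error, activity misreporting, accelerometer count distributions),
and :class:`FilterThresholds`, the exclusion constants applied by the
ingest filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import time
from typing import Sequence

import numpy as np

#: Closed food-group vocabulary shared by momentary reports and recall coding.
FOOD_GROUPS = (
    "sweets",
    "salty",
    "fruits_vegetables",
    "entree",
    "breads_grains",
    "other",
)

#: The five named groups that enter the match statistics ("other" is carried
#: through ingest but excluded from reporting).
NAMED_FOOD_GROUPS = FOOD_GROUPS[:-1]

#: Ordered intensity vocabulary. The instrument's "strenuous" label is
#: unified with "vigorous" throughout.
PA_LEVELS = ("sedentary", "light", "moderate", "vigorous")

BEHAVIORS = ("eating", "drinking", "physically_active", "none")

SEDENTARY_ACTIVITIES = (
    "sleeping",
    "browsing_internet",
    "social_media",
    "tv_movie",
    "video_games",
    "texting",
    "class_studying",
    "working",
    "hanging_out",
    "other",
)


class ConfigurationError(ValueError):
    """Raised when a cohort or threshold configuration violates an invariant."""


def _as_time(value) -> time:
    if isinstance(value, time):
        return value
    if isinstance(value, str):
        hh, mm = value.split(":")
        return time(int(hh), int(mm))
    raise ConfigurationError(f"cannot interpret {value!r} as a clock time")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the validation study's design: 8 prompts/day (two per
    time block, the last of the day retrospective) over 4 days, up to three
    recall days per participant, Freedson-band count distributions, and a
    misreporting structure under which self-reported intensity agrees well
    for sedentary time and poorly above it.

    Parameters
    ----------
    n_participants : int
        Cohort size. Default 41, the activity-arm analytic sample.
    n_days : int
        Monitoring days per participant (default 4, Wednesday-Saturday).
    prompts_per_block : int
        Prompts drawn uniformly within each daily time block (default 2).
    time_blocks : sequence of (start, end) clock times
        Four non-overlapping daily windows, default 09-12, 12-15, 15-19,
        19-22.
    eating_rate : float
        Mean true eating occasions per participant-day (Poisson), default
        3.7 — the recall-instance density observed in the study
        (607 instances / 163 participant-days).
    food_group_probs : 6-vector
        Multinomial over :data:`FOOD_GROUPS` for true eating occasions.
    recall_omission_prob : float
        Probability a true eating occasion is absent from the recall table.
    recall_time_sd_min : float
        SD (minutes) of the centred Gaussian displacement applied to recall
        clock times, emulating misremembered eating times.
    pa_level_probs : 4-vector
        Marginal distribution of true intensity during wear time.
    misreport_matrix : 4x4 row-stochastic
        P(reported level | true level); default derived from the observed
        column-conditioned agreement pattern (strong sedentary agreement,
        heavy sedentary-ward misreporting above it).
    count_params : mapping level -> (log_mu, log_sigma)
        Lognormal parameters of the epoch count distribution per true level;
        draws are truncated to the level's cut-point band except for a
        ``count_spillover`` mass drawn unconstrained.
    count_spillover : float
        Probability mass allowed to spill outside the generating band.
    day_kcal_range : (float, float)
        Uniform range for plausible recall-day energy.
    implausible_kcal_prob : float
        Probability a recall day draws an implausible energy total
        (mostly < 500 kcal, matching the study's observed exclusions).
    recall_days_probs : 3-vector
        P(participant completes 1, 2, 3 recall days); default matches the
        reported 38/37/17 split.
    prompt_response_prob : float
        Probability a delivered prompt is answered (survey completed).
    eating_report_window_min : float
        A completed real-time prompt endorses the food groups of true
        occasions within this many minutes before it (each occasion is
        credited to at most one prompt).
    nonwear_hours : float
        Hours of device non-wear (all-zero epochs) at the start of each day.
    activity_bout_min : int
        Length in minutes of constant-intensity bouts in the true track.
    drinking_prob : float
        Per-prompt probability of endorsing drinking (not analysed).
    p_female, p_white, p_pell : float
        Subgroup attribute prevalences for chi-square subgroup tests.
    seed : int
        Root seed; the generator is deterministic given config + seed.
    """

    n_participants: int = 41
    n_days: int = 4
    prompts_per_block: int = 2
    time_blocks: Sequence = (
        ("09:00", "12:00"),
        ("12:00", "15:00"),
        ("15:00", "19:00"),
        ("19:00", "22:00"),
    )
    eating_rate: float = 3.7
    food_group_probs: Sequence[float] = (0.20, 0.21, 0.18, 0.15, 0.20, 0.06)
    recall_omission_prob: float = 0.2
    recall_time_sd_min: float = 45.0
    pa_level_probs: Sequence[float] = (0.54, 0.41, 0.04, 0.01)
    misreport_matrix: Sequence[Sequence[float]] = (
        (0.914, 0.051, 0.030, 0.005),
        (0.736, 0.130, 0.071, 0.063),
        (0.432, 0.189, 0.243, 0.136),
        (0.050, 0.100, 0.150, 0.700),
    )
    count_params: dict = field(
        default_factory=lambda: {
            "sedentary": (3.4, 0.9),
            "light": (6.2, 0.7),
            "moderate": (8.05, 0.30),
            "vigorous": (8.92, 0.25),
        }
    )
    count_spillover: float = 0.05
    day_kcal_range: Sequence[float] = (1400.0, 3200.0)
    implausible_kcal_prob: float = 0.05
    recall_days_probs: Sequence[float] = (0.41, 0.40, 0.19)
    prompt_response_prob: float = 0.55
    eating_report_window_min: float = 30.0
    nonwear_hours: float = 7.0
    activity_bout_min: int = 30
    drinking_prob: float = 0.15
    p_female: float = 0.70
    p_white: float = 0.55
    p_pell: float = 0.35
    seed: int = 0

    _PROB_TOL = 1e-9

    def __post_init__(self):
        self.validate()

    def blocks(self) -> list[tuple[time, time]]:
        """Time blocks as ``datetime.time`` pairs, validated and ordered."""
        return [(_as_time(a), _as_time(b)) for a, b in self.time_blocks]

    def validate(self) -> None:
        if self.n_participants < 0 or self.n_days < 0 or self.prompts_per_block < 0:
            raise ConfigurationError("counts must be nonnegative")
        if self.eating_rate < 0 or self.recall_time_sd_min < 0:
            raise ConfigurationError("rates and SDs must be nonnegative")
        for name, vec, k in (
            ("food_group_probs", self.food_group_probs, len(FOOD_GROUPS)),
            ("pa_level_probs", self.pa_level_probs, len(PA_LEVELS)),
            ("recall_days_probs", self.recall_days_probs, 3),
        ):
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (k,) or (vec < 0).any():
                raise ConfigurationError(f"{name} must be a nonnegative {k}-vector")
            if abs(vec.sum() - 1.0) > self._PROB_TOL:
                raise ConfigurationError(f"{name} must sum to 1 (got {vec.sum()!r})")
        mat = np.asarray(self.misreport_matrix, dtype=float)
        if mat.shape != (4, 4) or (mat < 0).any():
            raise ConfigurationError("misreport_matrix must be a nonnegative 4x4 matrix")
        if np.abs(mat.sum(axis=1) - 1.0).max() > self._PROB_TOL:
            raise ConfigurationError("misreport_matrix rows must sum to 1")
        for p_name in (
            "recall_omission_prob",
            "count_spillover",
            "implausible_kcal_prob",
            "prompt_response_prob",
            "drinking_prob",
            "p_female",
            "p_white",
            "p_pell",
        ):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{p_name} must be in [0, 1]")
        blocks = self.blocks()
        if len(blocks) != 4:
            raise ConfigurationError("exactly four time blocks are required")
        prev_end = None
        for start, end in blocks:
            if start >= end:
                raise ConfigurationError(f"empty or inverted time block {start}-{end}")
            if prev_end is not None and start < prev_end:
                raise ConfigurationError("time blocks overlap or are out of order")
            prev_end = end
        missing = set(PA_LEVELS) - set(self.count_params)
        if missing:
            raise ConfigurationError(f"count_params missing levels: {sorted(missing)}")
        lo, hi = self.day_kcal_range
        if not 0 <= lo <= hi:
            raise ConfigurationError("day_kcal_range must be a nonnegative interval")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "time_blocks" in d:
            d["time_blocks"] = [tuple(b) for b in d["time_blocks"]]
        return cls(**d)


@dataclass
class FilterThresholds:
    """Exclusion constants for the analysis filters.

    kcal bounds form a closed interval [500, 5000] so that a recall day at
    exactly 500 kcal is retained. ``zero_window_min`` is the flank length
    around a prompt that, when entirely zero on either side, excludes the
    occasion. ``nonwear_zero_run_min`` is the consecutive-zero run length
    treated as device non-wear when computing daily wear time.
    """

    kcal_min: float = 500.0
    kcal_max: float = 5000.0
    zero_window_min: int = 30
    min_wear_hours: float = 5.0
    preprompt_avg_min: int = 5
    nonwear_zero_run_min: int = 60

    def __post_init__(self):
        if self.kcal_min > self.kcal_max:
            raise ConfigurationError("kcal_min must not exceed kcal_max")
        if min(self.zero_window_min, self.preprompt_avg_min, self.nonwear_zero_run_min) <= 0:
            raise ConfigurationError("window lengths must be positive")
        if self.min_wear_hours < 0:
            raise ConfigurationError("min_wear_hours must be nonnegative")

    @property
    def min_wear_minutes(self) -> float:
        return self.min_wear_hours * 60.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        return cls(**d)
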