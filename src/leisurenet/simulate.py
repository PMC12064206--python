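"""Synthetic time-use diary generator.

The restricted national survey microdata behind the motivating analysis
cannot be redistributed, so this module generates diaries with the same
*statistical* structure: two groups of adolescents stratified by subjective
well-being (SWB), each keeping one weekday and one weekend diary over a
fixed catalogue of leisure activities.

The design targets the qualitative contrast the analysis is about:

* the **high-SWB** group participates broadly — most activities have a
  moderate-to-high participation probability, so activity co-participation
  is dense and evenly spread;
* the **low-SWB** group is concentrated — a handful of universal
  activities (sleep, TV, video) plus latent "interest segments" that each
  boost one small block of activities, so co-participation is sparse,
  blocky and leaves many activities isolated.

Participation is Bernoulli per (respondent, day type, activity); durations
are lognormal and rounded to the 10-minute diary grid. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activities import DEFAULT_ACTIVITIES

__all__ = [
    "ConfigurationError",
    "GroupProfile",
    "SimulationConfig",
    "default_config",
    "generate_diaries",
    "inject_pathologies",
    "PATHOLOGY_KINDS",
]

HIGH = "high_swb"
LOW = "low_swb"
DAY_TYPES = ("weekday", "weekend")

#: canonical long-format diary schema, in column order
DIARY_COLUMNS = (
    "person_id",
    "age",
    "sex",
    "education",
    "swb_score",
    "health_score",
    "leisure_satisfaction",
    "day_type",
    "activity_code",
    "minutes",
)


class ConfigurationError(ValueError):
    """A simulation config field is invalid; the message names the field."""


@dataclass
class GroupProfile:
    """Participation profile for one SWB group.

    Parameters
    ----------
    group_label : {"high_swb", "low_swb"}
    n_respondents : int
        Number of diarists in the group (>= 0; 0 yields no records).
    activity_probs : array of shape (n_activities,)
        Marginal per-activity participation probability in [0, 1], used
        directly for homogeneous groups.
    minutes_mean, minutes_sd : float
        Mean and standard deviation (minutes) of the lognormal duration
        draw for one participated activity.
    day_type_shift : mapping day_type -> float
        Multiplicative adjustment of participation probabilities per day
        type; shifted probabilities are clipped to [0, 1].
    segment_probs : array of shape (n_segments, n_activities), optional
        Latent-interest segments. When given, each respondent is assigned
        one segment uniformly at random and participates according to that
        row; ``activity_probs`` must then equal the segment mean and is
        kept only as the marginal profile.
    """

    group_label: str
    n_respondents: int
    activity_probs: np.ndarray
    minutes_mean: float = 60.0
    minutes_sd: float = 45.0
    day_type_shift: dict[str, float] = field(
        default_factory=lambda: {"weekday": 1.0, "weekend": 1.0}
    )
    segment_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity_probs = np.asarray(self.activity_probs, dtype=float)
        if self.segment_probs is not None:
            self.segment_probs = np.asarray(self.segment_probs, dtype=float)

    def validate(self, n_activities: int) -> None:
        if self.group_label not in (HIGH, LOW):
            raise ConfigurationError(f"group_label: unknown label {self.group_label!r}")
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents: must be >= 0")
        if self.activity_probs.ndim != 1 or self.activity_probs.size != n_activities:
            raise ConfigurationError(
                f"activity_probs: expected length {n_activities}, "
                f"got shape {self.activity_probs.shape}"
            )
        if self.activity_probs.size == 0:
            raise ConfigurationError("activity_probs: empty profile")
        if np.any(self.activity_probs < 0) or np.any(self.activity_probs > 1):
            raise ConfigurationError("activity_probs: values must lie in [0, 1]")
        if not (self.minutes_mean > 0):
            raise ConfigurationError("minutes_mean: must be > 0")
        if not (self.minutes_sd > 0):
            raise ConfigurationError("minutes_sd: must be > 0")
        for day_type in DAY_TYPES:
            if day_type not in self.day_type_shift:
                raise ConfigurationError(f"day_type_shift: missing {day_type!r}")
            if self.day_type_shift[day_type] < 0:
                raise ConfigurationError("day_type_shift: must be >= 0")
        if self.segment_probs is not None:
            if self.segment_probs.ndim != 2 or self.segment_probs.shape[1] != n_activities:
                raise ConfigurationError(
                    "segment_probs: expected shape (n_segments, n_activities)"
                )
            if np.any(self.segment_probs < 0) or np.any(self.segment_probs > 1):
                raise ConfigurationError("segment_probs: values must lie in [0, 1]")

    def shifted_probs(self, day_type: str) -> np.ndarray:
        """Per-segment (or marginal) probabilities adjusted for a day type."""
        base = self.segment_probs if self.segment_probs is not None else self.activity_probs
        return np.clip(base * self.day_type_shift[day_type], 0.0, 1.0)


#: valid (swb, health) score ranges per group, inclusive bounds
_SCORE_BOUNDS = {HIGH: ((1, 4), (1, 2)), LOW: ((5, 7), (3, 5))}


@dataclass
class SimulationConfig:
    """Full specification of one synthetic diary dataset."""

    activities: tuple[str, ...] = DEFAULT_ACTIVITIES
    profiles: dict[str, GroupProfile] = field(default_factory=dict)
    seed: int = 0
    score_rules: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {
            HIGH: {"swb": (1, 4), "health": (1, 2)},
            LOW: {"swb": (5, 7), "health": (3, 5)},
        }
    )
    #: diary days recorded per day type; multiple days are aggregated into
    #: one row per (person, day_type, activity) with summed minutes
    diary_days: int = 1

    @property
    def n_activities(self) -> int:
        return len(self.activities)

    def validate(self) -> None:
        if self.n_activities < 2:
            raise ConfigurationError("activities: need at least 2 activity items")
        if self.diary_days < 1:
            raise ConfigurationError("diary_days: must be >= 1")
        if set(self.profiles) != {HIGH, LOW}:
            raise ConfigurationError(
                f"profiles: expected exactly {{{HIGH!r}, {LOW!r}}}, got {set(self.profiles)}"
            )
        for label, profile in self.profiles.items():
            if profile.group_label != label:
                raise ConfigurationError("profiles: key does not match group_label")
            profile.validate(self.n_activities)
        for label, rule in self.score_rules.items():
            (swb_lo, swb_hi), (h_lo, h_hi) = _SCORE_BOUNDS[label]
            r_swb, r_h = rule["swb"], rule["health"]
            if not (swb_lo <= r_swb[0] <= r_swb[1] <= swb_hi):
                raise ConfigurationError(f"score_rules[{label}]['swb']: outside [{swb_lo},{swb_hi}]")
            if not (h_lo <= r_h[0] <= r_h[1] <= h_hi):
                raise ConfigurationError(f"score_rules[{label}]['health']: outside [{h_lo},{h_hi}]")


def _tiered_probs(tiers: dict[float, list[str]], activities: tuple[str, ...],
                  base: float = 0.0) -> np.ndarray:
    probs = np.full(len(activities), base, dtype=float)
    index = {a: i for i, a in enumerate(activities)}
    for p, names in tiers.items():
        for name in names:
            probs[index[name]] = p
    return probs


_HIGH_CORE = [
    "Sleeping", "Face-to-face socializing", "Video/audio calls",
    "Community participation", "Watching video", "Mobile games",
    "Doing nothing and resting", "Watching live TV",
    "Travel related to cultural and leisure activities",
]
_HIGH_REGULAR = [
    "Text messages or e-mails", "Socializing via social networking services",
    "Searching the Internet", "PC games", "Group games/play", "Reading books",
    "Walking/strolling", "Personal exercises", "Purchasing goods offline",
    "Purchasing goods online", "Pet care", "Listening to audio devices",
    "Sleeplessness", "Cultural and tourism activities",
    "Travel related to socializing and community participation",
    "Attendance at religious meetings/gatherings",
]
_HIGH_OCCASIONAL = [
    "Ball games", "Team sports", "Hobbies", "Board games", "Jogging/running",
    "Biking and inline skating", "Dancing", "Arts and crafts",
    "Playing musical instruments", "Singing/karaoke",
    "Drinking alcohol/social drinking", "Window shopping",
    "Visiting family/relatives", "Watching sports events",
]

_LOW_UNIVERSAL = {
    "Sleeping": 0.95, "Watching live TV": 0.45, "Watching video": 0.45,
    "Doing nothing and resting": 0.40,
}
#: latent interest segments of the low-SWB group; each boosts one block
_LOW_SEGMENTS = {
    "screen": [
        "Mobile games", "PC games", "Searching the Internet",
        "Socializing via social networking services",
        "Text messages or e-mails", "Group games/play",
    ],
    "social": [
        "Face-to-face socializing", "Video/audio calls",
        "Community participation",
        "Travel related to socializing and community participation",
        "Purchasing goods offline", "Attendance at religious meetings/gatherings",
    ],
    "rest": [
        "Reading books", "Listening to audio devices", "Purchasing goods online",
        "Pet care", "Sleeplessness", "Personal religious practice",
    ],
    "outdoor": [
        "Personal exercises", "Walking/strolling", "Ball games", "Hobbies",
        "Biking and inline skating", "Cultural and tourism activities",
    ],
}
_LOW_BASE = 0.03
_LOW_BLOCK = 0.55


def default_config(seed: int = 0, n_respondents: int = 241) -> SimulationConfig:
    """The default two-group study design (241 diarists per group).

    High-SWB participation is tiered (core 0.80, regular 0.50, occasional
    0.30, rare 0.15) with less leisure on weekdays (x0.85) and more on
    weekends (x1.10). Low-SWB participation is 0.95/0.45/0.45/0.40 for the
    four universal activities, 0.55 within the respondent's interest
    segment, and 0.03 elsewhere, nearly identical across day types.
    """
    activities = DEFAULT_ACTIVITIES
    high_probs = _tiered_probs(
        {0.80: _HIGH_CORE, 0.50: _HIGH_REGULAR, 0.30: _HIGH_OCCASIONAL},
        activities, base=0.15,
    )
    low_base = _tiered_probs(
        {p: [name] for name, p in _LOW_UNIVERSAL.items()}, activities, base=_LOW_BASE
    )
    segments = []
    for block in _LOW_SEGMENTS.values():
        row = low_base.copy()
        idx = [activities.index(a) for a in block]
        row[idx] = _LOW_BLOCK
        segments.append(row)
    segment_probs = np.array(segments)

    profiles = {
        HIGH: GroupProfile(
            group_label=HIGH,
            n_respondents=n_respondents,
            activity_probs=high_probs,
            day_type_shift={"weekday": 0.85, "weekend": 1.10},
        ),
        LOW: GroupProfile(
            group_label=LOW,
            n_respondents=n_respondents,
            activity_probs=segment_probs.mean(axis=0),
            day_type_shift={"weekday": 1.0, "weekend": 0.95},
            segment_probs=segment_probs,
        ),
    }
    config = SimulationConfig(activities=activities, profiles=profiles, seed=seed)
    config.validate()
    return config


def _education_for_age(age: int) -> str:
    if age <= 12:
        return "elementary"
    if age <= 15:
        return "middle"
    return "high"


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_diaries(config: SimulationConfig) -> pd.DataFrame:
    """Generate the long-format diary table for a config.

    Returns one row per (person, day type, activity) actually performed,
    in the canonical column order. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    activities = np.asarray(config.activities, dtype=object)
    frames: list[pd.DataFrame] = []

    for label in (HIGH, LOW):
        profile = config.profiles[label]
        n = profile.n_respondents
        if n == 0:
            continue
        prefix = "H" if label == HIGH else "L"
        ids = np.array([f"{prefix}{i:04d}" for i in range(1, n + 1)], dtype=object)
        ages = rng.integers(10, 20, size=n)
        sexes = rng.choice(["male", "female"], size=n)
        (swb_lo, swb_hi) = config.score_rules[label]["swb"]
        (h_lo, h_hi) = config.score_rules[label]["health"]
        swb = rng.integers(swb_lo, swb_hi + 1, size=n)
        health = rng.integers(h_lo, h_hi + 1, size=n)
        satisfaction = rng.integers(1, 6, size=n)
        if profile.segment_probs is not None:
            segment = rng.integers(0, profile.segment_probs.shape[0], size=n)
        else:
            segment = np.zeros(n, dtype=int)
        mu, sigma = _lognormal_params(profile.minutes_mean, profile.minutes_sd)

        for day_type in DAY_TYPES:
            probs = profile.shifted_probs(day_type)
            if probs.ndim == 1:
                person_probs = np.broadcast_to(probs, (n, probs.size))
            else:
                person_probs = probs[segment]
            # participation on >=1 of the diary days for that day type
            if config.diary_days > 1:
                person_probs = 1.0 - (1.0 - person_probs) ** config.diary_days
            hits = rng.random((n, len(activities))) < person_probs
            person_idx, act_idx = np.nonzero(hits)
            minutes = np.exp(rng.normal(mu, sigma, size=person_idx.size))
            minutes = np.maximum(10, np.round(minutes / 10.0) * 10.0).astype(int)
            if config.diary_days > 1:
                minutes = minutes * config.diary_days  # summed over diary days
            frames.append(pd.DataFrame({
                "person_id": ids[person_idx],
                "age": ages[person_idx],
                "sex": sexes[person_idx],
                "education": [_education_for_age(a) for a in ages[person_idx]],
                "swb_score": swb[person_idx],
                "health_score": health[person_idx],
                "leisure_satisfaction": satisfaction[person_idx],
                "day_type": day_type,
                "activity_code": activities[act_idx],
                "minutes": minutes,
            }))

    if not frames:
        return pd.DataFrame(columns=list(DIARY_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    return out[list(DIARY_COLUMNS)]


PATHOLOGY_KINDS = ("duplicates", "missing_scores", "out_of_age_range")


def inject_pathologies(records: pd.DataFrame, kind: str, rate: float = 0.05,
                       seed: int = 0) -> pd.DataFrame:
    """Return a copy of ``records`` with a named data defect injected.

    kind:
      * ``duplicates`` — append exact copies of a Bernoulli(rate) sample
        of rows;
      * ``missing_scores`` — blank the SWB score on a Bernoulli(rate)
        sample of rows;
      * ``out_of_age_range`` — push the age of a Bernoulli(rate) sample
        of rows outside the 10-19 study range (at least one row whenever
        rate > 0 and the table is non-empty).
    """
    if kind not in PATHOLOGY_KINDS:
        raise ValueError(f"unknown pathology kind {kind!r}; expected one of {PATHOLOGY_KINDS}")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    out = records.copy()
    if rate == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(len(out)) < rate
    if kind == "out_of_age_range" and not mask.any():
        mask[rng.integers(0, len(out))] = True

    if kind == "duplicates":
        return pd.concat([out, out[mask]], ignore_index=True)
    if kind == "missing_scores":
        out["swb_score"] = out["swb_score"].astype("Float64")
        out.loc[mask, "swb_score"] = pd.NA
        return out
    bad_ages = rng.choice([7, 8, 9, 20, 21, 22], size=int(mask.sum()))
    out.loc[mask, "age"] = bad_ages
    return out
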