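"""Synthetic longitudinal cohorts with the study's statistical structure.

Compositions are logistic-normal: a subject's baseline family profile is
softmax(log_mean + between-subject Gaussian), and in each subsequent year
the log-abundance vector either drifts by within-subject Gaussian noise
(the common case) or — with a small, intake-group-dependent probability —
is replaced by a fresh draw from the cohort prior, modelling the rare
predominant-family replacement events.  A replacement draw is rejection-
sampled until its Jensen-Shannon distance from the previous year reaches
the classification threshold, so a simulated event is a substantial
change by construction and the configured event rate is recoverable from
the classifier.  Event recurrence across consecutive intervals follows a
separate persistence probability.

The frozen default noise scales were fixed once by a grid search
(see ``analysis/05_calibration_search.py``) so that, at the study sizes,
the median within-subject JSD is ~0.205 and the median between-subject
JSD (first year) is ~0.401.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CompositionProfile,
    LongitudinalCohort,
    SampleRecord,
    SubjectCovariates,
    intake_group,
)
from .distances import jsd
from .errors import GutdriftError
from .stability import DEFAULT_THRESHOLD

#: Illustrative predominant gut bacterial families of elderly Japanese
#: adults (order-of-magnitude typical, not estimates from any dataset).
DEFAULT_FAMILIES = (
    "Ruminococcaceae",
    "Lachnospiraceae",
    "Bacteroidaceae",
    "Bifidobacteriaceae",
    "Prevotellaceae",
    "Coriobacteriaceae",
    "Clostridiaceae",
    "Enterobacteriaceae",
    "Veillonellaceae",
    "Erysipelotrichaceae",
    "Porphyromonadaceae",
    "Rikenellaceae",
    "Streptococcaceae",
    "Eubacteriaceae",
    "Lactobacillaceae",
)

_DEFAULT_MEANS = (
    0.30, 0.25, 0.15, 0.08, 0.05, 0.03, 0.02, 0.02, 0.02,
    0.015, 0.015, 0.01, 0.01, 0.01, 0.005,
)
DEFAULT_LOG_MEAN = tuple(float(np.log(m)) for m in _DEFAULT_MEANS)

#: Frozen calibration products (grid search; see module docstring).
CALIBRATED_BETWEEN_SUBJECT_SD = 1.10
CALIBRATED_WITHIN_SUBJECT_SD = 0.75


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; fully determines a cohort given ``seed``.

    Defaults mirror the study conditions: 218 subjects sampled in 2
    consecutive yearly waves (135 of them extended to a third wave when
    ``n_years=3``), 58/218 in the >= 3 days/week fermented-milk intake
    group, per-year replacement-event odds of 0.113 (< 3 days/week) vs
    0.017 (>= 3 days/week) — the observed group-wise rates of substantial
    change — and an event-recurrence probability of 8/14.
    """

    n_subjects: int = 218
    n_years: int = 2
    n_subjects_third_year: int = 135
    family_names: tuple[str, ...] = DEFAULT_FAMILIES
    log_mean: tuple[float, ...] = DEFAULT_LOG_MEAN
    between_subject_sd: float = CALIBRATED_BETWEEN_SUBJECT_SD
    within_subject_sd: float = CALIBRATED_WITHIN_SUBJECT_SD
    event_prob_lt3: float = 0.113
    event_prob_ge3: float = 0.017
    prop_ge3: float = 58 / 218
    event_persistence: float = 8 / 14
    event_min_jsd: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.family_names) < 2:
            raise GutdriftError("need at least 2 families")
        if len(self.log_mean) != len(self.family_names):
            raise GutdriftError("log_mean length must match family_names")
        if self.n_years not in (2, 3):
            raise GutdriftError("n_years must be 2 or 3")
        if self.n_subjects < 1:
            raise GutdriftError("n_subjects must be >= 1")
        for name in ("event_prob_lt3", "event_prob_ge3", "prop_ge3",
                     "event_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GutdriftError(f"{name}={v} outside [0, 1]")
        if self.between_subject_sd <= 0:
            raise GutdriftError("between_subject_sd must be > 0")
        # within_subject_sd = 0 is the useful no-drift limit
        if self.within_subject_sd < 0:
            raise GutdriftError("within_subject_sd must be >= 0")


def calibrate_defaults() -> SimulationConfig:
    """The packaged default configuration with frozen calibrated noise scales."""
    return SimulationConfig()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max())
    return z / z.sum()


def _ge3_indices(n_subjects: int, prop_ge3: float) -> set[int]:
    """Evenly spread deterministic assignment of the >= 3 days/week group."""
    n_ge3 = int(round(prop_ge3 * n_subjects))
    if n_ge3 == 0:
        return set()
    return {int(i) for i in np.linspace(0, n_subjects - 1, n_ge3).round()}


def _draw_covariates(rng: np.random.Generator, ge3: bool) -> SubjectCovariates:
    # Table-like marginals of the study cohort (elderly Japanese adults)
    age = float(np.clip(rng.normal(75.3, 6.2), 66, 91))
    sex = "male" if rng.random() < 0.457 else "female"
    bmi = float(np.clip(rng.normal(22.6, 3.1), 15, 40))
    smoker = bool(rng.random() < 0.046)
    alcohol = bool(rng.random() < 0.394)
    if ge3:
        days_10y = float(3.0 + 4.0 * rng.beta(1.2, 2.0))
    else:
        days_10y = float(3.0 * rng.beta(0.8, 1.6))
    intake = {"10y": days_10y}
    for window in ("1m", "5y"):
        intake[window] = float(np.clip(days_10y + rng.normal(0.8, 1.2), 0, 7))
    return SubjectCovariates(
        age=age, sex=sex, bmi=bmi, smoker=smoker, alcohol=alcohol,
        lcs_intake_days_per_week=intake,
    )


def _replacement_draw(
    rng: np.random.Generator,
    previous: np.ndarray,
    log_mean: np.ndarray,
    between_sd: float,
    min_jsd: float,
    max_tries: int = 200,
) -> np.ndarray:
    for _ in range(max_tries):
        candidate = _softmax(log_mean + between_sd * rng.standard_normal(log_mean.size))
        if jsd(previous, candidate) >= min_jsd:
            return candidate
    raise GutdriftError(
        f"could not draw a replacement composition at JSD >= {min_jsd} "
        f"in {max_tries} tries; event_min_jsd is likely too high for "
        "the configured between-subject spread"
    )


def generate_cohort(config: SimulationConfig) -> LongitudinalCohort:
    """Simulate a longitudinal cohort; bitwise-deterministic given the seed.

    Each subject owns an RNG sub-stream derived from (config.seed, subject
    index), so changing ``n_subjects`` leaves the other subjects'
    trajectories untouched.  The returned cohort carries an ``event_log``
    attribute mapping subject_id to the list of replacement-event
    indicators, one per year transition, for downstream diagnostics.
    """
    log_mean = np.asarray(config.log_mean, dtype=float)
    ge3_set = _ge3_indices(config.n_subjects, config.prop_ge3)
    samples: list[SampleRecord] = []
    covariates: dict[str, SubjectCovariates] = {}
    event_log: dict[str, list[bool]] = {}

    for i in range(config.n_subjects):
        rng = np.random.default_rng([abs(int(config.seed)), i])
        subject_id = f"sub{i + 1:04d}"
        ge3 = i in ge3_set
        cov = _draw_covariates(rng, ge3)
        covariates[subject_id] = cov
        event_prob = config.event_prob_ge3 if ge3 else config.event_prob_lt3

        logits = log_mean + config.between_subject_sd * rng.standard_normal(
            log_mean.size
        )
        comp = _softmax(logits)
        n_years = config.n_years
        if config.n_years == 3 and i >= config.n_subjects_third_year:
            n_years = 2
        prev_event = False
        event_log[subject_id] = []
        for year in range(1, n_years + 1):
            if year > 1:
                p_event = config.event_persistence if prev_event else event_prob
                if rng.random() < p_event:
                    comp = _replacement_draw(
                        rng, comp, log_mean,
                        config.between_subject_sd, config.event_min_jsd,
                    )
                    logits = np.log(comp)
                    prev_event = True
                else:
                    logits = logits + config.within_subject_sd * rng.standard_normal(
                        log_mean.size
                    )
                    comp = _softmax(logits)
                    prev_event = False
                event_log[subject_id].append(prev_event)
            samples.append(
                SampleRecord(
                    sample_id=f"{subject_id}.y{year}",
                    subject_id=subject_id,
                    year_index=year,
                    profile=CompositionProfile(config.family_names, comp),
                )
            )
    cohort = LongitudinalCohort(samples, covariates)
    cohort.event_log = event_log
    return cohort


def with_event_probs(
    config: SimulationConfig, lt3: float, ge3: float
) -> SimulationConfig:
    """Convenience copy-with-new-event-odds used in power analyses."""
    return replace(config, event_prob_lt3=lt3, event_prob_ge3=ge3)
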