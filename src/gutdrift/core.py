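"""Core in-memory containers for longitudinal family-level microbiota data.

A cohort is a set of fecal samples, each a relative-abundance vector over a
fixed, ordered list of bacterial families, indexed by (subject, collection
wave).  Waves are ordinal year indexes (1, 2, 3, ...) roughly one year
apart; calendar dates are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import GutdriftError

#: Recall windows over which fermented-milk intake frequency is reported.
INTAKE_WINDOWS = ("1m", "5y", "10y")

#: Intake-frequency cut: fewer than 3 days/week vs 3 or more.
INTAKE_CUTOFF_DAYS_PER_WEEK = 3.0


def intake_group(days_per_week: float) -> str:
    """Categorize an intake frequency: ``lt3`` iff < 3 days/week, else ``ge3``."""
    return "lt3" if days_per_week < INTAKE_CUTOFF_DAYS_PER_WEEK else "ge3"


@dataclass(frozen=True)
class CompositionProfile:
    """One sample's relative abundances over an ordered family list.

    Abundances live on the probability simplex: nonnegative, summing to 1
    within 1e-9 after validation.
    """

    family_names: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "family_names", tuple(self.family_names))
        if ab.ndim != 1 or len(ab) != len(self.family_names):
            raise GutdriftError(
                f"abundance vector length {ab.shape} does not match "
                f"{len(self.family_names)} family names"
            )
        if np.any(ab < 0):
            raise GutdriftError("negative abundance")
        total = float(ab.sum())
        if abs(total - 1.0) > 1e-9:
            raise GutdriftError(
                f"abundances sum to {total!r}, not 1 within 1e-9; "
                "renormalize via CompositionProfile.from_raw"
            )

    @classmethod
    def from_raw(
        cls,
        family_names: Sequence[str],
        abundances: Iterable[float],
        tol: float = 1e-6,
    ) -> "CompositionProfile":
        """Build a profile from near-simplex data, renormalizing.

        Row sums within ``tol`` of 1 (sequencing exports round their
        fractions) are rescaled to exactly 1; anything further off is an
        error rather than silently renormalized.
        """
        ab = np.asarray(list(abundances), dtype=float)
        if np.any(ab < 0):
            raise GutdriftError("negative abundance")
        total = float(ab.sum())
        if abs(total - 1.0) > tol:
            raise GutdriftError(
                f"row sum {total!r} outside [1-{tol}, 1+{tol}]"
            )
        return cls(tuple(family_names), ab / total)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionProfile):
            return NotImplemented
        return self.family_names == other.family_names and np.array_equal(
            self.abundances, other.abundances
        )


@dataclass(frozen=True)
class SampleRecord:
    """A profiled fecal sample from one subject at one collection wave."""

    sample_id: str
    subject_id: str
    year_index: int
    profile: CompositionProfile

    def __post_init__(self) -> None:
        if self.year_index < 1:
            raise GutdriftError(f"year_index must be >= 1, got {self.year_index}")


@dataclass
class SubjectCovariates:
    """Per-subject background covariates.

    ``lcs_intake_days_per_week`` holds the fermented-milk (LcS product)
    intake frequency for each recall window in :data:`INTAKE_WINDOWS`.
    Missing covariates are ``None`` and are dropped listwise by the
    statistical procedures that use them.
    """

    age: float | None = None
    sex: str | None = None  # "male" | "female"
    bmi: float | None = None
    smoker: bool | None = None
    alcohol: bool | None = None
    lcs_intake_days_per_week: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise GutdriftError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for window, days in self.lcs_intake_days_per_week.items():
            if window not in INTAKE_WINDOWS:
                raise GutdriftError(f"unknown intake window {window!r}")
            if not 0 <= days <= 7:
                raise GutdriftError(f"intake days/week {days} outside [0, 7]")

    def intake_group(self, window: str = "10y") -> str | None:
        days = self.lcs_intake_days_per_week.get(window)
        return None if days is None else intake_group(days)


class LongitudinalCohort:
    """Samples from many subjects over consecutive yearly waves.

    All samples share one ordered family list; (subject, wave) pairs are
    unique.  Subjects with a single wave are retained (they simply drop out
    of within-subject analyses).
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        covariates: Mapping[str, SubjectCovariates] | None = None,
    ) -> None:
        samples = list(samples)
        if not samples:
            raise GutdriftError("cohort must contain at least one sample")
        families = samples[0].profile.family_names
        seen: set[tuple[str, int]] = set()
        for rec in samples:
            if rec.profile.family_names != families:
                raise GutdriftError(
                    f"sample {rec.sample_id!r} uses a different family list"
                )
            key = (rec.subject_id, rec.year_index)
            if key in seen:
                raise GutdriftError(f"duplicate (subject, year): {key}")
            seen.add(key)
        self.samples: list[SampleRecord] = samples
        self.covariates: dict[str, SubjectCovariates] = dict(covariates or {})
        self._by_key = {(r.subject_id, r.year_index): r for r in samples}

    @property
    def family_names(self) -> tuple[str, ...]:
        return self.samples[0].profile.family_names

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.samples:
            seen.setdefault(rec.subject_id)
        return list(seen)

    def years_of(self, subject_id: str) -> list[int]:
        return sorted(
            r.year_index for r in self.samples if r.subject_id == subject_id
        )

    def sample_at(self, subject_id: str, year_index: int) -> SampleRecord | None:
        return self._by_key.get((subject_id, year_index))

    def samples_in_year(self, year_index: int) -> list[SampleRecord]:
        return [r for r in self.samples if r.year_index == year_index]

    def abundance_matrix(self) -> np.ndarray:
        """(n_samples, n_families) array in sample order."""
        return np.vstack([r.profile.abundances for r in self.samples])

    def __len__(self) -> int:
        return len(self.samples)

    def __repr__(self) -> str:
        return (
            f"LongitudinalCohort({len(self.samples)} samples, "
            f"{len(self.subject_ids)} subjects, "
            f"{len(self.family_names)} families)"
        )
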