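"""Classification of within-subject change and its persistence.

A subject whose within-subject Jensen-Shannon distance between two yearly
samples reaches 0.4 is classified as having undergone a *substantial
change* of gut-microbiota composition; 0.4 is approximately the median of
between-subject distances (and about twice the median within-subject
distance), so a "changed" subject moved as far from themselves in a year
as two unrelated subjects differ.  Over three waves the two consecutive
classifications combine into a persistence typology:

    stable_both             both intervals below threshold
    transient               exactly one interval at/above threshold
    continuous_reverted     both intervals at/above, but wave 1 -> wave 3
                            distance below threshold (returned to the
                            initial state)
    continuous_progressive  both intervals at/above and still far from the
                            initial state at wave 3
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import LongitudinalCohort
from .distances import PairDistanceSet, intra_individual
from .errors import GutdriftError

#: Study threshold on within-subject JSD for "substantial change".
DEFAULT_THRESHOLD = 0.4

PERSISTENCE_CATEGORIES = (
    "stable_both",
    "transient",
    "continuous_reverted",
    "continuous_progressive",
    "NA",
)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-subject stable/changed labels at a threshold."""

    threshold: float
    labels: dict[str, str]  # subject_id -> "stable" | "changed"

    @property
    def n_changed(self) -> int:
        return sum(1 for v in self.labels.values() if v == "changed")

    @property
    def n_total(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return self.n_changed / self.n_total


@dataclass
class StabilityReport:
    """Per-subject distances, class labels and persistence categories.

    ``table`` is indexed by subject_id with columns jsd_12, jsd_23,
    jsd_13, bcd_12 (all possibly NaN), class_12, class_23, persistence.
    ``contingency`` is the 2x2 count table with rows class_12
    (changed, stable) and columns class_23 (changed, stable), over
    subjects scored at both intervals.
    """

    threshold: float
    table: pd.DataFrame
    contingency: np.ndarray | None = None

    @property
    def persistence_counts(self) -> dict[str, int]:
        scored = self.table["persistence"].dropna()
        return {c: int((scored == c).sum()) for c in PERSISTENCE_CATEGORIES}


def derive_threshold(inter: PairDistanceSet) -> float:
    """Median of between-subject distances (midpoint for even counts).

    This is how the study's 0.4 cut was motivated; the packaged default
    remains the fixed constant :data:`DEFAULT_THRESHOLD` and is never
    silently replaced by this estimate.
    """
    if len(inter) == 0:
        raise GutdriftError("cannot derive a threshold from an empty distance set")
    return float(np.median(inter.values))


def classify(
    intra: PairDistanceSet | Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> ClassificationResult:
    """Label each subject changed iff their distance >= threshold.

    The boundary is inclusive: a subject at exactly the threshold counts
    as changed.
    """
    if threshold <= 0:
        raise GutdriftError(f"threshold must be > 0, got {threshold}")
    values = intra.as_dict() if isinstance(intra, PairDistanceSet) else dict(intra)
    if not values:
        raise GutdriftError("no subjects to classify")
    labels = {
        s: ("changed" if v >= threshold else "stable") for s, v in values.items()
    }
    return ClassificationResult(threshold=threshold, labels=labels)


def _persistence_category(
    j12: float, j23: float, j13: float | None, threshold: float, subject: str
) -> str:
    c12 = j12 >= threshold
    c23 = j23 >= threshold
    if not c12 and not c23:
        return "stable_both"
    if c12 != c23:
        return "transient"
    if j13 is None or np.isnan(j13):
        warnings.warn(
            f"subject {subject!r}: continuous change but no wave-1 to wave-3 "
            "distance; persistence subtype set to NA",
            stacklevel=3,
        )
        return "NA"
    return "continuous_reverted" if j13 < threshold else "continuous_progressive"


def persistence(
    jsd_12: Mapping[str, float],
    jsd_23: Mapping[str, float],
    jsd_13: Mapping[str, float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> StabilityReport:
    """Assign the four-way persistence typology over three waves.

    Every subject must appear in both ``jsd_12`` and ``jsd_23``; the
    wave-1 to wave-3 distance is only needed to subtype subjects changed
    in both intervals (reverted vs progressive).  The report also carries
    the 2x2 contingency of interval-1 vs interval-2 classifications.
    """
    jsd_13 = jsd_13 or {}
    missing = set(jsd_12) ^ set(jsd_23)
    if missing:
        raise GutdriftError(
            f"subjects must have both interval distances; mismatched: {sorted(missing)}"
        )
    if not jsd_12:
        raise GutdriftError("no subjects to score")
    rows = {}
    for subject in jsd_12:
        j12 = float(jsd_12[subject])
        j23 = float(jsd_23[subject])
        j13 = jsd_13.get(subject)
        cat = _persistence_category(j12, j23, j13, threshold, subject)
        rows[subject] = {
            "jsd_12": j12,
            "jsd_23": j23,
            "jsd_13": np.nan if j13 is None else float(j13),
            "class_12": "changed" if j12 >= threshold else "stable",
            "class_23": "changed" if j23 >= threshold else "stable",
            "persistence": cat,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    cc = int(((table.class_12 == "changed") & (table.class_23 == "changed")).sum())
    cs = int(((table.class_12 == "changed") & (table.class_23 == "stable")).sum())
    sc = int(((table.class_12 == "stable") & (table.class_23 == "changed")).sum())
    ss = int(((table.class_12 == "stable") & (table.class_23 == "stable")).sum())
    contingency = np.array([[cc, cs], [sc, ss]])
    return StabilityReport(threshold=threshold, table=table, contingency=contingency)


def build_stability_report(
    cohort: LongitudinalCohort,
    threshold: float = DEFAULT_THRESHOLD,
    include_bcd: bool = True,
) -> StabilityReport:
    """Full per-subject stability report straight from a cohort.

    Two-wave subjects get distances and a first-interval class only
    (persistence NA); three-wave subjects additionally get the typology.
    """
    intra12 = intra_individual(cohort, (1, 2), "jsd").as_dict()
    intra23 = intra_individual(cohort, (2, 3), "jsd").as_dict()
    intra13 = intra_individual(cohort, (1, 3), "jsd").as_dict()
    bcd12 = (
        intra_individual(cohort, (1, 2), "bcd").as_dict() if include_bcd else {}
    )
    if not intra12:
        raise GutdriftError("no subject has samples at both wave 1 and wave 2")

    three_wave = {s: v for s, v in intra12.items() if s in intra23}
    if three_wave:
        report = persistence(
            three_wave,
            {s: intra23[s] for s in three_wave},
            {s: intra13[s] for s in three_wave if s in intra13},
            threshold,
        )
        table = report.table
        contingency = report.contingency
    else:
        table = pd.DataFrame(
            columns=["jsd_12", "jsd_23", "jsd_13", "class_12", "class_23", "persistence"]
        )
        table.index.name = "subject_id"
        contingency = None

    two_wave = {s: v for s, v in intra12.items() if s not in intra23}
    extra = pd.DataFrame.from_dict(
        {
            s: {
                "jsd_12": v,
                "jsd_23": np.nan,
                "jsd_13": np.nan,
                "class_12": "changed" if v >= threshold else "stable",
                "class_23": None,
                "persistence": "NA",
            }
            for s, v in two_wave.items()
        },
        orient="index",
    )
    extra.index.name = "subject_id"
    if not extra.empty:
        table = extra if table.empty else pd.concat([table, extra])
    table = table.loc[[s for s in intra12 if s in table.index]]
    table["bcd_12"] = pd.Series(bcd12).reindex(table.index)
    order = [
        "jsd_12", "jsd_23", "jsd_13", "bcd_12", "class_12", "class_23", "persistence",
    ]
    return StabilityReport(
        threshold=threshold, table=table[order], contingency=contingency
    )


@dataclass
class FamilyDeltaTable:
    """Signed per-family abundance changes between two waves.

    ``deltas`` is subjects x families (fractions, wave2 - wave1); each row
    sums to 0 because both waves sum to 1.
    """

    year_pair: tuple[int, int]
    deltas: pd.DataFrame

    @property
    def family_medians(self) -> pd.Series:
        return self.deltas.median(axis=0)


def family_deltas(
    cohort: LongitudinalCohort, year_pair: tuple[int, int] = (1, 2)
) -> FamilyDeltaTable:
    """Per-subject, per-family abundance change across a wave pair."""
    t1, t2 = year_pair
    if t2 <= t1:
        raise GutdriftError(f"year_pair must be increasing, got {year_pair}")
    rows = {}
    for subject in cohort.subject_ids:
        first = cohort.sample_at(subject, t1)
        second = cohort.sample_at(subject, t2)
        if first is None or second is None:
            continue
        rows[subject] = second.profile.abundances - first.profile.abundances
    if not rows:
        raise GutdriftError(f"no subject sampled at both waves {year_pair}")
    deltas = pd.DataFrame.from_dict(rows, orient="index")
    deltas.columns = list(cohort.family_names)
    deltas.index.name = "subject_id"
    return FamilyDeltaTable(year_pair=(t1, t2), deltas=deltas)
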