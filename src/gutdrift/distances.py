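"""Compositional dissimilarity metrics and their cohort-level extraction.

The central metric is the Jensen-Shannon distance (JSD): the square root of
the Jensen-Shannon divergence between two relative-abundance distributions,

    JSd(x, y) = 1/2 KLD(x, m) + 1/2 KLD(y, m),   m = (x + y) / 2,
    KLD(x, y) = sum_i x_i ln(x_i / y_i),

with a pseudocount of 1e-7 added to every abundance (and the vectors
renormalized) before the divergence so that zeros never reach a logarithm.
In natural-log units JSD is a metric on the simplex bounded by
sqrt(ln 2) ~= 0.8326.  Bray-Curtis dissimilarity (1 - 2*sum(min)/sum(a+b))
is provided as the abundance-based alternative; it is zero-safe, so no
pseudocount is applied there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CompositionProfile, LongitudinalCohort
from .errors import GutdriftError

#: Pseudocount added to abundance distributions before log-based divergence.
DEFAULT_PSEUDOCOUNT = 1e-7

#: Upper bound of the Jensen-Shannon distance in natural-log units.
JSD_MAX = float(np.sqrt(np.log(2.0)))

_METRICS = ("jsd", "bcd")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if vals.shape != (n, n):
            raise GutdriftError(f"matrix shape {vals.shape} != ({n}, {n})")
        if self.metric_name not in _METRICS:
            raise GutdriftError(f"metric_name must be one of {_METRICS}")
        if np.any(np.abs(vals - vals.T) > 1e-12):
            raise GutdriftError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(vals) != 0.0):
            raise GutdriftError("distance matrix diagonal must be exactly 0")
        if np.any(vals < 0):
            raise GutdriftError("negative distances")
        upper = JSD_MAX + 1e-9 if self.metric_name == "jsd" else 1.0 + 1e-12
        if np.any(vals > upper):
            raise GutdriftError(
                f"{self.metric_name} distances exceed upper bound {upper}"
            )

    def value(self, label_a: str, label_b: str) -> float:
        i = self.labels.index(label_a)
        j = self.labels.index(label_b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class PairDistanceSet:
    """Within- or between-subject distances for one year (pair).

    ``kind='intra'`` carries one entry per subject sampled at both years of
    ``year_pair``; ``kind='inter'`` carries one entry per unordered subject
    pair within a single ``year``, keyed "idA|idB".
    """

    kind: str  # "intra" | "inter"
    metric_name: str
    entries: tuple[tuple[str, float], ...]
    year_pair: tuple[int, int] | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise GutdriftError(f"kind must be 'intra' or 'inter', got {self.kind!r}")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _as_vector(profile: CompositionProfile | Sequence[float]) -> np.ndarray:
    if isinstance(profile, CompositionProfile):
        return profile.abundances
    return np.asarray(profile, dtype=float)


def _check_same_families(a, b) -> None:
    if (
        isinstance(a, CompositionProfile)
        and isinstance(b, CompositionProfile)
        and a.family_names != b.family_names
    ):
        raise GutdriftError("profiles are on different family lists")


def kld(x: Sequence[float], y: Sequence[float]) -> float:
    """Kullback-Leibler divergence sum_i x_i ln(x_i / y_i), in nats.

    Inputs must already be strictly positive (pseudocounted) distributions
    of equal length; the divergence is asymmetric and nonnegative.
    """
    xv = _as_vector(x)
    yv = _as_vector(y)
    if xv.shape != yv.shape:
        raise GutdriftError(f"length mismatch: {xv.shape} vs {yv.shape}")
    if np.any(xv <= 0) or np.any(yv <= 0):
        raise GutdriftError(
            "KLD requires strictly positive entries; apply the pseudocount first"
        )
    return float(np.sum(xv * np.log(xv / yv)))


def _pseudocounted(v: np.ndarray, pseudocount: float) -> np.ndarray:
    w = v + pseudocount
    return w / w.sum()


def jsd(
    a: CompositionProfile | Sequence[float],
    b: CompositionProfile | Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Jensen-Shannon distance between two abundance distributions.

    The pseudocount is added to each input distribution and each is
    renormalized *before* the mixture m = (x + y)/2 is formed.  Result is
    symmetric and lies in [0, sqrt(ln 2)].
    """
    _check_same_families(a, b)
    x = _pseudocounted(_as_vector(a), pseudocount)
    y = _pseudocounted(_as_vector(b), pseudocount)
    if x.shape != y.shape:
        raise GutdriftError(f"length mismatch: {x.shape} vs {y.shape}")
    m = (x + y) / 2.0
    jsdiv = 0.5 * kld(x, m) + 0.5 * kld(y, m)
    # roundoff can leave a tiny negative divergence for near-identical inputs
    return float(np.sqrt(max(jsdiv, 0.0)))


def bray_curtis(
    a: CompositionProfile | Sequence[float],
    b: CompositionProfile | Sequence[float],
) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min(a,b)) / sum(a + b), in [0, 1]."""
    _check_same_families(a, b)
    x = _as_vector(a)
    y = _as_vector(b)
    if x.shape != y.shape:
        raise GutdriftError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise GutdriftError("both profiles are entirely zero")
    return float(1.0 - 2.0 * np.sum(np.minimum(x, y)) / denom)


def _pairwise_jsd(mat: np.ndarray, pseudocount: float) -> np.ndarray:
    """All-pairs JSD on rows of a (n, d) abundance matrix, vectorized."""
    p = mat + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    logp = np.log(p)
    # entropy trick: JSd(x, y) = H(m) - (H(x) + H(y))/2 with H in nats
    h = -np.sum(p * logp, axis=1)
    n = p.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        m = (p[i] + p) / 2.0
        hm = -np.sum(m * np.log(m), axis=1)
        out[i] = hm - (h[i] + h) / 2.0
    out = np.sqrt(np.clip(out, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return np.minimum(out, JSD_MAX)


def _pairwise_bcd(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(mat[i], mat).sum(axis=1)
        sums = (mat[i] + mat).sum(axis=1)
        out[i] = 1.0 - 2.0 * mins / sums
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, 1.0)


def pairwise_matrix(
    cohort: LongitudinalCohort,
    metric: str = "jsd",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DistanceMatrix:
    """All unordered sample-pair distances for a cohort."""
    if metric not in _METRICS:
        raise GutdriftError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if len(cohort) < 2:
        raise GutdriftError("need at least 2 samples for a distance matrix")
    mat = cohort.abundance_matrix()
    if metric == "jsd":
        values = _pairwise_jsd(mat, pseudocount)
    else:
        values = _pairwise_bcd(mat)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    labels = tuple(r.sample_id for r in cohort.samples)
    return DistanceMatrix(labels, values, metric)


def _metric_fn(metric: str, pseudocount: float):
    if metric == "jsd":
        return lambda a, b: jsd(a, b, pseudocount)
    if metric == "bcd":
        return bray_curtis
    raise GutdriftError(f"unknown metric {metric!r}; choose from {_METRICS}")


def intra_individual(
    cohort: LongitudinalCohort,
    year_pair: tuple[int, int] = (1, 2),
    metric: str = "jsd",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PairDistanceSet:
    """Within-subject distance between two collection waves.

    Subjects lacking either wave are silently omitted; a subject appears at
    most once.  Any (earlier, later) pair is accepted, so the explicit
    first-to-third comparison used in persistence analysis is available,
    but consecutive waves are the default.
    """
    t1, t2 = year_pair
    if t2 <= t1:
        raise GutdriftError(f"year_pair must be increasing, got {year_pair}")
    fn = _metric_fn(metric, pseudocount)
    entries = []
    for subject in cohort.subject_ids:
        first = cohort.sample_at(subject, t1)
        second = cohort.sample_at(subject, t2)
        if first is None or second is None:
            continue
        entries.append((subject, fn(first.profile, second.profile)))
    return PairDistanceSet(
        kind="intra", metric_name=metric, entries=tuple(entries), year_pair=(t1, t2)
    )


def inter_individual(
    cohort: LongitudinalCohort,
    year: int = 1,
    metric: str = "jsd",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PairDistanceSet:
    """Between-subject distances among all samples of one collection wave.

    Produces n(n-1)/2 entries for n subjects sampled in that year; never
    mixes waves.
    """
    records = cohort.samples_in_year(year)
    if len(records) < 2:
        raise GutdriftError(f"need >= 2 subjects sampled in year {year}")
    mat = np.vstack([r.profile.abundances for r in records])
    if metric == "jsd":
        values = _pairwise_jsd(mat, pseudocount)
    elif metric == "bcd":
        values = _pairwise_bcd(mat)
    else:
        raise GutdriftError(f"unknown metric {metric!r}; choose from {_METRICS}")
    entries = []
    for i, j in itertools.combinations(range(len(records)), 2):
        key = f"{records[i].subject_id}|{records[j].subject_id}"
        entries.append((key, float(values[i, j])))
    return PairDistanceSet(
        kind="inter", metric_name=metric, entries=tuple(entries), year=year
    )
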