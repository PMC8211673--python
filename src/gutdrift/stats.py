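"""Statistical procedures used by the stability analyses.

Closed-form tests (Fisher's exact, Pearson chi-square, Levene, Spearman,
covariate-adjusted group comparison) delegate to scipy/statsmodels behind
a uniform :class:`TestResult` surface.  The two procedures without a
suitable library implementation — Steel's many-to-one rank test and
PERMANOVA on a precomputed dissimilarity matrix — are implemented here as
seeded permutation tests, deterministic given (seed, n_permutations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .distances import DistanceMatrix
from .errors import GutdriftError


def _clip_p(p: float) -> float:
    """Keep closed-form p-values inside the documented (0, 1] interval."""
    return float(min(max(p, np.finfo(float).tiny), 1.0))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise GutdriftError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise GutdriftError(f"counts must be nonnegative integers: {cells}")
        if sum(cells) == 0:
            raise GutdriftError("empty contingency table")

    @classmethod
    def from_labels(
        cls, group: Sequence[str], outcome: Sequence[bool]
    ) -> "ContingencyTable2x2":
        """Cross-tabulate a binary group label against a boolean outcome.

        Row order follows first appearance of each group; columns are
        (outcome True, outcome False).
        """
        groups = list(dict.fromkeys(group))
        if len(groups) != 2:
            raise GutdriftError(f"need exactly 2 groups, got {groups}")
        g = np.asarray(group)
        o = np.asarray(outcome, dtype=bool)
        g1, g2 = groups
        return cls(
            int(((g == g1) & o).sum()),
            int(((g == g1) & ~o).sum()),
            int(((g == g2) & o).sum()),
            int(((g == g2) & ~o).sum()),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sidedness follows the probability-mass convention: with margins
    fixed, p is the total hypergeometric probability of all tables no more
    likely than the observed one.
    """
    odds, p = scipy.stats.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=_clip_p(p),
                      method="fisher_exact")


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise GutdriftError("chi-square undefined with a zero row/column margin")
    stat, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), p_value=_clip_p(p),
                      method="chi_square")


def _rank_sum_z(pooled_ranks_sum: np.ndarray, n_t: int, n_c: int,
                tie_term: np.ndarray) -> np.ndarray:
    """Standardized Wilcoxon rank-sum with tie-corrected variance."""
    n = n_t + n_c
    mean = n_t * (n + 1) / 2.0
    var = n_t * n_c / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (pooled_ranks_sum - mean) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def _tie_term(sorted_rows: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row of a sorted 2-d array."""
    n = sorted_rows.shape[1]
    boundaries = np.ones(sorted_rows.shape, dtype=bool)
    boundaries[:, 1:] = sorted_rows[:, 1:] != sorted_rows[:, :-1]
    out = np.zeros(sorted_rows.shape[0])
    for r in range(sorted_rows.shape[0]):
        idx = np.flatnonzero(boundaries[r])
        runs = np.diff(np.append(idx, n))
        out[r] = float(np.sum(runs**3 - runs))
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, axis=1)


def steel_test(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> list[TestResult]:
    """Steel's many-to-one rank test by max-statistic permutation.

    Each treatment group is compared with the single control via the
    Wilcoxon rank-sum statistic on the jointly ranked pair (control union
    that treatment).  The familywise p-value of treatment k is the
    fraction of label permutations whose maximum absolute standardized
    statistic across *all* treatments reaches treatment k's observed
    absolute statistic — a single-step max-T analogue of the tabulated
    test, calibrated by permutation rather than by critical-value tables.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if control.size < 2 or any(g.size < 2 for g in groups) or not groups:
        raise GutdriftError("control and every treatment need >= 2 values")
    pooled = np.concatenate([control] + groups)
    sizes = [control.size] + [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    n_c = control.size

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations + 1, pooled.size), dtype=float)
    perms[0] = pooled
    for i in range(1, n_permutations + 1):
        perms[i] = pooled[rng.permutation(pooled.size)]

    abs_z = np.empty((n_permutations + 1, len(groups)))
    for k in range(len(groups)):
        tk = perms[:, offsets[k + 1]:offsets[k + 2]]
        sub = np.concatenate([perms[:, :n_c], tk], axis=1)
        ranks = _rank_rows(sub)
        tsum = ranks[:, n_c:].sum(axis=1)
        if np.unique(pooled).size == pooled.size:  # tie-free pool, all perms tie-free
            ties = np.zeros(sub.shape[0])
        else:
            ties = _tie_term(np.sort(sub, axis=1))
        abs_z[:, k] = np.abs(_rank_sum_z(tsum, tk.shape[1], n_c, ties))

    max_null = abs_z[1:].max(axis=1)
    results = []
    for k in range(len(groups)):
        observed = abs_z[0, k]
        p = (np.sum(max_null >= observed) + 1.0) / (n_permutations + 1.0)
        results.append(
            TestResult(
                statistic=float(observed),
                p_value=float(min(p, 1.0)),
                method="steel_max_permutation",
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    return results


def adjusted_group_compare(
    y: Sequence[float],
    group: Sequence,
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
) -> TestResult:
    """Covariate-adjusted two-group comparison (ANCOVA as a linear model).

    Fits y ~ intercept + group + covariates by OLS and reports the t-test
    of the group coefficient — identical to the classic 1-df adjusted
    ANCOVA F.  Rows with any missing value are dropped listwise.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    gseries = pd.Series(group)
    levels = [v for v in gseries.dropna().unique()]
    if len(levels) != 2:
        raise GutdriftError(f"group must have exactly 2 levels, got {levels}")
    indicator = gseries.map({levels[0]: 0.0, levels[1]: 1.0}).to_numpy(dtype=float)

    design = pd.DataFrame({"group": indicator})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for col in cov.columns:
            series = cov[col]
            if series.dtype == object or series.dtype == bool:
                vals = [v for v in series.dropna().unique()]
                if len(vals) > 2:
                    raise GutdriftError(
                        f"covariate {col!r} is non-numeric with >2 levels"
                    )
                series = series.map({vals[0]: 0.0, vals[-1]: 1.0})
            design[col] = pd.to_numeric(series)
    design.insert(0, "const", 1.0)

    frame = design.assign(_y=y).dropna()
    if len(frame) < design.shape[1] + 2:
        raise GutdriftError(
            f"too few complete cases ({len(frame)}) for {design.shape[1] - 1} predictors"
        )
    if frame["group"].nunique() < 2:
        raise GutdriftError("one group level vanished after listwise deletion")
    x = frame.drop(columns="_y")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        running_rank = 0
        for j in range(1, x.shape[1] + 1):
            new_rank = np.linalg.matrix_rank(x.iloc[:, :j].to_numpy())
            if new_rank == running_rank:
                raise GutdriftError(
                    f"design is rank-deficient: column {x.columns[j - 1]!r} "
                    "is collinear with earlier columns"
                )
            running_rank = new_rank
    fit = sm.OLS(frame["_y"].to_numpy(), x.to_numpy()).fit()
    idx = list(x.columns).index("group")
    return TestResult(
        statistic=float(fit.tvalues[idx]),
        p_value=_clip_p(fit.pvalues[idx]),
        method="ancova_ols_t",
    )


def levene(
    groups: Sequence[Sequence[float]], center: str = "mean"
) -> TestResult:
    """Levene's homogeneity-of-dispersion test (classic mean-centered form).

    One-way ANOVA F on absolute deviations from each group's center;
    ``center='median'`` gives the Brown-Forsythe variant.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise GutdriftError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise GutdriftError("zero dispersion everywhere: Levene statistic undefined")
    stat, p = scipy.stats.levene(*arrays, center=center)
    return TestResult(statistic=float(stat), p_value=_clip_p(p),
                      method=f"levene_{center}")


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value.

    Ties receive average ranks.  ``exact=True`` (n <= 10 only) replaces
    the t approximation with the full permutation distribution of rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise GutdriftError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GutdriftError("rank correlation undefined for a constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    if exact:
        if x.size > 10:
            raise GutdriftError("exact permutation p only supported for n <= 10")
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        count = 0
        total = 0
        obs = abs(rho)
        for perm in itertools.permutations(range(x.size)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return TestResult(statistic=float(rho), p_value=count / total,
                          method="spearman_exact", n_permutations=total)
    return TestResult(statistic=float(rho), p_value=_clip_p(p),
                      method="spearman_t")


def _group_indicators(labels: Sequence) -> tuple[list, np.ndarray]:
    levels = list(dict.fromkeys(labels))
    arr = np.asarray(labels)
    ind = np.vstack([(arr == lv).astype(float) for lv in levels])
    return levels, ind


def _pseudo_f(d2: np.ndarray, ind: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Anderson pseudo-F for each row of group-indicator matrices.

    ``ind`` has shape (n_perm, n_groups, n_samples); within-group sums of
    squared distances are read off the quadratic form ind @ d2 @ ind^T.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    nperm, ngroups, _ = ind.shape
    ss_within = np.zeros(nperm)
    for g in range(ngroups):
        ig = ind[:, g, :]
        quad = np.einsum("pi,ij,pj->p", ig, d2, ig)
        ss_within += quad / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    df_between = ngroups - 1
    df_within = n - ngroups
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    matrix: DistanceMatrix,
    labels: Sequence,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> TestResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Decomposes the total sum of squared dissimilarities into between- and
    within-group parts directly from the matrix (no ordination), forms the
    pseudo-F, and assesses it by permuting sample labels; p follows the
    (count + 1)/(n + 1) convention with a fixed seed.
    """
    labels = list(labels)
    if len(labels) != len(matrix.labels):
        raise GutdriftError(
            f"{len(labels)} labels for {len(matrix.labels)} samples"
        )
    levels, ind0 = _group_indicators(labels)
    if len(levels) < 2:
        raise GutdriftError("PERMANOVA needs >= 2 groups")
    sizes = ind0.sum(axis=1)
    if np.any(sizes < 1):
        raise GutdriftError("every group needs at least one sample")
    d2 = matrix.values**2
    n = d2.shape[0]

    rng = np.random.default_rng(seed)
    codes = np.argmax(ind0, axis=0)
    perm_codes = np.empty((n_permutations + 1, n), dtype=int)
    perm_codes[0] = codes
    for i in range(1, n_permutations + 1):
        perm_codes[i] = codes[rng.permutation(n)]
    ind = np.stack(
        [(perm_codes == g).astype(float) for g in range(len(levels))], axis=1
    )
    f_values = _pseudo_f(d2, ind, sizes)
    observed = f_values[0]
    p = (np.sum(f_values[1:] >= observed) + 1.0) / (n_permutations + 1.0)
    return TestResult(
        statistic=float(observed),
        p_value=float(min(p, 1.0)),
        method="permanova",
        n_permutations=n_permutations,
        seed=seed,
    )
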