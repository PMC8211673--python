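"""Embedded worked examples with their published expectations.

Each check re-runs one of the study's printed results through the package
— the intake-frequency Fisher table, the persistence contingency, the
alcohol chi-square, the persistence percentages and the changed-subject
prevalence — and compares the recomputed value with the printed one.
The tables themselves are the published counts, embedded as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import stability, stats

#: Published 2x2 count tables (rows: group, columns: outcome yes/no).
EMBEDDED_TABLES: dict[str, tuple[int, int, int, int]] = {
    # substantial change (JSD >= 0.4) by intake < 3 vs >= 3 days/week
    "fisher_intake_vs_change": (18, 142, 1, 57),
    # second-interval change by first-interval class (changed vs stable)
    "fisher_persistence": (8, 6, 8, 113),
    # current alcohol consumers by intake group
    "chi_square_alcohol": (73, 87, 13, 45),
}

#: Published persistence counts over the 135 three-wave subjects.
PERSISTENCE_COUNTS = {
    "stable_both": 113,
    "transient_first_only": 6,
    "transient_second_only": 8,
    "continuous_reverted": 5,
    "continuous_progressive": 3,
}

#: Published prevalence of substantial change: 19 of 218 subjects.
PREVALENCE_COUNTS = (19, 218)


@dataclass(frozen=True)
class CheckResult:
    name: str
    observed: float
    expected: str
    passed: bool


def _persistence_inputs() -> tuple[dict, dict, dict]:
    """Synthetic per-subject distances realizing the published counts.

    Distances are placeholders on the correct side of the 0.4 threshold;
    only the counts are meaningful.
    """
    j12: dict[str, float] = {}
    j23: dict[str, float] = {}
    j13: dict[str, float] = {}
    idx = 0

    def add(n, v12, v23, v13=None):
        nonlocal idx
        for _ in range(n):
            sid = f"s{idx:03d}"
            j12[sid] = v12
            j23[sid] = v23
            if v13 is not None:
                j13[sid] = v13
            idx += 1

    add(PERSISTENCE_COUNTS["stable_both"], 0.2, 0.2)
    add(PERSISTENCE_COUNTS["transient_first_only"], 0.5, 0.2)
    add(PERSISTENCE_COUNTS["transient_second_only"], 0.2, 0.5)
    add(PERSISTENCE_COUNTS["continuous_reverted"], 0.5, 0.5, 0.2)
    add(PERSISTENCE_COUNTS["continuous_progressive"], 0.5, 0.5, 0.5)
    return j12, j23, j13


def run_paper_checks() -> list[CheckResult]:
    """Recompute every embedded worked example; one CheckResult each."""
    results: list[CheckResult] = []

    p = stats.fisher_exact(
        stats.ContingencyTable2x2(*EMBEDDED_TABLES["fisher_intake_vs_change"])
    ).p_value
    results.append(
        CheckResult("fisher_intake_vs_change_p", round(p, 3),
                    "P = 0.029 (+/- 0.001)", abs(p - 0.029) <= 0.001)
    )

    p = stats.fisher_exact(
        stats.ContingencyTable2x2(*EMBEDDED_TABLES["fisher_persistence"])
    ).p_value
    results.append(
        CheckResult("fisher_persistence_p", p, "P <= 0.001", p <= 0.001)
    )

    p = stats.chi_square_2x2(
        stats.ContingencyTable2x2(*EMBEDDED_TABLES["chi_square_alcohol"])
    ).p_value
    results.append(
        CheckResult("chi_square_alcohol_p", p, "P <= 0.05", p <= 0.05)
    )

    report = stability.persistence(*_persistence_inputs())
    counts = report.persistence_counts
    n = int(report.table.shape[0])
    stable_pct = round(100.0 * counts["stable_both"] / n, 1)
    results.append(
        CheckResult("stable_both_pct", stable_pct, "113/135 = 83.7%",
                    stable_pct == 83.7)
    )
    continuous = counts["continuous_reverted"] + counts["continuous_progressive"]
    cont_pct = round(100.0 * continuous / n, 1)
    results.append(
        CheckResult("continuous_pct", cont_pct, "8/135 = 5.9%", cont_pct == 5.9)
    )
    cc, cs = report.contingency[0]
    recur_pct = round(100.0 * cc / (cc + cs), 1)
    results.append(
        CheckResult("recurrence_among_changed_pct", recur_pct,
                    "8/14 = 57.1%", recur_pct == 57.1)
    )
    expected_tab = [[8, 6], [8, 113]]
    results.append(
        CheckResult(
            "persistence_contingency",
            float(report.contingency.sum()),
            str(expected_tab),
            report.contingency.tolist() == expected_tab,
        )
    )

    changed, total = PREVALENCE_COUNTS
    values = {f"s{i}": (0.5 if i < changed else 0.2) for i in range(total)}
    prev = stability.classify(values).prevalence
    prev_pct = round(100.0 * prev, 1)
    results.append(
        CheckResult("changed_prevalence_pct", prev_pct, "19/218 = 8.7%",
                    prev_pct == 8.7)
    )
    return results
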