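"""Associations between fermented-milk intake frequency and stability.

On the two-wave cohort: (i) Fisher's exact test of substantial-change
incidence between the < 3 and >= 3 days/week intake groups; (ii) the
covariate-adjusted (age, sex, BMI, smoking, alcohol) comparison of the
within-subject JSD between intake groups; (iii) chi-square on alcohol
use by group; (iv) Levene dispersion tests of the per-family yearly
abundance changes between groups; (v) PERMANOVA of each wave's JSD
matrix grouped by substantial-change class.
"""

from pathlib import Path

import pandas as pd

from gutdrift.core import LongitudinalCohort
from gutdrift.distances import intra_individual, pairwise_matrix
from gutdrift.io import read_abundance_table
from gutdrift.stability import classify, family_deltas
from gutdrift.stats import (
    ContingencyTable2x2,
    adjusted_group_compare,
    chi_square_2x2,
    fisher_exact,
    levene,
    permanova,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    cohort = read_abundance_table(SCRATCH / "abundance_2y.tsv",
                                  SCRATCH / "metadata_2y.tsv")
    intra = intra_individual(cohort, (1, 2), "jsd").as_dict()
    labels = classify(intra).labels
    subjects = list(labels)
    cov = cohort.covariates
    group = [cov[s].intake_group("10y") for s in subjects]
    changed = [labels[s] == "changed" for s in subjects]
    rows = []

    res = fisher_exact(ContingencyTable2x2.from_labels(group, changed))
    rows.append(("fisher_change_by_intake", res.statistic, res.p_value))

    res = adjusted_group_compare(
        [intra[s] for s in subjects], group,
        {"age": [cov[s].age for s in subjects],
         "sex": [cov[s].sex for s in subjects],
         "bmi": [cov[s].bmi for s in subjects],
         "smoker": [cov[s].smoker for s in subjects],
         "alcohol": [cov[s].alcohol for s in subjects]},
    )
    rows.append(("ancova_jsd_by_intake", res.statistic, res.p_value))

    res = chi_square_2x2(ContingencyTable2x2.from_labels(
        group, [bool(cov[s].alcohol) for s in subjects]))
    rows.append(("chi_square_alcohol_by_intake", res.statistic, res.p_value))

    deltas = family_deltas(cohort, (1, 2)).deltas
    by_group = pd.Series(group, index=subjects)
    for family in ("Ruminococcaceae", "Lactobacillaceae"):
        g_lt3 = deltas.loc[by_group == "lt3", family]
        g_ge3 = deltas.loc[by_group == "ge3", family]
        res = levene([g_lt3, g_ge3])
        rows.append((f"levene_delta_{family}", res.statistic, res.p_value))

    for year in (1, 2):
        recs = cohort.samples_in_year(year)
        year_cohort = LongitudinalCohort(recs, cov)
        matrix = pairwise_matrix(year_cohort, "jsd")
        year_labels = [labels[r.subject_id] for r in recs]
        res = permanova(matrix, year_labels, n_permutations=9999, seed=1)
        rows.append((f"permanova_class_year{year}", res.statistic, res.p_value))

    frame = pd.DataFrame(rows, columns=["test", "statistic", "p_value"])
    frame.to_csv(RESULTS / "associations.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print("\nLower intake frequency is associated with higher odds of "
          "substantial gut-microbiota change in this synthetic cohort, "
          "mirroring the structure the generator encodes.")


if __name__ == "__main__":
    main()
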