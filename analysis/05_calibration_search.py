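"""Grid search that fixed the generator's frozen noise scales.

Sweeps the between-subject and within-subject log-scale standard
deviations and measures, per candidate, the median within-subject JSD
(waves 1 -> 2) and the median between-subject JSD (wave 1) over
study-sized cohorts, averaged across replicate seeds.  The packaged
defaults (between 1.10, within 0.75) were chosen from this grid to put
the medians at the reference values 0.205 and 0.401; the grid table is
written to scratch/ for inspection.  This script documents the frozen
constants; it does not rewrite them.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from gutdrift.distances import inter_individual, intra_individual
from gutdrift.synthetic import (
    CALIBRATED_BETWEEN_SUBJECT_SD,
    CALIBRATED_WITHIN_SUBJECT_SD,
    calibrate_defaults,
    generate_cohort,
)

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEEDS = (1, 2, 3)
TARGET_INTRA, TARGET_INTER = 0.205, 0.401


def medians(between_sd: float, within_sd: float) -> tuple[float, float]:
    intra_meds, inter_meds = [], []
    for seed in SEEDS:
        cfg = replace(calibrate_defaults(), between_subject_sd=between_sd,
                      within_subject_sd=within_sd, seed=seed)
        cohort = generate_cohort(cfg)
        intra_meds.append(np.median(intra_individual(cohort, (1, 2)).values))
        inter_meds.append(np.median(inter_individual(cohort, 1).values))
    return float(np.mean(intra_meds)), float(np.mean(inter_meds))


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    rows = []
    for bsd in (0.9, 1.0, 1.05, 1.10, 1.15, 1.2):
        for wsd in (0.55, 0.65, 0.75, 0.85):
            intra_med, inter_med = medians(bsd, wsd)
            rows.append({
                "between_subject_sd": bsd, "within_subject_sd": wsd,
                "median_intra_jsd": round(intra_med, 4),
                "median_inter_jsd": round(inter_med, 4),
                "loss": round(abs(intra_med - TARGET_INTRA)
                              + abs(inter_med - TARGET_INTER), 4),
            })
    frame = pd.DataFrame(rows).sort_values("loss")
    frame.to_csv(SCRATCH / "calibration_grid.tsv", sep="\t", index=False)
    print(frame.head(8).to_string(index=False))
    best = frame.iloc[0]
    print(f"\nbest grid point: between={best.between_subject_sd}, "
          f"within={best.within_subject_sd}")
    print(f"frozen package constants: between={CALIBRATED_BETWEEN_SUBJECT_SD}, "
          f"within={CALIBRATED_WITHIN_SUBJECT_SD}")


if __name__ == "__main__":
    main()
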