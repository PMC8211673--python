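"""Generate the study-sized synthetic cohorts used by the later steps.

Writes the default 218-subject two-wave cohort and the three-wave variant
(135 subjects extended to a third yearly sample) as abundance/metadata
TSV pairs under scratch/ (bulky intermediates; the later steps read them
and write their summary tables under results/).
"""

from dataclasses import replace
from pathlib import Path

from gutdrift.io import write_cohort
from gutdrift.synthetic import calibrate_defaults, generate_cohort

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)

    two_wave = generate_cohort(replace(calibrate_defaults(), seed=SEED))
    write_cohort(two_wave, SCRATCH / "abundance_2y.tsv", SCRATCH / "metadata_2y.tsv")
    n_events = sum(any(v) for v in two_wave.event_log.values())
    print(f"two-wave cohort: {len(two_wave)} samples, "
          f"{len(two_wave.subject_ids)} subjects, "
          f"{n_events} replacement-event subjects")

    three_wave = generate_cohort(
        replace(calibrate_defaults(), n_years=3, seed=SEED)
    )
    write_cohort(three_wave, SCRATCH / "abundance_3y.tsv",
                 SCRATCH / "metadata_3y.tsv")
    n3 = sum(1 for s in three_wave.subject_ids if three_wave.sample_at(s, 3))
    print(f"three-wave cohort: {len(three_wave)} samples; "
          f"{n3} subjects have a third wave")


if __name__ == "__main__":
    main()
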