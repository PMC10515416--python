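"""Simulate the study cohort and write its raw streams.

Generates 500 monitored patients with the study's modality mix and
per-modality event incidence, then reports the realised structure. Raw
vitals/alerts CSVs are bulky per-sample intermediates and go under
``scratch/``; the ground-truth table goes with them.
"""

from common import ALERTS, SCRATCH, STUDY_CONFIG, TRUTH, VITALS

from ehival.io_streams import write_cohort
from ehival.synthetic_cohort import generate_cohort


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(STUDY_CONFIG)
    write_cohort(cohort, VITALS, ALERTS)
    truth.table.to_csv(TRUTH, index=False)

    tab = truth.table
    print(f"simulated {len(cohort)} patients (seed {STUDY_CONFIG.seed})")
    for modality in ("NIBP", "IAP"):
        sub = tab[tab["modality"] == modality]
        print(
            f"  {modality}: {len(sub)} patients, "
            f"{sub['has_event'].sum()} with an event "
            f"({100 * sub['has_event'].mean():.1f}%)"
        )
    print(f"raw streams written to {SCRATCH}")


if __name__ == "__main__":
    main()
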