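"""Lead-time analysis: how long is the unbroken high run before onset?

For every patient with a detected episode, walks backward from the last
alert before the first onset through the consecutive run of high-risk
outputs and summarises the run durations per modality, alongside the
monitoring time that was available before onset.
"""

import json
from dataclasses import asdict

import pandas as pd

from common import RESULTS, load_cohort

from ehival.ehi_detection import detect_cohort_episodes
from ehival.leadtime import cohort_lead_times, leadtime_stats


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort()
    episodes = detect_cohort_episodes(cohort)

    all_stats = {}
    for modality in ("NIBP", "IAP"):
        sub = [p for p in cohort if p.modality.value == modality]
        results = cohort_lead_times(sub, episodes)
        if not results:
            print(f"{modality}: no episode patients, lead time skipped")
            continue
        pd.DataFrame([asdict(r) for r in results]).to_csv(
            RESULTS / f"leadtime_results_{modality}.csv", index=False
        )
        stats = leadtime_stats(results)
        all_stats[modality] = stats
        lh = stats["lead_hours"]
        print(
            f"{modality}: {stats['n_with_lead']}/{stats['n_patients']} "
            f"({100 * stats['frac_with_lead']:.1f}%) with an immediate high run; "
            + (
                f"lead median {lh['median']:.2f} h "
                f"[Q1 {lh['q1']:.2f}, Q3 {lh['q3']:.2f}], mean {lh['mean']:.2f} h"
                if lh
                else "no leads"
            )
        )
    (RESULTS / "leadtime_summary.json").write_text(json.dumps(all_stats, indent=1))
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
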