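"""Annotate instability episodes from the simulated vital-sign streams.

Applies the modality-specific rules (10-minute sustained rule on the
0.5 Hz arterial streams; per-measurement point rule on hourly cuff
readings) and compares detected first onsets against the generator's
ground truth where it is available.
"""

import numpy as np
import pandas as pd

from common import EPISODES, RESULTS, TRUTH, load_cohort

from ehival.ehi_detection import detect_cohort_episodes, first_episode
from ehival.io_streams import write_episodes


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort()
    episodes = detect_cohort_episodes(cohort)
    flat = [e for eps in episodes.values() for e in eps]
    write_episodes(flat, EPISODES)

    n_with = sum(1 for eps in episodes.values() if eps)
    print(f"detected {len(flat)} episode(s) in {n_with} of {len(cohort)} patients")
    for modality in ("NIBP", "IAP"):
        sub = [p for p in cohort if p.modality.value == modality]
        n_ev = sum(1 for p in sub if episodes[p.patient_id])
        print(f"  {modality}: {n_ev}/{len(sub)} patients with >= 1 episode")

    if TRUTH.exists():
        truth = pd.read_csv(TRUTH)
        errs = []
        for _, row in truth[truth["has_event"]].iterrows():
            first = first_episode(episodes.get(row["patient_id"], []))
            if first is not None:
                errs.append(first.onset - row["true_onset"])
        if errs:
            print(
                f"first-onset error vs ground truth (s): "
                f"median {np.median(errs):.1f}, max |err| {np.max(np.abs(errs)):.1f}"
            )
    print(f"episodes table written to {EPISODES}")


if __name__ == "__main__":
    main()
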