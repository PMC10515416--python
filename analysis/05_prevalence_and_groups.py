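"""Pre-event prevalence of high-risk outputs and group contrasts.

Builds the backward hour-binned prevalence table (share of high-risk
outputs in each hour before the first onset, per modality), the raw
output-distribution table, the per-patient high-risk fractions for
patients with and without an episode, and the rank-sum / t-test contrast
between those groups.
"""

import json
from dataclasses import asdict

import pandas as pd

from common import RESULTS, load_cohort

from ehival.ehi_detection import detect_cohort_episodes
from ehival.group_comparison import compare_groups
from ehival.pre_event_prevalence import cohort_hourly_table, patient_high_fraction
from ehival.risk_strata import category_output_table, category_risks
from ehival.window_eval import cohort_windows


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort()
    episodes = detect_cohort_episodes(cohort)

    category_output_table(cohort).to_csv(RESULTS / "category_counts.csv", index=False)

    risks = {}
    for modality in ("NIBP", "IAP"):
        from ehival.io_streams import Cohort

        sub = Cohort([p for p in cohort if p.modality.value == modality])
        windows = cohort_windows(sub, episodes)
        risks[modality] = [asdict(r) for r in category_risks(windows)]
        high = next(r for r in risks[modality] if r["category"] == "high")
        if high["rr_vs_low"]:
            print(
                f"{modality}: risk of an episode in the next hour given a high "
                f"output {100 * high['risk']:.1f}% "
                f"({high['rr_vs_low']:.1f}x the low-output risk)"
            )
    (RESULTS / "risk_ratios.json").write_text(json.dumps(risks, indent=1))

    for modality, table in cohort_hourly_table(cohort, episodes).items():
        table.to_csv(RESULTS / f"pre_event_prevalence_{modality}.csv", index=False)
        print(
            f"{modality} prevalence 0-1 h before onset: median "
            f"{table['median'].iloc[0]:.1f}% high over {table['n_patients'].iloc[0]} patients"
        )

    rows = []
    for p in cohort:
        if not len(p.alerts):
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "modality": p.modality.value,
                "group": "EHI" if episodes[p.patient_id] else "no_EHI",
                "pct_high": patient_high_fraction(p),
            }
        )
    fr = pd.DataFrame(rows)
    fr.to_csv(RESULTS / "patient_high_fractions.csv", index=False)

    comparisons = {}
    for modality in ("NIBP", "IAP"):
        sub = fr[fr["modality"] == modality]
        a = sub[sub["group"] == "EHI"]["pct_high"]
        b = sub[sub["group"] == "no_EHI"]["pct_high"]
        if len(a) and len(b):
            g = compare_groups(a, b)
            comparisons[modality] = asdict(g)
            print(
                f"{modality}: median high fraction {g.median_a:.1f}% (episode) vs "
                f"{g.median_b:.1f}% (no episode); rank-sum p = {g.rank_sum_p:.2e}, "
                f"t-test p = {g.t_test_p:.2e}"
            )
    (RESULTS / "group_comparison.json").write_text(json.dumps(comparisons, indent=1))
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
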