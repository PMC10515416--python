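"""Prevalence of high-risk outputs in the hours before the first episode.

For each patient with an episode, the hours before its onset are cut into
disjoint one-hour bins counted backward from onset (bin k covers
``[onset - (k+1) h, onset - k h)``; an output exactly at onset belongs to
no bin). Within each bin the statistic is the percentage of that patient's
outputs that were high-risk; a patient enters a bin's summary only when at
least one output falls in it, which is why the per-bin patient count
declines for bins further from onset as monitoring-before-onset runs out.

Also here: the per-patient high-risk fraction over the whole monitored
record, used to contrast patients who did and did not experience an
episode.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_streams import PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "hourly_high_fraction",
    "cohort_bin_stats",
    "patient_high_fraction",
    "cohort_hourly_table",
]


def hourly_high_fraction(
    alerts: pd.DataFrame, first_onset: float, n_hours: int = 5
) -> list[float | None]:
    """Percent of high-risk outputs per backward hour bin for one patient.

    Element k is the percentage (0-100) of outputs in
    ``[first_onset - (k+1)*3600, first_onset - k*3600)`` that are high, or
    None when no output falls in that bin.
    """
    t = alerts["t"].to_numpy(float)
    high = np.asarray(alerts["category"].astype(str)) == "high"
    out: list[float | None] = []
    for k in range(n_hours):
        lo = first_onset - (k + 1) * 3600.0
        hi = first_onset - k * 3600.0
        in_bin = (t >= lo) & (t < hi)
        n = int(in_bin.sum())
        out.append(100.0 * high[in_bin].sum() / n if n else None)
    return out


def cohort_bin_stats(per_patient: list[list[float | None]], n_hours: int = 5) -> pd.DataFrame:
    """Summarise per-patient bin values across a cohort.

    Returns one row per bin with n (patients contributing), median, Q1, Q3
    (linear-interpolation quantiles), mean and sample SD. Empty bins are
    omitted with a warning.
    """
    rows = []
    for k in range(n_hours):
        vals = np.array(
            [p[k] for p in per_patient if k < len(p) and p[k] is not None], dtype=float
        )
        if not len(vals):
            logger.warning("hour bin %d-%d h: no contributing patients, omitted", k, k + 1)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "bin": f"{k}-{k + 1} h",
                "n_patients": int(len(vals)),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def patient_high_fraction(patient: PatientRecord) -> float:
    """Percent of a patient's outputs that are high over the whole record."""
    n = len(patient.alerts)
    if n == 0:
        raise ValueError(f"patient {patient.patient_id} has no alert outputs")
    high = (patient.alerts["category"].astype(str) == "high").sum()
    return 100.0 * float(high) / n


def cohort_hourly_table(
    cohort, episodes_by_patient: dict, n_hours: int = 5
) -> dict[str, pd.DataFrame]:
    """Per-modality backward-hour prevalence tables over episode patients."""
    from .ehi_detection import first_episode

    per_mod: dict[str, list[list[float | None]]] = {"NIBP": [], "IAP": []}
    for p in cohort:
        first = first_episode(episodes_by_patient.get(p.patient_id, []))
        if first is None:
            continue
        per_mod[p.modality.value].append(
            hourly_high_fraction(p.alerts, first.onset, n_hours)
        )
    return {
        m: cohort_bin_stats(vals, n_hours) for m, vals in per_mod.items() if vals
    }
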