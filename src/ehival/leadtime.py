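"""Alert lead time to the first instability episode.

"How far in advance does the analytic *repeatedly* flag high risk before an
event?" — the lead time of a patient is the duration of the unbroken run of
high-risk outputs immediately preceding the onset of their first episode.
A single lower-category output, or a gap longer than the alert cadence
(plus tolerance), breaks the run; earlier, non-contiguous high runs earn no
credit. This is deliberately conservative. Only the first episode per
patient is used, so a run is never ambiguously attributed across episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_streams import PatientRecord

__all__ = [
    "LeadTimeResult",
    "lead_time",
    "monitoring_before",
    "leadtime_stats",
    "cohort_lead_times",
]


@dataclass(frozen=True)
class LeadTimeResult:
    """Lead-time outcome for one patient with an episode.

    ``has_lead`` is true when the latest pre-onset output was high-risk;
    ``lead_hours`` is then the span from the earliest output of that
    unbroken high run to onset.
    """

    patient_id: str
    has_lead: bool
    lead_hours: float | None
    monitor_before_hours: float


def lead_time(
    alerts: pd.DataFrame,
    first_onset: float,
    cadence_s: float = 120.0,
    gap_tol_s: float = 0.0,
    patient_id: str = "",
    monitor_start: float = 0.0,
) -> LeadTimeResult:
    """Walk backward from the last output before onset through the high run.

    Only outputs strictly before ``first_onset`` are considered. The run
    extends while each step is high-category and the time gap to the next
    kept output is at most ``cadence_s + gap_tol_s``. Without any pre-onset
    output, or when the latest one is not high, ``has_lead`` is false.
    """
    t = alerts["t"].to_numpy(float)
    cat = np.asarray(alerts["category"].astype(str))
    before = t < first_onset
    monitor_before_hours = (first_onset - monitor_start) / 3600.0
    if not before.any():
        return LeadTimeResult(patient_id, False, None, monitor_before_hours)
    t, cat = t[before], cat[before]
    if cat[-1] != "high":
        return LeadTimeResult(patient_id, False, None, monitor_before_hours)
    i = len(t) - 1
    while i > 0 and cat[i - 1] == "high" and (t[i] - t[i - 1]) <= cadence_s + gap_tol_s:
        i -= 1
    lead_hours = (first_onset - t[i]) / 3600.0
    return LeadTimeResult(patient_id, True, float(lead_hours), monitor_before_hours)


def monitoring_before(patient: PatientRecord, first_onset: float) -> float:
    """Hours of monitoring available before the first onset."""
    if first_onset < patient.monitor_start or first_onset > patient.monitor_end:
        raise ValueError("onset outside the monitoring interval")
    return (first_onset - patient.monitor_start) / 3600.0


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {
        "n": int(len(values)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def leadtime_stats(results: list[LeadTimeResult]) -> dict:
    """Cohort lead-time summary over patients with at least one episode.

    Returns the fraction of patients with a lead (latest pre-onset output
    high), distribution summaries of ``lead_hours`` over those patients,
    and of monitoring-before-onset hours over all episode patients.
    Quantiles use linear interpolation; SD is the sample SD (n-1).
    """
    if not results:
        raise ValueError("no lead-time results to summarise")
    n = len(results)
    with_lead = [r for r in results if r.has_lead]
    out = {
        "n_patients": n,
        "n_with_lead": len(with_lead),
        "frac_with_lead": len(with_lead) / n,
        "monitor_before_hours": _summary(
            np.array([r.monitor_before_hours for r in results])
        ),
    }
    if with_lead:
        out["lead_hours"] = _summary(np.array([r.lead_hours for r in with_lead]))
    else:
        out["lead_hours"] = None
    return out


def cohort_lead_times(
    cohort,
    episodes_by_patient: dict,
    cadence_s: float = 120.0,
    gap_tol_s: float = 0.0,
) -> list[LeadTimeResult]:
    """Per-patient lead times for every patient with a detected episode."""
    from .ehi_detection import first_episode

    results = []
    for p in cohort:
        first = first_episode(episodes_by_patient.get(p.patient_id, []))
        if first is None:
            continue
        results.append(
            lead_time(
                p.alerts,
                first.onset,
                cadence_s=cadence_s,
                gap_tol_s=gap_tol_s,
                patient_id=p.patient_id,
                monitor_start=p.monitor_start,
            )
        )
    return results
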