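"""Detection of episodes of hemodynamic instability (EHI) from vital signs.

An instant qualifies as unstable when tachycardia and hypotension co-occur:
heart rate >= 100 bpm together with systolic pressure < 90 mmHg or mean
arterial pressure < 70 mmHg. The episode rule is modality specific:

* **IAP** (continuous, 0.5 Hz): the unstable state must be *sustained* —
  a maximal run of consecutive qualifying samples becomes an episode only
  when it spans at least 10 minutes. Samples are "consecutive" when spaced
  at most ``gap_tol_s`` apart (default 4 s, two nominal sample intervals);
  a larger gap, or a sample with missing heart rate, breaks the run.
* **NIBP** (intermittent, ~hourly validated measurements): every qualifying
  measurement is an episode on its own; adjacent qualifying measurements
  (no non-qualifying measurement between them) merge into one episode. No
  sustain requirement — with hourly charting it would be unverifiable.

Thresholds are configurable via :class:`EHICriteria`; the heart-rate
threshold is inclusive by default (>= 100), with ``hr_inclusive=False``
available for the strict-inequality variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_streams import Modality, PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EHICriteria",
    "EHIEpisode",
    "instantaneous_unstable",
    "qualifying_mask",
    "detect_episodes_iap",
    "detect_episodes_nibp",
    "detect_episodes",
    "detect_cohort_episodes",
    "first_episode",
]


@dataclass(frozen=True)
class EHICriteria:
    """Thresholds and run parameters of the instability definition.

    ``sustain_s`` and ``gap_tol_s`` apply to the continuous (IAP) rule only.
    """

    hr_threshold: float = 100.0  # bpm, inclusive by default
    sbp_threshold: float = 90.0  # mmHg, qualifying strictly below
    map_threshold: float = 70.0  # mmHg, qualifying strictly below
    sustain_s: float = 600.0
    gap_tol_s: float = 4.0
    hr_inclusive: bool = True

    def __post_init__(self) -> None:
        if min(self.hr_threshold, self.sbp_threshold, self.map_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.sustain_s < 0:
            raise ValueError("sustain_s must be >= 0")


@dataclass(frozen=True)
class EHIEpisode:
    """One detected instability episode, ``onset <= offset`` in seconds."""

    patient_id: str
    onset: float
    offset: float
    rule: str  # "IAP_sustained" or "NIBP_point"

    def __post_init__(self) -> None:
        if self.onset > self.offset:
            raise ValueError("episode onset after offset")

    def overlaps(self, start: float, stop: float) -> bool:
        """True when [onset, offset] intersects the half-open [start, stop)."""
        return self.onset < stop and self.offset >= start


def instantaneous_unstable(
    hr: float, sbp: float, map_: float, criteria: EHICriteria = EHICriteria()
) -> bool:
    """Evaluate the instability predicate at a single sample.

    Heart rate must be present; a missing pressure channel simply cannot
    satisfy its clause. Raises ``ValueError`` when heart rate is missing or
    both pressures are (callers skip such samples).
    """
    if hr is None or np.isnan(hr):
        raise ValueError("heart rate missing at sample")
    sbp_miss = sbp is None or np.isnan(sbp)
    map_miss = map_ is None or np.isnan(map_)
    if sbp_miss and map_miss:
        raise ValueError("both pressure channels missing at sample")
    c = criteria
    tachy = hr >= c.hr_threshold if c.hr_inclusive else hr > c.hr_threshold
    hypo = (not sbp_miss and sbp < c.sbp_threshold) or (
        not map_miss and map_ < c.map_threshold
    )
    return bool(tachy and hypo)


def qualifying_mask(patient: PatientRecord, criteria: EHICriteria) -> np.ndarray:
    """Vectorised predicate over a patient's vitals.

    Returns a boolean array aligned with ``patient.vitals``; samples missing
    heart rate or both pressures are False (and counted in a debug log).
    """
    v = patient.vitals
    hr = v["hr"].to_numpy(float)
    sbp = v["sbp"].to_numpy(float)
    map_ = v["map"].to_numpy(float)
    evaluable = ~np.isnan(hr) & (~np.isnan(sbp) | ~np.isnan(map_))
    n_skip = int((~evaluable).sum())
    if n_skip:
        logger.debug("patient %s: %d unevaluable sample(s) skipped", patient.patient_id, n_skip)
    c = criteria
    tachy = hr >= c.hr_threshold if c.hr_inclusive else hr > c.hr_threshold
    with np.errstate(invalid="ignore"):
        hypo = (sbp < c.sbp_threshold) | (map_ < c.map_threshold)
    return evaluable & tachy & np.nan_to_num(hypo, nan=False).astype(bool)


def _runs(t: np.ndarray, ok: np.ndarray, gap_tol_s: float):
    """Maximal runs of True in ``ok`` where consecutive kept samples are
    spaced <= gap_tol_s; non-qualifying samples break runs. Yields (i, j)
    index pairs (inclusive)."""
    runs = []
    start = None
    for i in range(len(t)):
        if not ok[i]:
            if start is not None:
                runs.append((start, i - 1))
                start = None
            continue
        if start is None:
            start = i
        elif t[i] - t[i - 1] > gap_tol_s:
            runs.append((start, i - 1))
            start = i
    if start is not None:
        runs.append((start, len(t) - 1))
    return runs


def detect_episodes_iap(
    patient: PatientRecord, criteria: EHICriteria = EHICriteria()
) -> list[EHIEpisode]:
    """Sustained-rule detector for continuously monitored patients.

    A maximal run of qualifying samples (inter-sample spacing
    <= ``gap_tol_s``) is an episode iff its span, last time minus first
    time, is at least ``sustain_s``. Span, not sample count, is used so the
    rule is robust to sampling jitter.
    """
    if patient.modality != Modality.IAP:
        raise ValueError("detect_episodes_iap requires an IAP patient")
    if not len(patient.vitals):
        return []
    t = patient.vitals["t"].to_numpy(float)
    ok = qualifying_mask(patient, criteria)
    episodes = []
    for i, j in _runs(t, ok, criteria.gap_tol_s):
        if t[j] - t[i] >= criteria.sustain_s:
            episodes.append(
                EHIEpisode(patient.patient_id, float(t[i]), float(t[j]), "IAP_sustained")
            )
    return episodes


def detect_episodes_nibp(
    patient: PatientRecord, criteria: EHICriteria = EHICriteria()
) -> list[EHIEpisode]:
    """Point-rule detector for intermittently monitored patients.

    Each qualifying validated measurement opens an episode; adjacent
    qualifying measurements merge. A single qualifying measurement yields a
    point episode (onset == offset).
    """
    if patient.modality != Modality.NIBP:
        raise ValueError("detect_episodes_nibp requires an NIBP patient")
    if not len(patient.vitals):
        return []
    t = patient.vitals["t"].to_numpy(float)
    ok = qualifying_mask(patient, criteria)
    episodes = []
    for i, j in _runs(t, ok, np.inf):
        episodes.append(
            EHIEpisode(patient.patient_id, float(t[i]), float(t[j]), "NIBP_point")
        )
    return episodes


def detect_episodes(
    patient: PatientRecord, criteria: EHICriteria = EHICriteria()
) -> list[EHIEpisode]:
    """Modality dispatch: sustained rule for IAP, point rule for NIBP."""
    if patient.modality == Modality.IAP:
        return detect_episodes_iap(patient, criteria)
    return detect_episodes_nibp(patient, criteria)


def detect_cohort_episodes(cohort, criteria: EHICriteria = EHICriteria()):
    """Map patient_id -> time-ordered episode list over a whole cohort."""
    return {p.patient_id: detect_episodes(p, criteria) for p in cohort}


def first_episode(episodes: list[EHIEpisode]) -> EHIEpisode | None:
    """Earliest episode of a time-ordered list, or None when empty.

    Lead-time statistics use only the first episode per patient, to avoid
    ambiguity in attributing alert runs to one of several episodes.
    """
    onsets = [e.onset for e in episodes]
    if onsets != sorted(onsets):
        raise ValueError("episodes must be time-ordered")
    return episodes[0] if episodes else None
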