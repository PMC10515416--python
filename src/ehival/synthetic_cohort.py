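"""Seeded generator of synthetic monitored cohorts with known ground truth.

The hospital data behind this kind of validation study are restricted and
the predictive analytic is proprietary, so every downstream stage is
exercised on simulated cohorts that reproduce the *statistical structure*
the analysis assumes:

* two monitoring modalities with their cadences — intermittent cuff
  measurements roughly hourly (with +/-20% jitter) versus a 0.5 Hz
  arterial line — mixed in a configurable proportion;
* a per-patient event process: with modality-specific probability a patient
  carries one contiguous instability interval, placed at a configurable
  fraction of a log-normally distributed monitoring duration, during which
  every generated sample satisfies the instability predicate (heart rate
  >= 100 bpm with systolic < 90 mmHg or mean arterial pressure < 70 mmHg),
  with a linear ramp of at most five minutes on each side;
* an alert stream at a two-minute cadence whose high-risk probability
  switches from a background rate to ``p_high_pre`` over the interval from
  ``lead_hours`` before onset through the end of the event, moderate
  outputs filling at a constant background rate. Categories are drawn
  independently given the regime — the simplest coupling that gives every
  downstream statistic a known target.

Mean arterial pressure is derived as (SBP + 2 DBP)/3 with DBP = SBP minus a
pulse-pressure draw, so MAP <= SBP always holds. Cuff-monitored event
patients get one charted measurement exactly at onset (a nurse charting a
reading during deterioration); hourly sampling would otherwise miss most
sub-hour events entirely and no point-rule detector could recover them.

Default incidence structure (9.6% of NIBP patients, 46.4% of IAP patients
with an event) and the 85.5/14.5 modality split mirror the cohort the
analysis was designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ehi_detection import EHIEpisode
from .io_streams import Cohort, Modality, PatientRecord, _categorical

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "truth_episodes"]

#: vital-sign levels inside an event, chosen to clear the thresholds with
#: margin while staying physiologically plausible (compensated shock)
EVENT_HR_MEAN, EVENT_HR_SD = 115.0, 5.0
EVENT_SBP_MEAN, EVENT_SBP_SD = 78.0, 5.0
PULSE_PRESSURE_MEAN, PULSE_PRESSURE_SD = 40.0, 5.0
RAMP_S = 300.0  # transition on each side of the event interval


@dataclass(frozen=True)
class CohortConfig:
    """Simulator parameters. All probabilities are per-patient or per-output.

    ``monitor_hours_median``/``monitor_hours_sigma`` parameterise a
    log-normal monitoring duration (hours); ``onset_fraction_range`` places
    the event onset as a uniform fraction of the monitoring duration;
    ``lead_hours`` is the pre-onset interval during which the alert stream
    runs at ``p_high_pre`` instead of the ``p_high_stable`` background.
    """

    n_patients: int = 500
    frac_iap: float = 0.145
    p_ehi_nibp: float = 0.096
    p_ehi_iap: float = 0.464
    monitor_hours_median: float = 12.0
    monitor_hours_sigma: float = 0.8
    onset_fraction_range: tuple[float, float] = (0.3, 0.8)
    event_duration_min: float = 30.0
    lead_hours: float = 2.0
    p_high_pre: float = 0.9
    p_high_stable: float = 0.05
    p_mod_stable: float = 0.10
    alert_cadence_s: float = 120.0
    nibp_interval_s: float = 3600.0
    iap_hz: float = 0.5
    baseline_hr_mean: float = 75.0
    baseline_hr_sd: float = 8.0
    baseline_sbp_mean: float = 125.0
    baseline_sbp_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.frac_iap, self.p_ehi_nibp, self.p_ehi_iap,
            self.p_high_pre, self.p_high_stable, self.p_mod_stable,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if max(self.p_high_pre, self.p_high_stable) + self.p_mod_stable > 1.0:
            raise ValueError("p_high + p_mod_stable must not exceed 1")
        if self.lead_hours < 0:
            raise ValueError("lead_hours must be >= 0")
        lo, hi = self.onset_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("onset_fraction_range must lie inside (0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "onset_fraction_range" in raw:
            raw["onset_fraction_range"] = tuple(raw["onset_fraction_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["onset_fraction_range"] = list(d["onset_fraction_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class GroundTruth:
    """Per-patient event truth: ``patient_id, modality, has_event,
    true_onset, true_offset`` (onset/offset NaN without an event)."""

    table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def event_patients(self) -> pd.DataFrame:
        return self.table[self.table["has_event"]]

    def onset_of(self, patient_id: str) -> float | None:
        row = self.table[self.table["patient_id"] == patient_id]
        if not len(row) or not bool(row["has_event"].iloc[0]):
            return None
        return float(row["true_onset"].iloc[0])


def _nibp_times(rng: np.random.Generator, duration_s: float, nominal_s: float) -> np.ndarray:
    """Hourly-ish measurement grid: nominal interval with +/-20% jitter."""
    n_max = int(duration_s / (0.8 * nominal_s)) + 2
    gaps = nominal_s * rng.uniform(0.8, 1.2, size=n_max)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    return t[t <= duration_s]


def _event_weight(t: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """1 inside [onset, offset], linear ramp over RAMP_S on each side."""
    up = (t - (onset - RAMP_S)) / RAMP_S
    down = ((offset + RAMP_S) - t) / RAMP_S
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def _vitals(
    rng: np.random.Generator,
    t: np.ndarray,
    cfg: CohortConfig,
    onset: float | None,
    offset: float | None,
) -> pd.DataFrame:
    n = len(t)
    hr = rng.normal(cfg.baseline_hr_mean, cfg.baseline_hr_sd, n)
    sbp = rng.normal(cfg.baseline_sbp_mean, cfg.baseline_sbp_sd, n)
    ramp = None
    if onset is not None:
        w = _event_weight(t, onset, offset)
        hr_ev = rng.normal(EVENT_HR_MEAN, EVENT_HR_SD, n)
        sbp_ev = rng.normal(EVENT_SBP_MEAN, EVENT_SBP_SD, n)
        hr = (1 - w) * hr + w * hr_ev
        sbp = (1 - w) * sbp + w * sbp_ev
        core = w >= 1.0
        ramp = (w > 0.0) & ~core
        # the event interval satisfies the predicate by construction
        hr[core] = np.maximum(hr[core], 100.5)
        sbp[core] = np.minimum(sbp[core], 89.0)
    pp = np.maximum(rng.normal(PULSE_PRESSURE_MEAN, PULSE_PRESSURE_SD, n), 5.0)
    sbp = np.maximum(sbp, 40.0)
    hr = np.maximum(hr, 20.0)
    map_ = sbp - 2.0 * pp / 3.0  # (sbp + 2 dbp) / 3 with dbp = sbp - pp
    if ramp is not None and ramp.any():
        # compensated phase: heart rate climbs through the ramp while the
        # pressures hold just above the hypotension thresholds, collapsing
        # only at the event boundary — so the qualifying interval is exactly
        # [onset, offset] and detection aligns with the ground truth
        sbp[ramp] = np.maximum(sbp[ramp], 90.5)
        map_[ramp] = np.minimum(np.maximum(map_[ramp], 70.5), sbp[ramp])
    return pd.DataFrame({"t": t, "hr": hr, "sbp": sbp, "map": map_})


def _alerts(
    rng: np.random.Generator,
    duration_s: float,
    cfg: CohortConfig,
    onset: float | None,
    offset: float | None,
) -> pd.DataFrame:
    t = np.arange(0.0, duration_s + 1e-9, cfg.alert_cadence_s)
    t = t[t <= duration_s]
    p_high = np.full(len(t), cfg.p_high_stable)
    if onset is not None:
        # elevated regime covers the lead interval AND the event itself
        hot = (t >= onset - cfg.lead_hours * 3600.0) & (t <= offset)
        p_high[hot] = cfg.p_high_pre
    u = rng.random(len(t))
    codes = np.where(u < p_high, 2, np.where(u < p_high + cfg.p_mod_stable, 1, 0))
    cats = np.array(["low", "moderate", "high"])[codes]
    return pd.DataFrame({"t": t, "category": _categorical(cats)})


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth, deterministic given the seed.

    Event patients carry exactly one event. Monitoring durations too short
    to contain the event at an onset fraction inside the configured range
    are redrawn (at most 100 attempts, then ``RuntimeError``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    event_s = cfg.event_duration_min * 60.0
    lo, hi = cfg.onset_fraction_range

    patients: list[PatientRecord] = []
    truth_rows = []
    width = len(str(cfg.n_patients))
    for i in range(cfg.n_patients):
        pid = f"S{i:0{width}d}"
        modality = Modality.IAP if rng.random() < cfg.frac_iap else Modality.NIBP
        p_event = cfg.p_ehi_iap if modality == Modality.IAP else cfg.p_ehi_nibp
        has_event = rng.random() < p_event

        mu = np.log(cfg.monitor_hours_median)
        for attempt in range(100):
            duration_s = float(np.exp(rng.normal(mu, cfg.monitor_hours_sigma)) * 3600.0)
            if duration_s <= 0:
                continue
            if not has_event or lo * duration_s + event_s <= duration_s:
                break
        else:
            raise RuntimeError("could not draw a feasible monitoring duration")

        onset = offset = None
        if has_event:
            f_hi = min(hi, (duration_s - event_s) / duration_s)
            onset = float(rng.uniform(lo, f_hi) * duration_s)
            offset = onset + event_s

        if modality == Modality.IAP:
            t_v = np.arange(0.0, duration_s + 1e-9, 1.0 / cfg.iap_hz)
            t_v = t_v[t_v <= duration_s]
        else:
            t_v = _nibp_times(rng, duration_s, cfg.nibp_interval_s)
            if has_event:  # charted measurement at deterioration
                t_v = np.unique(np.append(t_v, onset))
        vitals = _vitals(rng, t_v, cfg, onset, offset)
        alerts = _alerts(rng, duration_s, cfg, onset, offset)
        patients.append(
            PatientRecord(
                patient_id=pid,
                modality=modality,
                vitals=vitals,
                alerts=alerts,
                monitor_start=0.0,
                monitor_end=duration_s,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "modality": modality.value,
                "has_event": bool(has_event),
                "true_onset": onset if has_event else np.nan,
                "true_offset": offset if has_event else np.nan,
            }
        )

    cohort = Cohort(patients=patients, provenance=f"synthetic cohort, seed={cfg.seed}")
    return cohort, GroundTruth(pd.DataFrame(truth_rows))


def truth_episodes(gt: GroundTruth) -> list[EHIEpisode]:
    """Ground-truth event intervals as episodes (rule ``truth``), one row
    per event patient, for comparison against detector output."""
    out = []
    for _, r in gt.event_patients.iterrows():
        out.append(
            EHIEpisode(
                patient_id=str(r["patient_id"]),
                onset=float(r["true_onset"]),
                offset=float(r["true_offset"]),
                rule="truth",
            )
        )
    return out
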