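"""Data model and CSV I/O for cohorts of monitored patients.

A monitored encounter couples two irregular time series, both expressed in
seconds from the start of monitoring:

* a vital-sign stream (heart rate, systolic and mean arterial pressure),
  sampled roughly hourly for cuff-based (NIBP) patients or at 0.5 Hz for
  patients with an arterial line (IAP);
* a three-level alert stream (low < moderate < high) emitted nominally every
  two minutes by a predictive analytic, treated here as an opaque score.

Times are relative durations, not wall clock: the source data are
deidentified and every downstream statistic is a duration or a rate.

File formats (UTF-8 CSV, ``.`` decimal separator):

* vitals:  ``patient_id,modality,t_seconds,hr,sbp,map`` — modality is
  ``NIBP`` or ``IAP`` and constant per patient; empty cell means missing.
* alerts:  ``patient_id,t_seconds,category`` — category is
  ``low``/``moderate``/``high``; the monitor-color aliases
  ``green``/``yellow``/``red`` are accepted on input and normalised.
* episodes (written by :mod:`ehival.ehi_detection`):
  ``patient_id,onset_seconds,offset_seconds,rule``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "ALERT_CATEGORIES",
    "CATEGORY_ALIASES",
    "PatientRecord",
    "Cohort",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
]

#: Ordered alert levels, lowest risk first.
ALERT_CATEGORIES = ("low", "moderate", "high")

#: Monitor-color vocabulary mapped onto the canonical levels.
CATEGORY_ALIASES = {"green": "low", "yellow": "moderate", "red": "high"}

VITALS_COLUMNS = ["t", "hr", "sbp", "map"]
ALERTS_COLUMNS = ["t", "category"]


class Modality(str, Enum):
    """Blood-pressure monitoring modality of an encounter."""

    NIBP = "NIBP"  # intermittent cuff, charted ~hourly after validation
    IAP = "IAP"  # continuous intra-arterial line, 0.5 Hz


class CohortParseError(ValueError):
    """Raised for malformed rows; message names file, line and field."""


def _empty_vitals() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in VITALS_COLUMNS})


def _empty_alerts() -> pd.DataFrame:
    return pd.DataFrame(
        {"t": pd.Series(dtype=float), "category": _categorical([])}
    )


def _categorical(values: Iterable[str]) -> pd.Categorical:
    return pd.Categorical(list(values), categories=ALERT_CATEGORIES, ordered=True)


@dataclass
class PatientRecord:
    """One monitored encounter.

    ``vitals`` has float columns ``t, hr, sbp, map`` (NaN = missing channel);
    ``alerts`` has ``t`` (float seconds) and ``category`` (ordered
    categorical low < moderate < high). Both are sorted by ``t`` with
    strictly increasing times. ``monitor_start``/``monitor_end`` bound the
    observation interval; by convention monitoring starts at 0 and, when not
    stated otherwise, ends at the last recorded sample.
    """

    patient_id: str
    modality: Modality
    vitals: pd.DataFrame = field(default_factory=_empty_vitals)
    alerts: pd.DataFrame = field(default_factory=_empty_alerts)
    monitor_start: float = 0.0
    monitor_end: float | None = None

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.vitals = self.vitals.reset_index(drop=True)
        self.alerts = self.alerts.reset_index(drop=True)
        if not isinstance(self.alerts["category"].dtype, pd.CategoricalDtype):
            self.alerts = self.alerts.assign(
                category=_categorical(self.alerts["category"])
            )
        if self.monitor_end is None:
            last = [self.monitor_start]
            if len(self.vitals):
                last.append(float(self.vitals["t"].iloc[-1]))
            if len(self.alerts):
                last.append(float(self.alerts["t"].iloc[-1]))
            self.monitor_end = max(last)
        self._validate()

    def _validate(self) -> None:
        for name, df in (("vitals", self.vitals), ("alerts", self.alerts)):
            t = df["t"].to_numpy(dtype=float)
            if len(t) and not np.all(np.diff(t) > 0):
                raise ValueError(
                    f"patient {self.patient_id}: {name} times not strictly increasing"
                )
            if len(t) and (t[0] < self.monitor_start or t[-1] > self.monitor_end):
                raise ValueError(
                    f"patient {self.patient_id}: {name} times outside "
                    f"[{self.monitor_start}, {self.monitor_end}]"
                )
        v = self.vitals
        both = v["sbp"].notna() & v["map"].notna()
        bad = both & (v["map"] > v["sbp"])
        if bad.any():
            logger.warning(
                "patient %s: %d sample(s) with MAP > SBP (kept, flagged)",
                self.patient_id,
                int(bad.sum()),
            )

    @property
    def duration_s(self) -> float:
        return float(self.monitor_end - self.monitor_start)

    def equals(self, other: "PatientRecord") -> bool:
        return (
            self.patient_id == other.patient_id
            and self.modality == other.modality
            and np.isclose(self.monitor_start, other.monitor_start)
            and np.isclose(self.monitor_end, other.monitor_end)
            and _frames_equal(self.vitals, other.vitals)
            and _frames_equal(self.alerts, other.alerts)
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b) or list(a.columns) != list(b.columns):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if x.dtype.kind == "f":
            if not np.allclose(
                x.to_numpy(), y.to_numpy(dtype=float), equal_nan=True, atol=1e-6
            ):
                return False
        elif not (x.astype(str).to_numpy() == y.astype(str).to_numpy()).all():
            return False
    return True


@dataclass
class Cohort:
    """A sequence of patient records plus free-text provenance."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def by_modality(self, modality: Modality) -> list[PatientRecord]:
        modality = Modality(modality)
        return [p for p in self.patients if p.modality == modality]

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def equals(self, other: "Cohort") -> bool:
        return len(self) == len(other) and all(
            a.equals(b) for a, b in zip(self.patients, other.patients)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, expected: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path, allow_missing: bool) -> pd.Series:
    raw = df[col].str.strip()
    out = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = out.isna() & (raw != "")
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise CohortParseError(
            f"{path}: line {line}: field '{col}': not a number: {raw[bad].iloc[0]!r}"
        )
    if not allow_missing and out.isna().any():
        line = int(df.index[out.isna()][0]) + 2
        raise CohortParseError(f"{path}: line {line}: field '{col}': value required")
    return out


def read_cohort(vitals_path: str | Path, alerts_path: str | Path) -> Cohort:
    """Read a cohort from a vitals CSV and an alerts CSV.

    Rows are sorted by ``(patient_id, t)``; a patient present in only one of
    the two files gets an empty stream for the other (with a logged warning).
    Malformed numerics, unknown categories and duplicate alert timestamps
    raise :class:`CohortParseError`.
    """
    vpath, apath = Path(vitals_path), Path(alerts_path)
    vdf = _read_csv(vpath, ["patient_id", "modality", "t_seconds", "hr", "sbp", "map"])
    adf = _read_csv(apath, ["patient_id", "t_seconds", "category"])

    vdf = vdf.assign(
        t=_to_float(vdf, "t_seconds", vpath, allow_missing=False),
        hr=_to_float(vdf, "hr", vpath, allow_missing=True),
        sbp=_to_float(vdf, "sbp", vpath, allow_missing=True),
        map=_to_float(vdf, "map", vpath, allow_missing=True),
    )
    bad_mod = ~vdf["modality"].isin([m.value for m in Modality])
    if bad_mod.any():
        line = int(vdf.index[bad_mod][0]) + 2
        raise CohortParseError(
            f"{vpath}: line {line}: field 'modality': "
            f"unknown value {vdf['modality'][bad_mod].iloc[0]!r}"
        )

    cat = adf["category"].str.strip().str.lower().replace(CATEGORY_ALIASES)
    bad_cat = ~cat.isin(ALERT_CATEGORIES)
    if bad_cat.any():
        line = int(adf.index[bad_cat][0]) + 2
        raise CohortParseError(
            f"{apath}: line {line}: field 'category': "
            f"unknown value {adf['category'][bad_cat].iloc[0]!r}"
        )
    adf = adf.assign(t=_to_float(adf, "t_seconds", apath, allow_missing=False), category=cat)
    dup = adf.duplicated(subset=["patient_id", "t"])
    if dup.any():
        line = int(adf.index[dup][0]) + 2
        raise CohortParseError(
            f"{apath}: line {line}: duplicate (patient_id, t) in alerts"
        )

    v_ids = list(dict.fromkeys(vdf["patient_id"]))
    a_ids = list(dict.fromkeys(adf["patient_id"]))
    only_v = [i for i in v_ids if i not in set(a_ids)]
    only_a = [i for i in a_ids if i not in set(v_ids)]
    for pid in only_v:
        logger.warning("patient %s has vitals but no alerts", pid)
    for pid in only_a:
        logger.warning("patient %s has alerts but no vitals", pid)
    all_ids = v_ids + [i for i in a_ids if i not in set(v_ids)]

    v_groups = dict(tuple(vdf.groupby("patient_id", sort=False)))
    a_groups = dict(tuple(adf.groupby("patient_id", sort=False)))

    patients = []
    for pid in all_ids:
        pv = v_groups.get(pid)
        pa = a_groups.get(pid)
        if pv is not None:
            mods = pv["modality"].unique()
            if len(mods) > 1:
                raise CohortParseError(
                    f"{vpath}: patient {pid}: modality not constant ({list(mods)})"
                )
            modality = Modality(mods[0])
            vitals = pv.sort_values("t")[VITALS_COLUMNS].reset_index(drop=True)
            dup_t = vitals["t"].duplicated()
            if dup_t.any():
                raise CohortParseError(
                    f"{vpath}: patient {pid}: duplicate vitals timestamp "
                    f"{vitals['t'][dup_t].iloc[0]}"
                )
        else:
            modality = Modality.NIBP
            vitals = _empty_vitals()
            logger.warning("patient %s: modality defaulted to NIBP (no vitals)", pid)
        if pa is not None:
            pa = pa.sort_values("t")
            alerts = pd.DataFrame(
                {"t": pa["t"].to_numpy(float), "category": _categorical(pa["category"])}
            )
        else:
            alerts = _empty_alerts()
        patients.append(
            PatientRecord(patient_id=pid, modality=modality, vitals=vitals, alerts=alerts)
        )
    return Cohort(patients=patients, provenance=f"read from {vpath} + {apath}")


def write_cohort(
    cohort: Cohort, vitals_path: str | Path, alerts_path: str | Path
) -> None:
    """Write a cohort back to the two-file CSV layout.

    Round-trips through :func:`read_cohort` field-for-field (times with three
    decimal places; missing channels as empty cells, never zeros). Monitoring
    bounds are not stored: on re-read they are inferred from the last sample.
    """
    vcols = ["patient_id", "modality", "t_seconds", "hr", "sbp", "map"]
    acols = ["patient_id", "t_seconds", "category"]
    vframes, aframes = [], []
    for p in cohort:
        if len(p.vitals):
            vframes.append(
                p.vitals.rename(columns={"t": "t_seconds"}).assign(
                    patient_id=p.patient_id, modality=p.modality.value
                )[vcols]
            )
        if len(p.alerts):
            aframes.append(
                p.alerts.rename(columns={"t": "t_seconds"})
                .assign(patient_id=p.patient_id, category=p.alerts["category"].astype(str))[acols]
            )
    vdf = pd.concat(vframes, ignore_index=True) if vframes else pd.DataFrame(columns=vcols)
    adf = pd.concat(aframes, ignore_index=True) if aframes else pd.DataFrame(columns=acols)
    vdf.to_csv(vitals_path, index=False, float_format="%.3f", na_rep="")
    adf.to_csv(alerts_path, index=False, float_format="%.3f", na_rep="")


def write_episodes(episodes, path: str | Path) -> None:
    """Write detected episodes as ``patient_id,onset_seconds,offset_seconds,rule``."""
    rows = [
        {
            "patient_id": e.patient_id,
            "onset_seconds": f"{e.onset:.3f}",
            "offset_seconds": f"{e.offset:.3f}",
            "rule": e.rule,
        }
        for e in episodes
    ]
    cols = ["patient_id", "onset_seconds", "offset_seconds", "rule"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_episodes(path: str | Path) -> pd.DataFrame:
    """Read an episodes CSV into a DataFrame with float onset/offset."""
    df = _read_csv(Path(path), ["patient_id", "onset_seconds", "offset_seconds", "rule"])
    return df.assign(
        onset=_to_float(df, "onset_seconds", Path(path), allow_missing=False),
        offset=_to_float(df, "offset_seconds", Path(path), allow_missing=False),
    )[["patient_id", "onset", "offset", "rule"]]
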