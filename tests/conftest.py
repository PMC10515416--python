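"""Shared fixtures and small builders for the test suite.

Fixtures build patients and cohorts programmatically; no data files are
shipped. Random content is always drawn from a seeded generator so every
run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ehival.io_streams import Cohort, Modality, PatientRecord, _categorical


def make_patient(
    patient_id="P1",
    modality="NIBP",
    t_vitals=(),
    hr=(),
    sbp=(),
    map_=None,
    t_alerts=(),
    categories=(),
    monitor_end=None,
):
    """Assemble a PatientRecord from plain sequences."""
    t_vitals = np.asarray(t_vitals, dtype=float)
    n = len(t_vitals)
    vitals = pd.DataFrame(
        {
            "t": t_vitals,
            "hr": np.asarray(hr, dtype=float) if len(t_vitals) else np.array([]),
            "sbp": np.asarray(sbp, dtype=float) if len(t_vitals) else np.array([]),
            "map": (
                np.asarray(map_, dtype=float)
                if map_ is not None
                else np.full(n, np.nan)
            ),
        }
    )
    alerts = pd.DataFrame(
        {
            "t": np.asarray(t_alerts, dtype=float),
            "category": _categorical(categories),
        }
    )
    return PatientRecord(
        patient_id=patient_id,
        modality=Modality(modality),
        vitals=vitals,
        alerts=alerts,
        monitor_end=monitor_end,
    )


def random_cohort(rng: np.random.Generator, n_patients=4) -> Cohort:
    """Small random cohort with mixed modalities and missing channels."""
    patients = []
    for i in range(n_patients):
        modality = "IAP" if rng.random() < 0.5 else "NIBP"
        n_v = int(rng.integers(0, 8))
        n_a = int(rng.integers(0, 8))
        t_v = np.sort(rng.uniform(0, 7200, n_v).round(3))
        t_v = np.unique(t_v)
        n_v = len(t_v)
        hr = rng.uniform(50, 150, n_v).round(3)
        sbp = rng.uniform(70, 180, n_v).round(3)
        map_ = sbp - rng.uniform(10, 40, n_v).round(3)
        # knock out some channels
        hr[rng.random(n_v) < 0.2] = np.nan
        map_[rng.random(n_v) < 0.3] = np.nan
        t_a = np.unique(rng.uniform(0, 7200, n_a).round(3))
        cats = rng.choice(["low", "moderate", "high"], len(t_a))
        patients.append(
            make_patient(
                patient_id=f"R{i}",
                modality=modality,
                t_vitals=t_v,
                hr=hr,
                sbp=sbp,
                map_=map_,
                t_alerts=t_a,
                categories=cats,
            )
        )
    return Cohort(patients=patients, provenance="random test cohort")


def random_windows(rng: np.random.Generator, n: int, p_pos=0.4) -> pd.DataFrame:
    """Random labelled window table over a couple of patients."""
    return pd.DataFrame(
        {
            "patient_id": rng.choice(["A", "B", "C"], n),
            "t": np.arange(n, dtype=float) * 120,
            "category": _categorical(rng.choice(["low", "moderate", "high"], n)),
            "label": rng.random(n) < p_pos,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20241005)
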