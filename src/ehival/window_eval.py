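"""Window-level evaluation of the alert stream against detected episodes.

Every alert output opens a one-hour forward-looking window: the output is
scored against whether an episode of hemodynamic instability (EHI) occurs
in ``[t, t + horizon)``. Outputs whose full horizon is not observed
(monitoring ends first) are dropped, not labelled negative — absence of
observation is not absence of an event. Low and moderate outputs are
grouped as the negative prediction; high is positive (configurable via
``positive_set``).

All window-level statistics — the confusion-derived suite, the ordinal
three-level ROC AUC and the PR area — are functions of the pooled 3x2
(category x label) contingency table, which is what makes the
patient-level bootstrap cheap: each patient is reduced to their table once
and resampling sums tables.

Tie handling for the ordinal AUC: with only three score levels, massive
ties are the norm. The AUC is the Mann-Whitney probability
``P(score_pos > score_neg) + 0.5 P(score_pos = score_neg)`` over all
positive-negative window pairs, equivalent to the trapezoidal area through
the two interior operating points of the three-level ROC.

The PR area uses linear-in-recall interpolation between the operating
points at thresholds {>= high, >= moderate, >= low}, anchored at
``(recall 0, precision of the first point)``; an uninformative score then
yields an area equal to the incidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehi_detection import EHIEpisode
from .io_streams import ALERT_CATEGORIES, Cohort, PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EvalWindows",
    "ConfusionCounts",
    "MetricSet",
    "label_windows",
    "cohort_windows",
    "binarize",
    "confusion",
    "metrics",
    "category_label_table",
    "ordinal_roc_auc",
    "ordinal_pr_auprc",
    "bootstrap_ci",
    "full_metrics",
    "metrics_from_summary",
]

WINDOW_COLUMNS = ["patient_id", "t", "category", "label"]
DEFAULT_HORIZON_S = 3600.0
DEFAULT_POSITIVE = frozenset({"high"})

#: category -> ordinal score used by the ROC/PR machinery
_SCORE = {c: i for i, c in enumerate(ALERT_CATEGORIES)}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricSet:
    """Confusion-derived metrics plus ordinal AUC/AUPRC, all on [0, 1].

    Undefined ratios (zero denominator) are NaN, never silently 0. ``ci``
    maps a metric name to its (low, high) bootstrap percentile interval.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    f1: float
    incidence: float
    n_windows: int
    auc: float = float("nan")
    auprc: float = float("nan")
    ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "sensitivity specificity ppv npv fpr fnr f1 incidence "
                "auc auprc n_windows".split()
            )
        }
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def label_windows(
    patient: PatientRecord,
    episodes: list[EHIEpisode],
    horizon_s: float = DEFAULT_HORIZON_S,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Pair each alert output with its forward-horizon event label.

    Returns a DataFrame ``patient_id, t, category, label`` with one row per
    alert whose full horizon ``[t, t + horizon_s)`` lies within the
    monitoring interval; trailing outputs with truncated horizons are
    dropped and counted in the log.

    ``mode='overlap'`` labels true when any episode interval intersects the
    horizon (an ongoing episode counts); ``mode='onset'`` requires an
    episode *onset* inside the horizon.
    """
    if mode not in ("overlap", "onset"):
        raise ValueError(f"unknown labeling mode {mode!r}")
    a = patient.alerts
    t = a["t"].to_numpy(float)
    keep = t + horizon_s <= patient.monitor_end
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "patient %s: %d window(s) with truncated horizon dropped",
            patient.patient_id,
            n_drop,
        )
    t = t[keep]
    label = np.zeros(len(t), dtype=bool)
    for e in episodes:
        if mode == "overlap":
            label |= (e.onset < t + horizon_s) & (e.offset >= t)
        else:
            label |= (e.onset >= t) & (e.onset < t + horizon_s)
    return pd.DataFrame(
        {
            "patient_id": patient.patient_id,
            "t": t,
            "category": a["category"].to_numpy()[keep],
            "label": label,
        }
    )


def cohort_windows(
    cohort: Cohort,
    episodes_by_patient: dict,
    horizon_s: float = DEFAULT_HORIZON_S,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Concatenate labelled windows over a cohort (patients without alerts
    contribute nothing)."""
    frames = [
        label_windows(p, episodes_by_patient.get(p.patient_id, []), horizon_s, mode)
        for p in cohort
        if len(p.alerts)
    ]
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


class EvalWindows:
    """Thin namespace alias: a windows table is a plain DataFrame."""


def binarize(category: str, positive_set=DEFAULT_POSITIVE) -> bool:
    """True when the category counts as a positive prediction."""
    if category not in ALERT_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return category in positive_set


# ---------------------------------------------------------------------------
# contingency machinery
# ---------------------------------------------------------------------------


def category_label_table(windows: pd.DataFrame) -> np.ndarray:
    """3x2 contingency table: rows low/moderate/high, columns label F/T."""
    tab = np.zeros((3, 2), dtype=np.int64)
    cat = pd.Categorical(
        windows["category"], categories=ALERT_CATEGORIES, ordered=True
    ).codes
    lab = windows["label"].to_numpy(bool).astype(int)
    np.add.at(tab, (cat, lab), 1)
    return tab


def _confusion_from_table(
    table: np.ndarray, positive_set=DEFAULT_POSITIVE
) -> np.ndarray:
    """Collapse (..., 3, 2) tables to (..., 4) = tp, fp, tn, fn."""
    pos = np.array([c in positive_set for c in ALERT_CATEGORIES])
    pred_pos = table[..., pos, :].sum(axis=-2)
    pred_neg = table[..., ~pos, :].sum(axis=-2)
    tp, fp = pred_pos[..., 1], pred_pos[..., 0]
    fn, tn = pred_neg[..., 1], pred_neg[..., 0]
    return np.stack([tp, fp, tn, fn], axis=-1)


def confusion(
    windows: pd.DataFrame, positive_set=DEFAULT_POSITIVE
) -> ConfusionCounts:
    """Tally windows into tp/fp/tn/fn under the category grouping."""
    if not len(windows):
        raise ValueError("no evaluable windows")
    tp, fp, tn, fn = _confusion_from_table(category_label_table(windows), positive_set)
    return ConfusionCounts(int(tp), int(fp), int(tn), int(fn))


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out if out.shape else float(out)


def metrics(conf: ConfusionCounts) -> MetricSet:
    """Standard confusion-derived metric suite.

    ``fpr = 1 - specificity`` and ``fnr = 1 - sensitivity`` by construction;
    undefined ratios come back NaN with a warning.
    """
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    f1 = _safe_div(2 * ppv * sens, ppv + sens) if np.isfinite(ppv + sens) else float("nan")
    inc = _safe_div(tp + fn, conf.n)
    for name, v in (("sensitivity", sens), ("specificity", spec), ("ppv", ppv), ("npv", npv)):
        if not np.isfinite(v):
            logger.warning("metric %s undefined (zero denominator)", name)
    return MetricSet(
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        npv=float(npv),
        fpr=float(1 - spec),
        fnr=float(1 - sens),
        f1=float(f1),
        incidence=float(inc),
        n_windows=conf.n,
    )


# ---------------------------------------------------------------------------
# ordinal ROC / PR
# ---------------------------------------------------------------------------


def _auc_from_table(table: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC with ties counted 1/2, from (..., 3, 2) tables."""
    neg = table[..., 0].astype(float)  # (..., 3)
    pos = table[..., 1].astype(float)
    P = pos.sum(axis=-1)
    N = neg.sum(axis=-1)
    # pairs where the positive's score strictly exceeds the negative's
    gt = (
        pos[..., 1] * neg[..., 0]
        + pos[..., 2] * (neg[..., 0] + neg[..., 1])
    )
    ties = (pos * neg).sum(axis=-1)
    return _safe_div(gt + 0.5 * ties, P * N)


def ordinal_roc_auc(windows: pd.DataFrame) -> float:
    """AUC of the ordinal score low < moderate < high.

    Computed as the Mann-Whitney statistic over all positive-negative pairs
    with tied scores counted one half; NaN (with a warning) when only one
    label class is present.
    """
    auc = float(_auc_from_table(category_label_table(windows)))
    if not np.isfinite(auc):
        logger.warning("AUC undefined: single-class labels")
    return auc


def _auprc_from_table(table: np.ndarray) -> np.ndarray:
    """PR area from (..., 3, 2) tables, linear-in-recall interpolation.

    Operating points are the cumulative thresholds >=high, >=moderate,
    >=low (everything predicted positive); the curve is anchored at recall
    0 with the precision of the most stringent non-empty point.
    """
    table = np.asarray(table, dtype=float)
    neg = table[..., 0]
    pos = table[..., 1]
    P = pos.sum(axis=-1)
    # cumulative from the top score down: thresholds high, >=moderate, all
    tp = np.stack(
        [pos[..., 2], pos[..., 2] + pos[..., 1], P], axis=-1
    )
    pp = np.stack(
        [
            pos[..., 2] + neg[..., 2],
            pos[..., 2] + neg[..., 2] + pos[..., 1] + neg[..., 1],
            table.sum(axis=(-2, -1)),
        ],
        axis=-1,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(P[..., None] > 0, tp / P[..., None], np.nan)
        precision = np.where(pp > 0, tp / pp, np.nan)
    # anchor at recall 0 with the first defined precision
    first_prec = precision[..., 0]
    for k in (1, 2):
        first_prec = np.where(np.isnan(first_prec), precision[..., k], first_prec)
    r = np.concatenate([np.zeros_like(P[..., None]), recall], axis=-1)
    p = np.concatenate([first_prec[..., None], precision], axis=-1)
    # zero-width segments (duplicate recall) contribute nothing; NaN
    # precision at an empty threshold is replaced by the anchor value
    p = np.where(np.isnan(p), first_prec[..., None], p)
    area = np.trapezoid(p, r, axis=-1)
    return np.where(P > 0, area, np.nan)


def ordinal_pr_auprc(windows: pd.DataFrame) -> float:
    """Area under the three-point precision-recall polygon.

    Equals 1 for perfect separation and approaches the incidence when the
    score is uninformative; NaN (with a warning) without positive labels.
    """
    area = float(_auprc_from_table(category_label_table(windows)))
    if not np.isfinite(area):
        logger.warning("AUPRC undefined: no positive labels")
    return area


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

_TABLE_STATS = {
    "sensitivity": lambda c: _safe_div(c[..., 0], c[..., 0] + c[..., 3]),
    "specificity": lambda c: _safe_div(c[..., 2], c[..., 2] + c[..., 1]),
    "ppv": lambda c: _safe_div(c[..., 0], c[..., 0] + c[..., 1]),
    "npv": lambda c: _safe_div(c[..., 2], c[..., 2] + c[..., 3]),
    "fpr": lambda c: 1 - _safe_div(c[..., 2], c[..., 2] + c[..., 1]),
    "fnr": lambda c: 1 - _safe_div(c[..., 0], c[..., 0] + c[..., 3]),
    "incidence": lambda c: _safe_div(c[..., 0] + c[..., 3], c.sum(axis=-1)),
    "f1": lambda c: _safe_div(2 * c[..., 0], 2 * c[..., 0] + c[..., 1] + c[..., 3]),
}


def _patient_tables(windows: pd.DataFrame):
    ids = windows["patient_id"].to_numpy()
    order = np.argsort(ids, kind="stable")
    w = windows.iloc[order]
    uniq, starts = np.unique(w["patient_id"].to_numpy(), return_index=True)
    bounds = list(starts) + [len(w)]
    tables = np.stack(
        [
            category_label_table(w.iloc[bounds[i] : bounds[i + 1]])
            for i in range(len(uniq))
        ]
    )
    return uniq, tables


def _eval_statistic(statistic, tables: np.ndarray, positive_set) -> np.ndarray:
    """Evaluate a named or callable statistic on (..., 3, 2) pooled tables."""
    if callable(statistic):
        flat = tables.reshape(-1, 3, 2)
        return np.array([statistic(tab) for tab in flat]).reshape(tables.shape[:-2])
    if statistic == "auc":
        return _auc_from_table(tables)
    if statistic == "auprc":
        return _auprc_from_table(tables)
    if statistic in _TABLE_STATS:
        conf = _confusion_from_table(tables, positive_set)
        return _TABLE_STATS[statistic](conf)
    raise ValueError(f"unknown statistic {statistic!r}")


def bootstrap_ci(
    windows: pd.DataFrame,
    statistic,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    positive_set=DEFAULT_POSITIVE,
) -> tuple[float, float]:
    """Patient-level bootstrap percentile interval for a window statistic.

    Patients (not windows) are resampled with replacement ``n_boot`` times;
    each resample pools its patients' windows and recomputes the statistic.
    ``statistic`` is one of ``sensitivity, specificity, ppv, npv, fpr, fnr,
    incidence, f1, auc, auprc`` or a callable on a pooled 3x2 category-by-
    label table. Resamples where the statistic is undefined are dropped and
    counted. Deterministic given ``seed``.
    """
    if not len(windows):
        raise ValueError("no windows to bootstrap")
    _, tables = _patient_tables(windows)
    n_pat = len(tables)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pat, size=(n_boot, n_pat))
    pooled = tables[idx].sum(axis=1)  # (n_boot, 3, 2)
    stats = np.asarray(_eval_statistic(statistic, pooled, positive_set), dtype=float)
    ok = np.isfinite(stats)
    n_bad = int((~ok).sum())
    if n_bad == n_boot:
        raise ValueError("statistic undefined in every bootstrap resample")
    if n_bad:
        logger.warning("%d/%d bootstrap resamples undefined, dropped", n_bad, n_boot)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(stats[ok], [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def full_metrics(
    windows: pd.DataFrame,
    positive_set=DEFAULT_POSITIVE,
    n_boot: int = 0,
    seed: int = 0,
    level: float = 0.95,
    ci_metrics=("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr",
                "incidence", "f1", "auc", "auprc"),
) -> MetricSet:
    """Full window-level metric suite, optionally with bootstrap CIs.

    With ``n_boot > 0``, patient-level percentile intervals are attached for
    every name in ``ci_metrics`` (seeds derived per metric from ``seed`` so
    adding a metric does not perturb the others).
    """
    ms = metrics(confusion(windows, positive_set))
    ms.auc = ordinal_roc_auc(windows)
    ms.auprc = ordinal_pr_auprc(windows)
    if n_boot > 0:
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(ci_metrics))
        for name, child in zip(ci_metrics, children):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                ms.ci[name] = bootstrap_ci(
                    windows, name, n_boot=n_boot, seed=sub_seed,
                    level=level, positive_set=positive_set,
                )
            except ValueError:
                logger.warning("bootstrap CI for %s unavailable", name)
    return ms


# ---------------------------------------------------------------------------
# analytic reconstruction from published summaries
# ---------------------------------------------------------------------------


def metrics_from_summary(
    n_low: int,
    n_mod: int,
    n_high: int,
    incidence: float,
    sensitivity: float,
) -> MetricSet:
    """Reconstruct the full metric suite from printed summary numbers.

    Published reports often give per-category output counts plus incidence
    and sensitivity but omit the confusion table. Those five numbers
    determine it: with ``N`` total windows, ``positives = incidence * N``
    and ``tp = sensitivity * positives`` (both rounded to integers),
    ``fp = n_high - tp``, ``fn = positives - tp`` and
    ``tn = N - n_high - fn`` under the low+moderate vs high grouping.
    Derived metrics (PPV, NPV, specificity, F1, ...) follow exactly;
    inconsistent inputs (negative fp or tn) raise ``ValueError``.
    """
    if min(n_low, n_mod, n_high) <= 0:
        raise ValueError("category counts must be positive")
    if not (0 < incidence < 1 and 0 < sensitivity < 1):
        raise ValueError("incidence and sensitivity must be in (0, 1)")
    N = n_low + n_mod + n_high
    positives = int(np.floor(incidence * N + 0.5))
    tp = int(np.floor(sensitivity * positives + 0.5))
    fp = n_high - tp
    fn = positives - tp
    tn = N - n_high - fn
    if fp < 0 or tn < 0:
        raise ValueError("inconsistent summary: implied negative fp or tn")
    return metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
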