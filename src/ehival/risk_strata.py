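"""Category-conditional event risk and output-distribution tables.

Two complementary views of the raw three-level alert stream:

* :func:`category_risks` — for each category, the probability of an
  episode in the following hour among windows carrying that category, and
  the risk ratio versus the low-risk category. This is the analysis that
  justifies grouping low with moderate when binarising.
* :func:`category_output_table` — counts and percentages of outputs per
  (modality, category) over the whole cohort.

Risks are computed on exactly the window set the window-level evaluation
uses (same horizon, same truncation exclusions), so the window-weighted
mean of the category risks equals the overall incidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_streams import ALERT_CATEGORIES, Cohort

__all__ = [
    "CategoryRisk",
    "category_risks",
    "category_output_table",
    "output_percentages",
]


def output_percentages(counts: dict) -> dict:
    """Percentage share (0-100) of each category in a counts mapping."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no outputs")
    return {k: 100.0 * v / total for k, v in counts.items()}


@dataclass(frozen=True)
class CategoryRisk:
    category: str
    n_windows: int
    n_positive: int
    risk: float
    rr_vs_low: float | None


def category_risks(windows: pd.DataFrame) -> list[CategoryRisk]:
    """Per-category event risk in the forward horizon, with risk ratios.

    ``windows`` is a labelled window table with raw categories retained
    (from :func:`ehival.window_eval.cohort_windows`). Categories with no
    windows are omitted. ``rr_vs_low`` is ``risk / risk(low)``, defined
    only when the low-category risk is positive; the low category's own
    ratio is identically 1.
    """
    if not len(windows):
        raise ValueError("no windows")
    out = []
    risk_low = None
    grouped = {
        c: windows[windows["category"].astype(str) == c] for c in ALERT_CATEGORIES
    }
    low = grouped["low"]
    if len(low):
        risk_low = float(low["label"].mean())
    for c in ALERT_CATEGORIES:
        g = grouped[c]
        if not len(g):
            continue
        n = int(len(g))
        npos = int(g["label"].sum())
        risk = npos / n
        if risk_low is None or risk_low == 0.0:
            rr = None
        elif c == "low":
            rr = 1.0
        else:
            rr = risk / risk_low
        out.append(CategoryRisk(c, n, npos, risk, rr))
    return out


def category_output_table(cohort: Cohort) -> pd.DataFrame:
    """Counts and percentages of alert outputs per modality and category.

    Returns a DataFrame ``modality, category, n, pct`` where ``pct`` is the
    percentage of that modality's total outputs (0-100 scale).
    """
    rows = []
    for modality in ("NIBP", "IAP"):
        counts = {c: 0 for c in ALERT_CATEGORIES}
        for p in cohort:
            if p.modality.value != modality:
                continue
            vc = p.alerts["category"].value_counts()
            for c in ALERT_CATEGORIES:
                counts[c] += int(vc.get(c, 0))
        total = sum(counts.values())
        for c in ALERT_CATEGORIES:
            rows.append(
                {
                    "modality": modality,
                    "category": c,
                    "n": counts[c],
                    "pct": 100.0 * counts[c] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)
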