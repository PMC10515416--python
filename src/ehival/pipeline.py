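"""End-to-end orchestration: simulate -> annotate -> evaluate -> report.

Each stage is a pure function over files or in-memory objects; the bundle
written by :func:`run_pipeline` contains every table the analysis
produces, plus a manifest echoing the configuration, the root seed and the
exclusion counts so that table row counts reconcile exactly. All
randomness (simulator, bootstrap) flows from the single root seed through
per-stage derived seeds, so identical config gives a byte-identical
bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ehi_detection import EHICriteria, detect_cohort_episodes, first_episode
from .group_comparison import compare_groups
from .io_streams import Cohort, read_cohort, write_cohort, write_episodes
from .leadtime import cohort_lead_times, leadtime_stats
from .pre_event_prevalence import cohort_hourly_table, patient_high_fraction
from .risk_strata import category_output_table, category_risks
from .synthetic_cohort import CohortConfig, generate_cohort, truth_episodes
from .window_eval import DEFAULT_POSITIVE, cohort_windows, full_metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a root seed."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str | Path = "results"
    vitals_path: str | Path | None = None
    alerts_path: str | Path | None = None
    sim_config: CohortConfig | None = None
    criteria: EHICriteria = field(default_factory=EHICriteria)
    horizon_s: float = 3600.0
    mode: str = "overlap"
    positive_set: frozenset = DEFAULT_POSITIVE
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.vitals_path is not None and self.alerts_path is not None
        if not has_files and self.sim_config is None:
            raise ValueError("either input files or a simulator config is required")


def _metrics_row(name: str, value: float, ci: tuple | None) -> dict:
    row = {"measure": name, "value": value}
    if ci is not None:
        row["ci_low"], row["ci_high"] = ci
    return row


def _evaluate_modality(cohort_mod, episodes, cfg: RunConfig, seed: int):
    windows = cohort_windows(cohort_mod, episodes, cfg.horizon_s, cfg.mode)
    if not len(windows) or windows["label"].nunique() < 2:
        logger.warning("degenerate window set (single label class); metrics limited")
    ms = full_metrics(
        windows, cfg.positive_set, n_boot=cfg.n_boot, seed=seed
    ) if len(windows) else None
    return windows, ms


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- input stage -------------------------------------------------------
    truth = None
    if cfg.sim_config is not None:
        sim = cfg.sim_config.with_(seed=derive_seed(cfg.seed, "simulate"))
        cohort, truth = generate_cohort(sim)
        write_cohort(cohort, outdir / "vitals.csv", outdir / "alerts.csv")
        truth.table.to_csv(outdir / "truth.csv", index=False)
    else:
        cohort = read_cohort(cfg.vitals_path, cfg.alerts_path)

    # --- episode annotation ------------------------------------------------
    episodes = detect_cohort_episodes(cohort, cfg.criteria)
    flat = [e for eps in episodes.values() for e in eps]
    write_episodes(flat, outdir / "episodes.csv")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "horizon_s": cfg.horizon_s,
        "mode": cfg.mode,
        "positive_set": sorted(cfg.positive_set),
        "n_boot": cfg.n_boot,
        "criteria": asdict(cfg.criteria),
        "n_patients": len(cohort),
        "n_episodes": len(flat),
        "modalities": {},
    }
    if cfg.sim_config is not None:
        manifest["sim_config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg.sim_config).items()
        }

    # --- Table-2-style output distribution --------------------------------
    out_table = category_output_table(cohort)
    out_table.to_csv(outdir / "category_counts.csv", index=False)

    metrics_json: dict = {}
    risks_json: dict = {}
    boot_seed = derive_seed(cfg.seed, "bootstrap")
    for modality in ("NIBP", "IAP"):
        sub = Cohort(
            [p for p in cohort if p.modality.value == modality] or [],
            provenance=cohort.provenance,
        ) if any(p.modality.value == modality for p in cohort) else None
        if sub is None:
            continue
        windows, ms = _evaluate_modality(sub, episodes, cfg, boot_seed)
        n_alerts = sum(len(p.alerts) for p in sub)
        manifest["modalities"][modality] = {
            "n_patients": len(sub),
            "n_alert_outputs": n_alerts,
            "n_windows": int(len(windows)),
            "n_truncated_dropped": int(n_alerts - len(windows)),
            "n_episode_patients": sum(
                1 for p in sub if episodes.get(p.patient_id)
            ),
        }
        if ms is not None:
            metrics_json[modality] = ms.as_dict()
            rows = [
                _metrics_row(k, getattr(ms, k), ms.ci.get(k))
                for k in (
                    "incidence sensitivity specificity auc ppv npv "
                    "fpr fnr auprc f1".split()
                )
            ]
            pd.DataFrame(rows).to_csv(
                outdir / f"window_metrics_{modality}.csv", index=False
            )
            if len(windows):
                risks_json[modality] = [
                    asdict(r) for r in category_risks(windows)
                ]

        # --- lead time -----------------------------------------------------
        results = cohort_lead_times(sub, episodes)
        if results:
            pd.DataFrame([asdict(r) for r in results]).to_csv(
                outdir / f"leadtime_results_{modality}.csv", index=False
            )
            stats = leadtime_stats(results)
            with open(outdir / f"leadtime_summary_{modality}.json", "w") as fh:
                json.dump(stats, fh, indent=1)
            manifest["modalities"][modality]["n_leadtime_patients"] = stats[
                "n_patients"
            ]
        else:
            logger.info("%s: no eligible patients for lead-time analysis", modality)
            manifest["modalities"][modality]["n_leadtime_patients"] = 0

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics_json, fh, indent=1, allow_nan=True)
    with open(outdir / "risk_ratios.json", "w") as fh:
        json.dump(risks_json, fh, indent=1)

    # --- pre-event prevalence + group comparison ---------------------------
    prev = cohort_hourly_table(cohort, episodes)
    for modality, table in prev.items():
        table.to_csv(outdir / f"pre_event_prevalence_{modality}.csv", index=False)

    frac_rows = []
    for p in cohort:
        if not len(p.alerts):
            continue
        has_ehi = bool(episodes.get(p.patient_id))
        frac_rows.append(
            {
                "patient_id": p.patient_id,
                "modality": p.modality.value,
                "group": "EHI" if has_ehi else "no_EHI",
                "pct_high": patient_high_fraction(p),
            }
        )
    frac_df = pd.DataFrame(frac_rows)
    frac_df.to_csv(outdir / "patient_high_fractions.csv", index=False)

    comparisons = {}
    for modality in ("NIBP", "IAP"):
        sub = frac_df[frac_df["modality"] == modality] if len(frac_df) else frac_df
        if not len(sub):
            continue
        a = sub[sub["group"] == "EHI"]["pct_high"].to_numpy()
        b = sub[sub["group"] == "no_EHI"]["pct_high"].to_numpy()
        if len(a) and len(b):
            comparisons[modality] = asdict(compare_groups(a, b))
        else:
            logger.info("%s: one comparison group empty, test skipped", modality)
    with open(outdir / "group_comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)

    if truth is not None:
        write_episodes(truth_episodes(truth), outdir / "truth_episodes.csv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
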