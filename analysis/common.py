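"""Shared paths and the cohort configuration used across the analysis.

The simulated study cohort mirrors the structure of the clinical cohort
the pipeline is designed for: 85.5% of patients on intermittent cuff
monitoring (9.6% of them with an instability episode) and 14.5% on a
continuous arterial line (46.4% with an episode). Bulky per-sample CSVs
live under ``scratch/`` (regenerable, not part of the deliverable);
summary tables go to ``results/``.
"""

from pathlib import Path

from ehival.synthetic_cohort import CohortConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

STUDY_SEED = 20230922
STUDY_CONFIG = CohortConfig(n_patients=500, seed=STUDY_SEED)

VITALS = SCRATCH / "vitals.csv"
ALERTS = SCRATCH / "alerts.csv"
TRUTH = SCRATCH / "truth.csv"
EPISODES = RESULTS / "episodes.csv"


def load_cohort():
    """Read the simulated cohort, regenerating it if 01 has not run."""
    from ehival.io_streams import read_cohort
    from ehival.synthetic_cohort import generate_cohort

    if VITALS.exists() and ALERTS.exists():
        return read_cohort(VITALS, ALERTS)
    cohort, _ = generate_cohort(STUDY_CONFIG)
    return cohort
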