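"""Window labeling, metric suite, ordinal ROC/PR and patient bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehival.ehi_detection import EHIEpisode
from ehival.io_streams import _categorical
from ehival.window_eval import (
    ConfusionCounts,
    binarize,
    bootstrap_ci,
    confusion,
    full_metrics,
    label_windows,
    metrics,
    metrics_from_summary,
    ordinal_pr_auprc,
    ordinal_roc_auc,
)

from conftest import make_patient, random_windows

SCORE = {"low": 0, "moderate": 1, "high": 2}


def brute_force_auc(windows: pd.DataFrame) -> float:
    """O(n^2) pair counting over all positive-negative window pairs."""
    s = windows["category"].map(SCORE).to_numpy()
    y = windows["label"].to_numpy(bool)
    pos, neg = s[y], s[~y]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total


def brute_force_auprc(windows: pd.DataFrame) -> float:
    """Direct construction of the three-point PR polygon."""
    s = windows["category"].map(SCORE).to_numpy()
    y = windows["label"].to_numpy(bool)
    P = y.sum()
    pts = []
    for thresh in (2, 1, 0):
        pred = s >= thresh
        if pred.sum() == 0:
            continue
        pts.append((y[pred].sum() / P, y[pred].sum() / pred.sum()))
    pts = [(0.0, pts[0][1])] + pts
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def _alert_patient(t_alerts, categories, monitor_end=None):
    return make_patient(
        t_alerts=t_alerts, categories=categories, monitor_end=monitor_end
    )


class TestLabelWindows:
    def test_episode_inside_horizon_positive_both_modes(self):
        p = _alert_patient([0.0], ["high"], monitor_end=3600.0)
        ep = [EHIEpisode("P1", 1800, 2400, "NIBP_point")]
        for mode in ("overlap", "onset"):
            w = label_windows(p, ep, mode=mode)
            assert w["label"].tolist() == [True]

    def test_episode_outside_horizon_negative(self):
        p = _alert_patient([0.0], ["high"], monitor_end=9000.0)
        ep = [EHIEpisode("P1", 5000, 9000, "NIBP_point")]
        for mode in ("overlap", "onset"):
            assert label_windows(p, ep, mode=mode)["label"].tolist() == [False]

    def test_ongoing_episode_overlap_vs_onset(self):
        # episode began before this window: overlap counts it, onset does not
        p = _alert_patient([600.0], ["high"], monitor_end=4800.0)
        ep = [EHIEpisode("P1", 0, 1200, "IAP_sustained")]
        assert label_windows(p, ep, mode="overlap")["label"].tolist() == [True]
        assert label_windows(p, ep, mode="onset")["label"].tolist() == [False]

    def test_truncated_horizons_dropped(self):
        p = _alert_patient([0, 1200, 2400], ["low"] * 3, monitor_end=4000.0)
        w = label_windows(p, [])
        assert w["t"].tolist() == [0.0]  # only the first horizon fits

    def test_horizon_half_open(self):
        # onset exactly at t + horizon is outside the window
        p = _alert_patient([0.0], ["high"], monitor_end=10800.0)
        ep = [EHIEpisode("P1", 3600, 4000, "NIBP_point")]
        assert label_windows(p, ep, mode="onset")["label"].tolist() == [False]
        assert label_windows(p, ep, mode="overlap")["label"].tolist() == [False]

    def test_unknown_mode_rejected(self):
        p = _alert_patient([0.0], ["low"], monitor_end=4000.0)
        with pytest.raises(ValueError):
            label_windows(p, [], mode="both")


class TestBinarizeConfusion:
    def test_binarize_default_and_custom(self):
        assert binarize("high") is True
        assert binarize("moderate") is False
        assert binarize("low", positive_set={"moderate", "high"}) is False
        with pytest.raises(ValueError):
            binarize("red")

    def test_confusion_enumeration(self):
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": [0, 1, 2, 3],
                "category": _categorical(["high", "high", "low", "low"]),
                "label": [True, False, True, False],
            }
        )
        c = confusion(w)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_confusion_matches_brute_force_tally(self, rng):
        w = random_windows(rng, 200)
        c = confusion(w)
        pred = w["category"].astype(str) == "high"
        lab = w["label"]
        assert c.tp == int((pred & lab).sum())
        assert c.fp == int((pred & ~lab).sum())
        assert c.fn == int((~pred & lab).sum())
        assert c.tn == int((~pred & ~lab).sum())
        assert c.n == 200

    def test_empty_windows_error(self):
        with pytest.raises(ValueError):
            confusion(pd.DataFrame(columns=["patient_id", "t", "category", "label"]))


class TestMetrics:
    def test_symmetric_case(self):
        ms = metrics(ConfusionCounts(1, 1, 1, 1))
        assert ms.sensitivity == ms.specificity == ms.ppv == ms.npv == 0.5

    def test_arithmetic(self):
        ms = metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert ms.sensitivity == pytest.approx(0.9)
        assert ms.specificity == pytest.approx(0.8)
        assert ms.incidence == pytest.approx(0.5)

    def test_undefined_is_nan_not_zero(self):
        ms = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(ms.sensitivity) and np.isnan(ms.ppv)
        assert ms.specificity == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    def test_complement_identities(self, tp, fp, tn, fn):
        ms = metrics(ConfusionCounts(tp, fp, tn, fn))
        if np.isfinite(ms.specificity):
            assert ms.fpr + ms.specificity == pytest.approx(1.0)
        if np.isfinite(ms.sensitivity):
            assert ms.fnr + ms.sensitivity == pytest.approx(1.0)
        if np.isfinite(ms.f1) and ms.ppv + ms.sensitivity > 0:
            assert ms.f1 == pytest.approx(
                2 * ms.ppv * ms.sensitivity / (ms.ppv + ms.sensitivity)
            )


class TestOrdinalROC:
    def test_perfect_separation(self):
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": range(6),
                "category": _categorical(["high"] * 3 + ["low"] * 3),
                "label": [True] * 3 + [False] * 3,
            }
        )
        assert ordinal_roc_auc(w) == 1.0

    def test_identical_distributions_exactly_half(self):
        cats = ["low", "moderate", "high", "high"]
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": range(8),
                "category": _categorical(cats + cats),
                "label": [True] * 4 + [False] * 4,
            }
        )
        assert ordinal_roc_auc(w) == 0.5

    def test_single_class_is_nan(self):
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": [0],
                "category": _categorical(["high"]),
                "label": [True],
            }
        )
        assert np.isnan(ordinal_roc_auc(w))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_windows(rng, 30)
        if w["label"].nunique() < 2:
            pytest.skip("degenerate draw")
        assert ordinal_roc_auc(w) == pytest.approx(brute_force_auc(w))

    def test_matches_sklearn_on_ordinal_scores(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        w = random_windows(rng, 400)
        expected = sklearn_metrics.roc_auc_score(
            w["label"], w["category"].map(SCORE)
        )
        assert ordinal_roc_auc(w) == pytest.approx(expected)


class TestOrdinalPR:
    def test_perfect_separation(self):
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": range(6),
                "category": _categorical(["high"] * 3 + ["low"] * 3),
                "label": [True] * 3 + [False] * 3,
            }
        )
        assert ordinal_pr_auprc(w) == pytest.approx(1.0)

    def test_uninformative_score_equals_incidence(self):
        # identical score distribution in both classes, in closed form
        cats = ["low"] * 6 + ["moderate"] * 3 + ["high"] * 1
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": range(40),
                "category": _categorical(cats * 4),
                "label": [True] * 10 + [False] * 30,
            }
        )
        assert ordinal_pr_auprc(w) == pytest.approx(0.25)

    def test_no_positives_is_nan(self):
        w = pd.DataFrame(
            {
                "patient_id": "P",
                "t": [0, 1],
                "category": _categorical(["low", "high"]),
                "label": [False, False],
            }
        )
        assert np.isnan(ordinal_pr_auprc(w))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_geometry_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_windows(rng, 30)
        if w["label"].sum() == 0:
            pytest.skip("degenerate draw")
        assert ordinal_pr_auprc(w) == pytest.approx(brute_force_auprc(w))


class TestBootstrap:
    def test_single_patient_degenerate(self, rng):
        w = random_windows(rng, 50).assign(patient_id="only")
        lo, hi = bootstrap_ci(w, "sensitivity", n_boot=50, seed=1)
        point = metrics(confusion(w)).sensitivity
        assert lo == hi == pytest.approx(point)

    def test_seed_determinism(self, rng):
        w = random_windows(rng, 300)
        a = bootstrap_ci(w, "auc", n_boot=200, seed=7)
        b = bootstrap_ci(w, "auc", n_boot=200, seed=7)
        c = bootstrap_ci(w, "auc", n_boot=200, seed=8)
        assert a == b
        assert a != c

    def test_interval_contains_plausible_values(self, rng):
        w = random_windows(rng, 600, p_pos=0.5)
        lo, hi = bootstrap_ci(w, "incidence", n_boot=300, seed=3)
        assert lo <= w["label"].mean() <= hi

    def test_width_shrinks_with_more_patients(self):
        """Interval width decreases stochastically as the cohort grows."""
        def cohort_windows_of(n_pat, rng):
            frames = []
            for i in range(n_pat):
                n = 30
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": f"P{i}",
                            "t": np.arange(n) * 120.0,
                            "category": _categorical(
                                rng.choice(["low", "moderate", "high"], n)
                            ),
                            "label": rng.random(n) < 0.3,
                        }
                    )
                )
            return pd.concat(frames, ignore_index=True)

        rng = np.random.default_rng(99)
        small = cohort_windows_of(10, rng)
        big = cohort_windows_of(160, rng)
        w_small = np.diff(bootstrap_ci(small, "sensitivity", n_boot=400, seed=5))[0]
        w_big = np.diff(bootstrap_ci(big, "sensitivity", n_boot=400, seed=5))[0]
        assert w_big < w_small

    def test_callable_statistic(self, rng):
        w = random_windows(rng, 200)
        lo, hi = bootstrap_ci(
            w, lambda tab: tab.sum() and tab[:, 1].sum() / tab.sum(), n_boot=100, seed=2
        )
        assert 0 <= lo <= hi <= 1

    def test_full_metrics_attaches_cis(self, rng):
        w = random_windows(rng, 400)
        ms = full_metrics(w, n_boot=100, seed=11)
        for name in ("sensitivity", "auc", "f1"):
            lo, hi = ms.ci[name]
            assert lo <= hi


class TestMetricsFromSummary:
    def test_consistency_with_own_confusion(self):
        """Feeding back a metric set's implied counts reproduces it."""
        conf = ConfusionCounts(tp=900, fp=2100, tn=6700, fn=300)
        ms = metrics(conf)
        n_high = conf.tp + conf.fp
        n_rest = conf.tn + conf.fn
        back = metrics_from_summary(
            n_low=n_rest - 1000,
            n_mod=1000,
            n_high=n_high,
            incidence=ms.incidence,
            sensitivity=ms.sensitivity,
        )
        for f in ("sensitivity", "specificity", "ppv", "npv", "f1", "incidence"):
            assert getattr(back, f) == pytest.approx(getattr(ms, f))

    def test_perfect_classifier_identity(self):
        ms = metrics_from_summary(
            n_low=400, n_mod=100, n_high=500, incidence=0.5, sensitivity=0.999999
        )
        assert ms.ppv == pytest.approx(1.0, abs=1e-5)
        assert ms.fnr == pytest.approx(0.0, abs=1e-5)

    def test_inconsistent_summary_rejected(self):
        # implied true positives exceed the high-output count
        with pytest.raises(ValueError):
            metrics_from_summary(
                n_low=100, n_mod=100, n_high=10, incidence=0.5, sensitivity=0.9
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_summary(0, 1, 1, 0.5, 0.5)
        with pytest.raises(ValueError):
            metrics_from_summary(10, 10, 10, 1.5, 0.5)
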