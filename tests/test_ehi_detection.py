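"""Instability predicate and the two modality-specific episode rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehival.ehi_detection import (
    EHICriteria,
    detect_episodes_iap,
    detect_episodes_nibp,
    first_episode,
    instantaneous_unstable,
    qualifying_mask,
)

from conftest import make_patient


def brute_force_iap_episodes(t, ok, sustain_s=600.0, gap_tol_s=4.0):
    """Independent oracle: enumerate every maximal qualifying run directly.

    For each qualifying sample not continuing a run (previous sample
    non-qualifying or too far back), walk forward to the run's end, then
    keep the run iff its time span reaches the sustain requirement.
    """
    episodes = []
    i = 0
    n = len(t)
    while i < n:
        if not ok[i] or (i > 0 and ok[i - 1] and t[i] - t[i - 1] <= gap_tol_s):
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and t[j + 1] - t[j] <= gap_tol_s:
            j += 1
        if t[j] - t[i] >= sustain_s:
            episodes.append((t[i], t[j]))
        i = j + 1
    return episodes


class TestPredicate:
    @pytest.mark.parametrize(
        "hr,sbp,map_,expected",
        [
            (110, 85, 75, True),  # sbp clause
            (100, 95, 69, True),  # boundary hr inclusive, map clause
            (99.9, 80, 60, False),  # tachycardia fails
            (120, 95, 75, False),  # no hypotension
            (100, 90, 70, False),  # both pressure thresholds exclusive below
            (100, 89.999, 75, True),
        ],
    )
    def test_examples(self, hr, sbp, map_, expected):
        assert instantaneous_unstable(hr, sbp, map_) is expected

    def test_missing_channel_cannot_qualify_its_clause(self):
        assert instantaneous_unstable(110, np.nan, 60) is True
        assert instantaneous_unstable(110, np.nan, 75) is False

    def test_missing_hr_is_an_error(self):
        with pytest.raises(ValueError):
            instantaneous_unstable(np.nan, 80, 60)

    def test_exclusive_hr_variant(self):
        crit = EHICriteria(hr_inclusive=False)
        assert instantaneous_unstable(100, 80, 60, crit) is False
        assert instantaneous_unstable(100.1, 80, 60, crit) is True


def _iap_patient(t, hr, sbp):
    return make_patient(
        modality="IAP", t_vitals=t, hr=hr, sbp=sbp, map_=np.asarray(sbp) - 25.0
    )


class TestIAPDetector:
    def test_fifteen_minute_run_is_one_episode(self):
        t = np.arange(0, 902, 2.0)
        p = _iap_patient(t, np.full(len(t), 110.0), np.full(len(t), 80.0))
        eps = detect_episodes_iap(p)
        assert len(eps) == 1
        assert eps[0].onset == 0.0 and eps[0].offset == 900.0
        assert eps[0].rule == "IAP_sustained"

    def test_sub_threshold_span_rejected(self):
        t = np.arange(0, 600, 2.0)  # span 598 s < 600
        p = _iap_patient(t, np.full(len(t), 110.0), np.full(len(t), 80.0))
        assert detect_episodes_iap(p) == []

    def test_span_exactly_at_threshold_accepted(self):
        t = np.arange(0, 602, 2.0)  # span 600 s
        p = _iap_patient(t, np.full(len(t), 110.0), np.full(len(t), 80.0))
        assert len(detect_episodes_iap(p)) == 1

    def test_gap_breaks_run(self):
        # two 400 s qualifying stretches separated by a 10 s hole
        t = np.concatenate([np.arange(0, 402, 2.0), np.arange(412, 814, 2.0)])
        p = _iap_patient(t, np.full(len(t), 110.0), np.full(len(t), 80.0))
        assert detect_episodes_iap(p) == []

    def test_missing_hr_breaks_run(self):
        t = np.arange(0, 1202, 2.0)
        hr = np.full(len(t), 110.0)
        hr[len(t) // 2] = np.nan  # one dropped beat annotation mid-run
        p = _iap_patient(t, hr, np.full(len(t), 80.0))
        eps = detect_episodes_iap(p)
        # the two halves each span < 600 s
        assert eps == []

    def test_empty_vitals_empty_result(self):
        p = make_patient(modality="IAP")
        assert detect_episodes_iap(p) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        gaps = rng.choice([2.0, 2.0, 2.0, 6.0, 30.0], n)
        t = np.cumsum(gaps)
        qual = rng.random(n) < 0.7
        hr = np.where(qual, 110.0, 80.0)
        sbp = np.where(qual, 80.0, 120.0)
        p = _iap_patient(t, hr, sbp)
        got = [(e.onset, e.offset) for e in detect_episodes_iap(p)]
        ok = qualifying_mask(p, EHICriteria())
        assert got == brute_force_iap_episodes(t, ok)

    def test_episodes_time_ordered_and_disjoint(self):
        # two sustained stretches separated by a gap, plus a short third
        t = np.concatenate(
            [np.arange(0, 702, 2.0), np.arange(1000, 1702, 2.0), np.arange(2000, 2100, 2.0)]
        )
        p = _iap_patient(t, np.full(len(t), 110.0), np.full(len(t), 80.0))
        eps = detect_episodes_iap(p)
        assert [(e.onset, e.offset) for e in eps] == [(0.0, 700.0), (1000.0, 1700.0)]
        for a, b in zip(eps, eps[1:]):
            assert a.offset < b.onset


class TestNIBPDetector:
    def test_single_qualifying_measurement_point_episode(self):
        p = make_patient(
            t_vitals=[3600, 7200, 10800],
            hr=[80, 110, 85],
            sbp=[120, 80, 115],
        )
        eps = detect_episodes_nibp(p)
        assert len(eps) == 1
        assert eps[0].onset == eps[0].offset == 7200.0
        assert eps[0].rule == "NIBP_point"

    def test_adjacent_qualifying_measurements_merge(self):
        p = make_patient(t_vitals=[3600, 7200], hr=[110, 105], sbp=[80, 85])
        eps = detect_episodes_nibp(p)
        assert len(eps) == 1
        assert (eps[0].onset, eps[0].offset) == (3600.0, 7200.0)

    def test_non_qualifying_between_splits_episodes(self):
        p = make_patient(
            t_vitals=[3600, 7200, 10800],
            hr=[110, 80, 105],
            sbp=[80, 120, 85],
        )
        eps = detect_episodes_nibp(p)
        assert [(e.onset, e.offset) for e in eps] == [(3600, 3600), (10800, 10800)]

    def test_no_qualifying_measurements(self):
        p = make_patient(t_vitals=[0, 3600], hr=[80, 90], sbp=[120, 130])
        assert detect_episodes_nibp(p) == []

    def test_modality_dispatch_guard(self):
        p = make_patient(modality="IAP", t_vitals=[0], hr=[80], sbp=[120])
        with pytest.raises(ValueError):
            detect_episodes_nibp(p)


class TestFirstEpisode:
    def test_returns_earliest(self):
        from ehival.ehi_detection import EHIEpisode

        eps = [EHIEpisode("P", 90, 100, "NIBP_point"), EHIEpisode("P", 500, 600, "NIBP_point")]
        assert first_episode(eps).onset == 90

    def test_unsorted_rejected(self):
        from ehival.ehi_detection import EHIEpisode

        eps = [EHIEpisode("P", 500, 600, "NIBP_point"), EHIEpisode("P", 90, 100, "NIBP_point")]
        with pytest.raises(ValueError):
            first_episode(eps)

    def test_empty_gives_none(self):
        assert first_episode([]) is None


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    hr_relax=st.floats(0, 20),
    sbp_relax=st.floats(0, 20),
    seed=st.integers(0, 10_000),
)
def test_relaxing_thresholds_monotone_in_qualifying_time(hr_relax, sbp_relax, seed):
    """Lowering the tachycardia bar / raising the hypotension bar can only
    add qualifying samples."""
    rng = np.random.default_rng(seed)
    n = 300
    t = np.cumsum(rng.choice([2.0, 4.0], n))
    p = _iap_patient(
        t, rng.uniform(85, 115, n), rng.uniform(75, 105, n)
    )
    strict = EHICriteria()
    relaxed = EHICriteria(
        hr_threshold=100 - hr_relax, sbp_threshold=90 + sbp_relax
    )
    assert qualifying_mask(p, relaxed).sum() >= qualifying_mask(p, strict).sum()
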