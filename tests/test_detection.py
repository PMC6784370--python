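"""Bipolar pulse detector: extrema refinement, validation, end-to-end scans."""

import numpy as np
import pytest

from gmrcyto import (
    DetectorConfig,
    Trace,
    TransitEvent,
    detect_events,
    field_to_voltage,
    make_object,
    simulate_trace,
)
from gmrcyto.detection import Candidate, refine_extrema, validate_candidate

FS = 200_000.0


def bipolar_pulse(n=4000, center=2000, half_width=60, amp=1.0):
    """Odd two-lobed test pulse: negative lobe first (k = -1 orientation)."""
    t = np.arange(n) - center
    return -amp * (t / half_width) * np.exp(0.5 - 0.5 * (t / half_width) ** 2)


@pytest.fixture
def cfg():
    return DetectorConfig(v_threshold=0.3, direction_k=-1)


class TestRefineExtrema:
    def test_finds_true_lobe_peaks(self, cfg):
        samples = bipolar_pulse()
        seed = 2000 + 60  # inside the positive lobe
        cand = refine_extrema(samples, seed, cfg, FS)
        assert cand.terminated
        assert cand.i_max == int(np.argmax(samples))
        assert cand.i_min == int(np.argmin(samples))

    def test_monotone_ramp_unterminated(self, cfg):
        samples = np.linspace(0.0, 2.0, 3000)
        cand = refine_extrema(samples, 1500, cfg, FS)
        assert not cand.terminated

    def test_idempotent_across_seed_points(self, cfg):
        samples = bipolar_pulse()
        a = refine_extrema(samples, 2040, cfg, FS)
        b = refine_extrema(samples, 2075, cfg, FS)
        assert (a.i_min, a.i_max) == (b.i_min, b.i_max)


class TestValidateCandidate:
    def test_weak_negative_lobe_fails_bipolarity(self, cfg):
        # Vthr = 0.3: the floor is 0.1 and |Vmin| = 0.05 misses it
        cand = Candidate(i_min=150, i_max=100, v_min=-0.05, v_max=0.5, terminated=True)
        ev = validate_candidate(cand, cfg, FS)
        assert not ev.accepted and ev.rejection_reason == "bipolarity"

    def test_asymmetric_lobes_fail_symmetry(self, cfg):
        # |1.0 - 0.4| / |1.0 + 0.4| = 0.6/1.4 ~ 0.43 > 0.4 (k=-1 wants i_max > i_min)
        cand = Candidate(i_min=100, i_max=150, v_min=-0.4, v_max=1.0, terminated=True)
        ev = validate_candidate(cand, cfg, FS)
        assert not ev.accepted and ev.rejection_reason == "symmetry"
        assert ev.symmetry == pytest.approx(0.6 / 1.4, rel=1e-12)

    def test_wrong_orientation_rejected(self):
        cfg = DetectorConfig(v_threshold=0.3, direction_k=1)
        cand = Candidate(i_min=100, i_max=150, v_min=-0.9, v_max=1.0, terminated=True)
        ev = validate_candidate(cand, cfg, FS)
        assert not ev.accepted and ev.rejection_reason == "orientation"

    def test_too_narrow_width_rejected(self, cfg):
        # 3 samples at 200 kHz = 15 us < 25 us
        cand = Candidate(i_min=100, i_max=103, v_min=-0.9, v_max=1.0, terminated=True)
        ev = validate_candidate(cand, cfg, FS)
        assert not ev.accepted and ev.rejection_reason == "width"

    def test_hand_checked_acceptance(self):
        # k=+1 wants i_max < i_min; 50 samples = 250 us within the window
        cfg = DetectorConfig(v_threshold=0.3, direction_k=1)
        cand = Candidate(i_min=150, i_max=100, v_min=-0.9, v_max=1.0, terminated=True)
        ev = validate_candidate(cand, cfg, FS)
        assert ev.accepted and ev.rejection_reason is None
        assert ev.width == pytest.approx(250e-6)

    def test_unterminated_search_reason(self, cfg):
        cand = Candidate(i_min=0, i_max=10, v_min=-0.9, v_max=1.0, terminated=False)
        assert validate_candidate(cand, cfg, FS).rejection_reason == "unterminated_search"


def _trace_with_cells(acq, sensor, channel, bead, n_cells=5, n_beads=60, h=8e-6):
    rng = np.random.default_rng(11)
    events = [
        TransitEvent(make_object("aggregate", n_beads, rng, bead), 0.004 * (i + 1), h, 0.0)
        for i in range(n_cells)
    ]
    duration = 0.004 * (n_cells + 1)
    return simulate_trace(events, duration, acq, sensor, channel, noise_on=False), events


class TestDetectEvents:
    def test_all_zero_trace_empty(self, acq, cfg):
        tr = Trace(np.zeros(10_000), FS, acq)
        assert detect_events(tr, cfg) == []

    def test_five_transits_give_five_events(self, acq, sensor, channel, bead, vthr):
        tr, events = _trace_with_cells(acq, sensor, channel, bead)
        cfg = DetectorConfig(v_threshold=vthr, direction_k=-1)
        accepted = [e for e in detect_events(tr, cfg) if e.accepted]
        assert len(accepted) == len(events)
        # each accepted event sits at its ground-truth transit (no splits/merges)
        for ev, truth in zip(accepted, events):
            i_cross = truth.t_arrival * acq.sample_rate
            assert ev.lo < i_cross < ev.hi

    def test_threshold_above_peak_gives_nothing(self, acq, sensor, channel, bead):
        tr, _ = _trace_with_cells(acq, sensor, channel, bead)
        cfg = DetectorConfig(v_threshold=1.5 * float(np.abs(tr.samples).max()), direction_k=-1)
        assert detect_events(tr, cfg) == []

    def test_threshold_monotonicity(self, acq, sensor, channel, bead, vthr):
        tr, _ = _trace_with_cells(acq, sensor, channel, bead)
        counts = []
        for f in (0.5, 1.0, 1.5, 2.0):
            cfg = DetectorConfig(v_threshold=f * vthr, direction_k=-1)
            counts.append(sum(e.accepted for e in detect_events(tr, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_time_reversal_k_flip_invariance(self, acq, sensor, channel, bead, vthr):
        tr, _ = _trace_with_cells(acq, sensor, channel, bead)
        fwd = sum(e.accepted for e in detect_events(tr, DetectorConfig(v_threshold=vthr, direction_k=-1)))
        rev_trace = Trace(tr.samples[::-1].copy(), tr.sample_rate, acq)
        rev = sum(e.accepted for e in detect_events(rev_trace, DetectorConfig(v_threshold=vthr, direction_k=1)))
        assert fwd == rev

    def test_deterministic(self, acq, sensor, channel, bead, vthr):
        tr, _ = _trace_with_cells(acq, sensor, channel, bead)
        cfg = DetectorConfig(v_threshold=vthr, direction_k=-1)
        a = detect_events(tr, cfg)
        b = detect_events(tr, cfg)
        assert [(e.i_min, e.i_max, e.accepted) for e in a] == [
            (e.i_min, e.i_max, e.accepted) for e in b
        ]

    def test_telegraph_step_rejected(self, acq, sensor, channel, vthr):
        # square two-state noise produces monopolar excursions the validator drops
        rng = np.random.default_rng(21)
        tr = simulate_trace([], 0.02, acq, sensor, channel, rng=rng,
                            noise_on=False, rtn=(200.0, 4e-6))
        cfg = DetectorConfig(v_threshold=vthr, direction_k=-1)
        assert not any(e.accepted for e in detect_events(tr, cfg))
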