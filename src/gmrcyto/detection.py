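"""Bipolar peak identification and validation.

A magnetized object crossing the sensor produces a two-lobed (bipolar)
voltage pulse because the sensor-averaged in-plane field changes sign at
the centerline.  The detector scans every sample exceeding the voltage
threshold, localizes the surrounding extrema by growing a window until both
extrema sit safely away from its edges, and validates each candidate with
four ordered checks:

1. bipolarity — both lobes exceed a fraction (default 1/3) of the threshold,
   with opposite signs;
2. orientation — the lobe order matches the user-declared flow direction k,
   i.e. k (i_max - i_min) < 0;
3. width — the lobe separation is coherent with the flow speed
   (25 μs .. 2.5 ms by default);
4. symmetry — |V_max + V_min| / |V_max - V_min| < 0.4, which discriminates
   genuine transits from random-telegraph-noise steps.

Overlapping detections seeded from different samples of the same pulse are
merged, keeping the candidate with the larger peak-to-peak swing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tracesim import Trace, voltage_to_field

__all__ = [
    "DetectorConfig",
    "DetectedEvent",
    "Candidate",
    "refine_extrema",
    "validate_candidate",
    "detect_events",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and window parameters of the pulse validator."""

    v_threshold: float
    direction_k: int = 1
    width_min: float = 25e-6  # s
    width_max: float = 2.5e-3  # s
    bipolar_fraction: float = 1.0 / 3.0
    symmetry_max: float = 0.4
    grow_step: int = 15  # samples added per side per iteration
    edge_margin: int = 20  # extrema must sit at least this far from window edges

    def __post_init__(self) -> None:
        if not self.v_threshold > 0:
            raise ValueError("v_threshold must be positive")
        if self.direction_k not in (1, -1):
            raise ValueError("direction_k must be +1 or -1")
        if not self.width_min < self.width_max:
            raise ValueError("width_min must be below width_max")
        if not 0.0 < self.bipolar_fraction < 1.0:
            raise ValueError("bipolar_fraction must lie in (0, 1)")
        if not self.symmetry_max > 0:
            raise ValueError("symmetry_max must be positive")
        if self.grow_step < 1 or self.edge_margin < 1:
            raise ValueError("grow_step and edge_margin must be >= 1")


@dataclass
class Candidate:
    """Raw extrema pair returned by the window-growing search."""

    i_min: int
    i_max: int
    v_min: float
    v_max: float
    terminated: bool  # False when the window cap or trace edge was hit


@dataclass
class DetectedEvent:
    """A validated (or rejected) candidate pulse."""

    i_min: int
    i_max: int
    v_min: float
    v_max: float
    width: float  # s
    symmetry: float
    amplitude_field: float  # tesla
    accepted: bool
    rejection_reason: Optional[str] = None  # 'bipolarity' | 'orientation' | 'width'
    #                                         | 'symmetry' | 'unterminated_search'

    @property
    def lo(self) -> int:
        return min(self.i_min, self.i_max)

    @property
    def hi(self) -> int:
        return max(self.i_min, self.i_max)


def refine_extrema(samples: np.ndarray, seed_index: int, cfg: DetectorConfig,
                   sample_rate: float) -> Candidate:
    """Localize the extrema around a super-threshold sample.

    Starting from seed +/- edge_margin, the window grows by ``grow_step``
    samples per side until both the argmax and the argmin lie at least
    ``edge_margin`` samples from both window edges.  The search fails
    (``terminated=False``) when the window would exceed 4 x width_max or is
    pinned against the trace boundaries without satisfying the margin.
    """
    n = len(samples)
    if not 0 <= seed_index < n:
        raise IndexError("seed index outside trace")
    cap = int(4.0 * cfg.width_max * sample_rate)
    lo = max(0, seed_index - cfg.edge_margin)
    hi = min(n - 1, seed_index + cfg.edge_margin)
    while True:
        window = samples[lo:hi + 1]
        i_max = lo + int(np.argmax(window))
        i_min = lo + int(np.argmin(window))
        ok = (
            i_max - lo >= cfg.edge_margin
            and hi - i_max >= cfg.edge_margin
            and i_min - lo >= cfg.edge_margin
            and hi - i_min >= cfg.edge_margin
        )
        if ok:
            return Candidate(i_min, i_max, float(samples[i_min]), float(samples[i_max]), True)
        if hi - lo + 1 >= cap or (lo == 0 and hi == n - 1):
            return Candidate(i_min, i_max, float(samples[i_min]), float(samples[i_max]), False)
        lo = max(0, lo - cfg.grow_step)
        hi = min(n - 1, hi + cfg.grow_step)


def validate_candidate(cand: Candidate, cfg: DetectorConfig, sample_rate: float,
                       volts_per_tesla: float = 1.0) -> DetectedEvent:
    """Apply the four ordered acceptance criteria to a candidate.

    The first failed check is recorded as the rejection reason; a candidate
    whose extrema search did not terminate is rejected outright.
    """
    width = abs(cand.i_max - cand.i_min) / sample_rate
    swing = abs(cand.v_max - cand.v_min)
    symmetry = abs(cand.v_max + cand.v_min) / swing if swing > 0 else np.inf
    amplitude_v = max(abs(cand.v_max), abs(cand.v_min))
    event = DetectedEvent(
        i_min=cand.i_min,
        i_max=cand.i_max,
        v_min=cand.v_min,
        v_max=cand.v_max,
        width=width,
        symmetry=symmetry,
        amplitude_field=amplitude_v / volts_per_tesla,
        accepted=False,
    )
    if not cand.terminated:
        event.rejection_reason = "unterminated_search"
        return event
    floor = cfg.bipolar_fraction * cfg.v_threshold
    if not (cand.v_max > 0.0 > cand.v_min and abs(cand.v_min) > floor and abs(cand.v_max) > floor):
        event.rejection_reason = "bipolarity"
        return event
    if not cfg.direction_k * (cand.i_max - cand.i_min) < 0:
        event.rejection_reason = "orientation"
        return event
    if not cfg.width_min <= width <= cfg.width_max:
        event.rejection_reason = "width"
        return event
    if not symmetry < cfg.symmetry_max:
        event.rejection_reason = "symmetry"
        return event
    event.accepted = True
    return event


def detect_events(trace: Trace, cfg: DetectorConfig) -> list[DetectedEvent]:
    """Scan a trace and return deduplicated validated events, sorted by index.

    Every sample with |V| above threshold seeds an extrema search; identical
    or >= 50%-overlapping candidate intervals merge, keeping the larger
    peak-to-peak swing.  ``amplitude_field`` converts the larger lobe back
    to tesla through the trace's acquisition chain.
    """
    samples = trace.samples
    acq = trace.acquisition
    volts_per_tesla = float(
        acq.bias_voltage * acq.sensitivity_per_tesla * acq.total_gain
    )
    seeds = np.flatnonzero(np.abs(samples) > cfg.v_threshold)
    events: list[DetectedEvent] = []
    seen: set[tuple[int, int]] = set()
    for s in seeds:
        cand = refine_extrema(samples, int(s), cfg, trace.sample_rate)
        key = (cand.i_min, cand.i_max)
        if key in seen:
            continue
        seen.add(key)
        events.append(validate_candidate(cand, cfg, trace.sample_rate, volts_per_tesla))

    events.sort(key=lambda e: (e.lo, e.hi))
    merged: list[DetectedEvent] = []
    for ev in events:
        if merged:
            prev = merged[-1]
            overlap = min(prev.hi, ev.hi) - max(prev.lo, ev.lo) + 1
            shorter = min(prev.hi - prev.lo, ev.hi - ev.lo) + 1
            if overlap >= 0.5 * shorter:
                if abs(ev.v_max - ev.v_min) > abs(prev.v_max - prev.v_min):
                    merged[-1] = ev
                continue
        merged.append(ev)
    return merged
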