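"""Synthetic sample generation for the in-flow magnetic cell counter.

Three kinds of magnetic objects transit the microfluidic channel: free
beads, bead aggregates (the dominant source of non-specific counts) and
antibody-labeled cells.  Their size statistics are anchored to measured
suspension characteristics:

* aggregates — a zero-truncated geometric law calibrated so that 93% of
  objects carry fewer than 7 beads (the second anchor, 99% below 15,
  follows to within a percent);
* beads per cell — a negative binomial with mean 50 beads calibrated so
  that 98% of cells carry more than 7 beads.

Arrivals of each object class are Poisson with rate concentration x
volumetric flow; transit heights are uniform over the open channel
cross-section above the separation layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .magnetics import BeadMagnetics

__all__ = [
    "MagneticObject",
    "SampleComposition",
    "ChannelGeometry",
    "TransitEvent",
    "SizeDistribution",
    "aggregate_size_distribution",
    "beads_per_cell_distribution",
    "tilt_angle_max",
    "make_object",
    "generate_sample",
]


@dataclass
class MagneticObject:
    """A bead, bead aggregate, or bead-decorated cell.

    Aggregates are modeled as ``n_beads`` co-located vertical dipoles (the
    spatial extent of an aggregate has negligible influence on its signal);
    cells as spheres with beads placed uniformly at random on the surface,
    each bead's moment tilted from vertical.
    """

    kind: str
    n_beads: int
    bead_offsets: np.ndarray  # (n, 3) offsets from object center, m
    bead_thetas: np.ndarray  # (n,) polar tilt of each bead moment, rad
    bead_psis: np.ndarray  # (n,) azimuth of each bead moment, rad
    bead_moments: np.ndarray  # (n,) moment magnitude per bead, A·m²
    cell_diameter: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("bead", "aggregate", "cell"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        if self.n_beads < 1:
            raise ValueError("a magnetic object must carry at least one bead")
        self.bead_offsets = np.asarray(self.bead_offsets, dtype=float).reshape(self.n_beads, 3)
        self.bead_thetas = np.asarray(self.bead_thetas, dtype=float).reshape(self.n_beads)
        self.bead_psis = np.asarray(self.bead_psis, dtype=float).reshape(self.n_beads)
        self.bead_moments = np.asarray(self.bead_moments, dtype=float).reshape(self.n_beads)

    @property
    def radius(self) -> float:
        return self.cell_diameter / 2.0 if self.kind == "cell" else 0.0


@dataclass(frozen=True)
class ChannelGeometry:
    """PDMS flow channel above the sensor.

    Defaults: 25 μm high, 100 μm wide channel on a 6 μm separation layer,
    1 mL flowed in 30 min.  Objects transit at heights (above the sensor
    plane) within [spacer_thickness, spacer_thickness + height].
    """

    height: float = 25e-6
    width: float = 100e-6
    spacer_thickness: float = 6e-6
    flow_volume_rate: float = 1.0 / 30.0  # mL/min

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.width > 0 and self.flow_volume_rate > 0):
            raise ValueError("channel dimensions and flow rate must be positive")
        if self.spacer_thickness < 0:
            raise ValueError("spacer thickness must be non-negative")

    @property
    def flow_mL_per_s(self) -> float:
        return self.flow_volume_rate / 60.0

    @property
    def mean_speed(self) -> float:
        """Mean transit speed, m/s (plug flow: volume rate / cross-section)."""
        q_m3_s = self.flow_mL_per_s * 1e-6
        return q_m3_s / (self.height * self.width)


class SizeDistribution:
    """Discrete probability table over object sizes (number of beads)."""

    def __init__(self, n: np.ndarray, pmf: np.ndarray):
        n = np.asarray(n, dtype=int)
        pmf = np.asarray(pmf, dtype=float)
        if n.shape != pmf.shape or n.ndim != 1:
            raise ValueError("n and pmf must be 1-D arrays of equal length")
        if np.any(pmf < 0):
            raise ValueError("probabilities must be non-negative")
        total = pmf.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probability table sums to {total}, not 1")
        self.n = n
        self.pmf = pmf / total
        self.cdf = np.cumsum(self.pmf)

    @property
    def mean(self) -> float:
        return float(np.sum(self.n * self.pmf))

    def prob_less_than(self, k: int) -> float:
        return float(self.pmf[self.n < k].sum())

    def prob_greater_than(self, k: int) -> float:
        return float(self.pmf[self.n > k].sum())

    def quantile(self, q: float) -> int:
        return int(self.n[np.searchsorted(self.cdf, q)])

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.n, size=size, p=self.pmf)


def aggregate_size_distribution(
    p: Optional[float] = None,
    calibrate_below7: float = 0.93,
    n_max: int = 400,
) -> SizeDistribution:
    """Zero-truncated geometric law for beads per aggregate.

    With success probability ``p``, P(n) = p (1-p)^(n-1) for n >= 1.  When
    ``p`` is None it is calibrated so that P(n < 7) equals
    ``calibrate_below7`` (solving (1-p)^6 = 1 - 0.93 gives p ≈ 0.358); the
    second suspension anchor, 99% of objects below 15 beads, then holds to
    within 0.01 automatically.
    """
    if p is None:
        if not 0.0 < calibrate_below7 < 1.0:
            raise ValueError("calibration target must lie in (0, 1)")
        p = 1.0 - (1.0 - calibrate_below7) ** (1.0 / 6.0)
    if not 0.0 < p < 1.0:
        raise ValueError("geometric parameter p must lie in (0, 1)")
    n = np.arange(1, n_max + 1)
    pmf = stats.geom.pmf(n, p)  # geom already starts at 1
    tail = 1.0 - pmf.sum()
    if tail > 1e-9:
        raise ValueError(f"truncation at n_max={n_max} drops probability {tail:.2e}")
    return SizeDistribution(n, pmf / pmf.sum())


def beads_per_cell_distribution(
    mean: float = 50.0,
    dispersion: Optional[float] = None,
    calibrate_above7: float = 0.98,
    n_max: int = 2000,
) -> SizeDistribution:
    """Negative-binomial law for the number of beads labeling one cell.

    ``dispersion`` is the negative-binomial size parameter r (variance =
    mean + mean²/r; r → ∞ recovers Poisson).  When None, r is calibrated so
    that P(n > 7) equals ``calibrate_above7`` at the given mean.
    """
    if not mean > 0:
        raise ValueError("mean must be positive")
    if dispersion is None:
        target = 1.0 - calibrate_above7  # P(n <= 7)

        def gap(log_r: float) -> float:
            r = np.exp(log_r)
            return stats.nbinom.cdf(7, r, r / (r + mean)) - target

        lo, hi = np.log(1e-3), np.log(1e3)
        if gap(lo) * gap(hi) > 0:
            raise ValueError(
                f"cannot calibrate dispersion: P(n<=7) target {target} unreachable at mean {mean}"
            )
        dispersion = float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-12)))
    if not dispersion > 0:
        raise ValueError("dispersion must be positive")
    n = np.arange(0, n_max + 1)
    pmf = stats.nbinom.pmf(n, dispersion, dispersion / (dispersion + mean))
    tail = 1.0 - pmf.sum()
    if tail > 1e-9:
        raise ValueError(f"truncation at n_max={n_max} drops probability {tail:.2e}")
    return SizeDistribution(n, pmf / pmf.sum())


def tilt_angle_max(bead: BeadMagnetics) -> float:
    """Largest tilt of a cell-bound bead moment from vertical.

    Per-bead tilts are drawn uniformly in [0, theta_max] with theta_max
    chosen so the ensemble vertical magnetization matches the measured
    operating moment: E[cos theta] = sin(theta_max)/theta_max =
    moment_operating / moment_saturation.
    """
    target = bead.moment_operating / bead.moment_saturation
    if target >= 1.0:
        return 0.0
    f = lambda t: np.sin(t) / t - target
    return float(optimize.brentq(f, 1e-9, np.pi - 1e-9, xtol=1e-12))


@dataclass(frozen=True)
class SampleComposition:
    """What is in one milliliter of sample.

    ``bead_concentration`` counts individual beads; free (unbound) beads
    cluster into aggregates whose sizes follow ``aggregate_dist``, so the
    aggregate-object concentration is the free-bead concentration divided
    by the mean aggregate size.
    """

    label: str = "sample"
    cell_concentration: float = 0.0  # labeled-cell candidates per mL
    bead_concentration: float = 2e7  # beads per mL
    fraction_beads_bound: float = 0.0
    cell_diameter: float = 6e-6
    nominal_class: str = "negative"  # 'positive' | 'negative'

    def __post_init__(self) -> None:
        if self.cell_concentration < 0 or self.bead_concentration < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.fraction_beads_bound <= 1.0:
            raise ValueError("fraction_beads_bound must lie in [0, 1]")
        if self.nominal_class not in ("positive", "negative"):
            raise ValueError("nominal_class must be 'positive' or 'negative'")


@dataclass
class TransitEvent:
    """One object arriving at the sensor."""

    obj: MagneticObject
    t_arrival: float  # s, instant the object center crosses the sensor centerline
    height: float  # m, object-center height above the sensor plane
    x_offset: float  # m, position along the sensor long axis


def make_object(
    kind: str,
    n_beads: int,
    rng: np.random.Generator,
    bead: BeadMagnetics = BeadMagnetics(),
    cell_diameter: float = 6e-6,
) -> MagneticObject:
    """Construct a magnetic object of a given kind and size.

    Aggregates (and single beads): co-located vertical dipoles at the
    operating moment.  Cells: beads uniform on the sphere surface, each
    moment at the saturation magnitude tilted by a random theta uniform in
    [0, theta_max] (see :func:`tilt_angle_max`) with uniform azimuth.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if kind in ("bead", "aggregate"):
        zeros = np.zeros(n_beads)
        return MagneticObject(
            kind=kind,
            n_beads=n_beads,
            bead_offsets=np.zeros((n_beads, 3)),
            bead_thetas=zeros,
            bead_psis=zeros,
            bead_moments=np.full(n_beads, bead.moment_operating),
        )
    if kind == "cell":
        r = cell_diameter / 2.0
        # uniform points on the sphere
        u = rng.normal(size=(n_beads, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        thetas = rng.uniform(0.0, tilt_angle_max(bead), size=n_beads)
        psis = rng.uniform(0.0, 2.0 * np.pi, size=n_beads)
        return MagneticObject(
            kind="cell",
            n_beads=n_beads,
            bead_offsets=r * u,
            bead_thetas=thetas,
            bead_psis=psis,
            bead_moments=np.full(n_beads, bead.moment_saturation),
            cell_diameter=cell_diameter,
        )
    raise ValueError(f"unknown object kind {kind!r}")


def generate_sample(
    composition: SampleComposition,
    channel: ChannelGeometry,
    duration: float,
    rng: np.random.Generator,
    bead: BeadMagnetics = BeadMagnetics(),
    cell_dist: Optional[SizeDistribution] = None,
    aggregate_dist: Optional[SizeDistribution] = None,
    x_jitter: bool = False,
) -> list[TransitEvent]:
    """Draw the transit events occurring during ``duration`` seconds.

    Arrivals per object class are homogeneous Poisson processes with rate
    concentration x volumetric flow rate.  Cells whose drawn label count is
    zero produce no object (an unlabeled cell is magnetically invisible).
    Transit heights are uniform over the object-center range the channel
    allows; the lateral offset along the sensor long axis defaults to 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if cell_dist is None:
        cell_dist = beads_per_cell_distribution()
    if aggregate_dist is None:
        aggregate_dist = aggregate_size_distribution()

    q = channel.flow_mL_per_s  # mL/s
    events: list[TransitEvent] = []

    def heights(n: int, obj_radius: float) -> np.ndarray:
        lo = channel.spacer_thickness + obj_radius
        hi = channel.spacer_thickness + channel.height - obj_radius
        if hi <= lo:  # object barely fits; pin to mid-channel
            return np.full(n, channel.spacer_thickness + channel.height / 2.0)
        return rng.uniform(lo, hi, size=n)

    def offsets(n: int) -> np.ndarray:
        if x_jitter:
            return rng.uniform(-channel.width / 2.0, channel.width / 2.0, size=n)
        return np.zeros(n)

    # labeled cells
    n_cells = rng.poisson(composition.cell_concentration * q * duration)
    if n_cells:
        times = np.sort(rng.uniform(0.0, duration, size=n_cells))
        labels = cell_dist.sample(rng, n_cells)
        hs = heights(n_cells, composition.cell_diameter / 2.0)
        xs = offsets(n_cells)
        for t, nb, h, x in zip(times, labels, hs, xs):
            if nb < 1:
                continue  # unlabeled cell: no magnetic object
            obj = make_object("cell", int(nb), rng, bead, composition.cell_diameter)
            events.append(TransitEvent(obj, float(t), float(h), float(x)))

    # free beads, clustered into aggregates
    free_beads = composition.bead_concentration * (1.0 - composition.fraction_beads_bound)
    agg_concentration = free_beads / aggregate_dist.mean if free_beads > 0 else 0.0
    n_aggs = rng.poisson(agg_concentration * q * duration)
    if n_aggs:
        times = np.sort(rng.uniform(0.0, duration, size=n_aggs))
        sizes = aggregate_dist.sample(rng, n_aggs)
        hs = heights(n_aggs, bead.diameter / 2.0)
        xs = offsets(n_aggs)
        for t, nb, h, x in zip(times, sizes, hs, xs):
            kind = "bead" if nb == 1 else "aggregate"
            obj = make_object(kind, int(nb), rng, bead)
            events.append(TransitEvent(obj, float(t), float(h), float(x)))

    events.sort(key=lambda e: e.t_arrival)
    return events
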