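# Methods

This note records the physical model, the calibration choices, the numerical
decisions and the limits of what the simulations can show.

## Field model

A superparamagnetic bead in the vertical bias field is a point dipole;
everything downstream needs only the *surface average* of the dipole field's
y-component over the rectangular active area (the spin valve is pinned along
y, free along x, and is insensitive to out-of-plane field below a critical
value — we treat that insensitivity as exact). The average has a closed form:
integrating `B_y` of a point dipole over `x ∈ [−L/2, L/2]`, `y ∈ [−l/2, l/2]`
gives corner-evaluated antiderivatives (`1/r` for the x-moment projection,
`−uv/((v²+h²)r)` for y, `hu/((v²+h²)r)` for z). The implementation carries
the `μ0/4π` prefactor so outputs are tesla, consistent with the μT-scale
detectivities used throughout.

Numerical safeguards:

* `sensor_averaged_hy_quadrature` is an independent oracle (adaptive 2-D
  quadrature of the raw dipole field); the closed form agrees with it to
  better than 1e−6 relative over h ∈ [1, 30] μm, θ ∈ [0, π/2], ψ ∈ [0, 2π).
  Any sign or transcription doubt in the closed form is settled by the
  oracle.
* `h ≤ 0` (dipole at or below the sensor plane) is a domain error.
* The yoke-shaped element is modeled as its 120 × 4 μm bounding rectangle;
  the yoke arms are ignored.

### Object signals

* **Aggregates** are N co-located vertical dipoles at the operating moment
  (1.6 × 10⁻¹¹ emu at 90 mT): exactly N× the single-bead signal. The spatial
  extent of real aggregates has negligible influence on the signal, so
  co-location is adopted. Where only aggregate amplitudes are needed (the
  design module), the N beads are collapsed into one dipole of N× moment,
  which is mathematically identical and O(1) in N.
* **Cells** are spheres (default 6 μm diameter) with beads placed uniformly
  at random on the surface. Each bead's moment has the *saturation*
  magnitude (2.1 × 10⁻¹¹ emu) tilted by θ drawn uniformly in [0, θmax], with
  θmax solving sin(θmax)/θmax = m_op/m_sat ≈ 0.762 (θmax ≈ 1.19 rad). The
  measured 90 mT ensemble magnetization is thus enforced in expectation, not
  per cell — the per-cell constraint is not precisely determined by the
  available characterization, and the ensemble version is the weaker, safer
  assumption.
* `peak_amplitude` sweeps the transit coordinate densely (default 2001
  points over sensor half-width + 10 heights per side); halving the
  resolution changes the result by < 0.1%.

### Transit direction

Transits cross the sensor along y (the 4 μm dimension), which produces the
bipolar signature for vertical moments; for that geometry the negative lobe
arrives first, so the natural detector orientation constant is k = −1. The
axis and k are configurable.

## Sample synthesis

The generator emulates the study conditions, not a dial to tune:

* **Aggregate sizes** — zero-truncated geometric, the simplest one-parameter
  family through the printed anchor: p solves (1−p)⁶ = 0.07, giving
  p ≈ 0.358, P(n < 7) = 0.93 and P(n < 15) ≈ 0.998 (the second anchor, 0.99,
  follows to within 0.01 without further freedom).
* **Beads per cell** — negative binomial (mean 50), the simplest
  two-parameter family fitting both anchors; the dispersion is calibrated by
  root-finding so P(n > 7) = 0.98. Cells drawing 0 beads (~0.03%) are
  magnetically invisible and emit no object.
* **Free beads** — the default 2 × 10⁷ beads/mL are grouped into aggregate
  objects with sizes from the aggregate law (the commercial suspension's own
  clustering), so the object concentration is beads / E[size] ≈ beads/2.79.
* **Arrivals** — Poisson per class at concentration × volumetric flow
  (default 1 mL / 30 min, i.e. mean transit speed ≈ 0.22 m/s through the
  25 × 100 μm cross-section).
* **Heights** — uniform over the object-center range the channel allows
  (spacer + radius to spacer + height − radius). Lateral offset along the
  sensor long axis defaults to 0 (configurable jitter over the channel
  width).

What the generator does *not* emulate: binding kinetics of the 2 h
incubation, antibody affinity, cell-line biology (negative samples are
simply bead-only compositions), Poiseuille velocity profiles (plug flow per
the constant-speed transit model), day-to-day sensor and channel-geometry
variability. Consequently, passing end-to-end tests demonstrates pipeline
correctness and concentration linearity — not the absolute non-specific
count levels of any particular experiment, which depend on exactly the
variability not modeled.

## Acquisition chain

`V = bias × sensitivity(per T) × B × 500 × 20`, sampled at 200 kHz. The
anti-aliasing filter is a 4th-order Butterworth at 15 kHz applied
zero-phase (forward-backward), a deliberate choice so the filter itself does
not skew the pulse symmetry the validator tests; the hardware filter's exact
topology is not modeled. Filter attenuation of realistic pulses (≥ 10
samples) stays below 5%.

Noise is specified as a single field-equivalent RMS (`noise_rms_field`,
default detectivity/3 = 0.73 μT, consistent with a threshold at
signal-to-noise 3). The printed per-experiment noise figures cannot be
reconciled quantitatively under a white-noise model, so this one tunable is
the noise interface; white noise is pre-scaled by the filter's measured RMS
gain so the *post-filter* RMS equals the requested value. An optional
two-state random-telegraph injector produces the square artifacts the
symmetry criterion exists to reject.

## Detector

Implementation choices where the published description is silent:

* Seeding uses |V| > Vthr (either polarity) since genuine signals are
  bipolar.
* The refine window starts at seed ± edge_margin and grows symmetrically by
  15 samples per side; the search is capped at 4 × width_max (rejection
  reason `unterminated_search`) or when pinned against both trace ends.
* The symmetry metric is read as |V_max + V_min|/|V_max − V_min| < 0.4 —
  the reading that accepts symmetric bipolar pulses (the inverse reading
  rejects every valid pulse).
* Bipolarity additionally requires V_max > 0 > V_min (implied by "bipolar";
  the magnitude checks alone would pass a monopolar window in pathological
  cases).
* Every super-threshold sample seeds a search, so deduplication is
  required: intervals identical or overlapping ≥ 50% of the shorter one
  merge, keeping the larger peak-to-peak swing.

Validation order is bipolarity → orientation → width → symmetry; the first
failure is recorded.

## Design optimization

`detectable_height(n)` bisects `peak_amplitude = detectivity` to 0.05 μm,
with the minimum height one bead radius (an object physically cannot be
lower); undetectable objects return a flagged 0. Discrimination fractions
weight, per size n, the detectable slice of the uniform height range by the
size distribution, treating cells as co-located bead stacks at the operating
moment — their worst case for the height inversion (the full decorated-
sphere Monte Carlo remains available through `make_object` +
`peak_amplitude` for verification).

Under these conventions a 7-bead object at the pooled 2.2 μT detectivity is
detectable up to 7.2 μm. The published design analysis places the same
quantity at 6 μm; the ~1 μm difference is within the uncertainty of
conventions that analysis leaves unstated (height datum relative to the
passivation surface vs the sensing layer, bead-center vs bead-bottom, yoke
arms). We report the model's own value rather than adjusting any convention
to match.

## Assay statistics

Population standard deviation (divisor n) is used throughout: on the
packaged count matrix it is the convention that reproduces every printed
mean ± SD cell at two significant figures and the 1.1 × 10³ / 8.2 × 10² /
3.6 × 10³ threshold chain from the four bead-only counts; sample SD
(divisor n−1) does not. Verdicts compare row *means* to the threshold, and
the LOD bracket is (highest negative-verdict concentration, lowest
positive-verdict concentration). Blank-based ELISA-style limits are
mean + 3 SD (LOD) and mean + 10 SD (LOQ) with the same SD convention.

## Problem sizes in the test suite

The end-to-end titration test runs five concentrations (10³–10⁵ cells/mL)
for 60 simulated seconds each (≈ 33 μL of sample per run), cell-only
compositions, noise off, fixed seed. Sixty seconds gives the bottom
titration pair (10³ vs 3 × 10³/mL, expected ≈ 8 vs 25 detected cells) a ≈ 3σ
monotonicity margin. Cell-only compositions are used because the full
default free-bead background under uniform transit heights is large enough
that single-run monotonicity at the bottom of the titration would be a coin
flip at any feasible duration — the recovery property under test concerns
the cell pipeline, while the bead background is characterized separately by
the design module's discrimination fractions. The oracle-equivalence test
draws 100 random dipole states; distribution-calibration tests use 10⁴
draws and 20 seeds for arrival statistics.

## Known limitations

* The field model is magnetostatic and linear; sensor transfer-function
  fidelity beyond gain + low-pass (hysteresis, micromagnetics, 50 Hz pickup,
  magnetophoretic forces) is out of scope.
* Absolute simulated non-specific counts exceed the measured ones — real
  aggregates are depleted near the channel floor and experiments carry
  variability the generator does not model; conclusions should rest on
  relative comparisons (spacer on/off, concentration ratios), which is how
  the design module is used.
* The detectability inversion assumes vertical moments; tilted-moment
  objects have slightly lower peaks, so the curve is an upper envelope.
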