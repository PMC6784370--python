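# gmrcyto

Simulation and analysis toolkit for **magnetic flow cytometry**: counting
antibody-labeled cells one by one as they flow over a giant-magnetoresistance
(GMR) spin-valve sensor.

## The problem

A cell decorated with superparamagnetic beads (magnetized vertically by a
permanent ~90 mT field) acts as a cluster of point dipoles. As it transits a
microfluidic channel above a narrow spin-valve element, the sensor — sensitive
only to the in-plane y-component of the field, averaged over its active
rectangle — sees a characteristic **bipolar voltage pulse**. Free beads also
cluster into aggregates that produce the same kind of pulse and are the
dominant source of non-specific counts. Whether a sample is "positive" is
therefore a chain of physics, signal processing and statistics:

1. **Field model.** For a dipole at `(x_B, y_B, z_B)` with moment μ at polar
   angle θ and azimuth ψ, the sensor-averaged y-field over the rectangle
   `[-L/2, L/2] × [-l/2, l/2]` has the closed form

   ```
   ⟨B_y⟩ = μ0 μ / (4π L l) · [ S_x sinθ cosψ + S_y sinθ sinψ + S_z cosθ ]
   ```

   where `S_x = 1/r1 − 1/r2 + 1/r3 − 1/r4`,
   `S_y = y_l/q2²·(x_r/r2 − x_l/r1) + y_r/q4²·(x_l/r4 − x_r/r3)`,
   `S_z = h/q2²·(x_l/r1 − x_r/r2) + h/q4²·(x_r/r3 − x_l/r4)`,
   with `x_r = L/2 − x_B`, `x_l = −L/2 − x_B`, `y_r = l/2 − y_B`,
   `y_l = −l/2 − y_B`, `h = z_B − z_C`, corner distances `r1…r4` and
   `q2² = y_l² + h²`, `q4² = y_r² + h²`. The closed form is validated against
   adaptive 2-D quadrature of the raw dipole field to 1e−6 relative.

2. **Sample statistics.** Aggregate sizes follow a zero-truncated geometric
   law calibrated so 93% of objects carry < 7 beads; beads-per-cell follow a
   negative binomial with mean 50 calibrated so 98% of cells carry > 7 beads.
   Arrivals are Poisson at concentration × flow rate; transit heights are
   uniform over the channel cross-section above the separation layer.

3. **Detection.** Every sample above the voltage threshold seeds a growing
   window search for the local extrema; candidates must be bipolar (both
   lobes > Vthr/3), correctly oriented (`k·(i_max − i_min) < 0`), of width
   25 μs – 2.5 ms, and symmetric (`|V_max + V_min|/|V_max − V_min| < 0.4`).

4. **Assay statistics.** Counts are normalized to 1 mL; the positivity
   threshold is the mean + 3 SD (population) of the worst negative control,
   and the limit of detection is bracketed by the titration verdicts.

## Worked example

```bash
gmrcyto reproduce-table2
```

prints the packaged seven-experiment count matrix with per-sample mean ± SD
and the decision chain:

```
   sample_label nominal_class  concentration_per_mL  n_replicates         mean          sd
        1e5 NS1      positive              100000.0             3 12396.666667 1779.492874
        3e4 NS1      positive               30000.0             4  4971.500000  972.927156
        1e4 NS1      positive               10000.0             4  1903.500000  609.488925
        ...
     beads only      negative                   NaN             4  1140.750000  821.747642
negative mean = 1141 /mL, SD = 821.7 /mL, count threshold = 3606 /mL
LOD bracket: 1e+04 .. 3e+04 cells/mL
```

The worst negative control (antibody-coated beads alone, mean 1.1 × 10³/mL,
SD 8.2 × 10²/mL) sets a positivity threshold of 3.6 × 10³ counts/mL; samples
at 3 × 10⁴ cells/mL and above exceed it while 10⁴/mL does not, so the limit
of detection lies between 10⁴ and 3 × 10⁴ cells/mL.

From Python, the design question "how thick must the separation layer be?"
is one call chain:

```python
>>> import gmrcyto as g
>>> sensor, bead = g.SensorGeometry(), g.BeadMagnetics()
>>> g.detectable_height(7, sensor.detectivity, bead, sensor) * 1e6   # μm
7.22
>>> cells, aggs = g.beads_per_cell_distribution(), g.aggregate_size_distribution()
>>> g.discrimination_fractions(cells, aggs, 6e-6, g.ChannelGeometry())
DiscriminationReport(spacer=6e-06, fraction_cells_detectable=0.507,
                     fraction_aggregates_detectable=0.0069)
```

A 7-bead object stops being detectable ~7 μm above the sensor, so a 6 μm
spacer silences 99.3% of aggregates while half the labeled-cell population
stays visible.

Other CLI verbs: `simulate` (composition YAML → trace CSV), `detect`
(trace → events TSV), `analyze` (events → counts/mL), `design`
(detectability/discrimination report), `run-campaign` (seeded multi-sample
pipeline with a checksummed manifest).

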