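"""Size-distribution calibration and sample generation statistics."""

import numpy as np
import pytest
from scipy import stats

from gmrcyto import (
    BeadMagnetics,
    ChannelGeometry,
    SampleComposition,
    aggregate_size_distribution,
    beads_per_cell_distribution,
    generate_sample,
    make_object,
)
from gmrcyto.sample import tilt_angle_max


class TestAggregateDistribution:
    def test_calibrated_anchors(self):
        d = aggregate_size_distribution()
        assert d.prob_less_than(7) == pytest.approx(0.93, abs=1e-9)
        assert d.prob_less_than(15) == pytest.approx(0.99, abs=0.01)

    def test_calibrated_parameter_value(self):
        p = 1.0 - 0.07 ** (1.0 / 6.0)
        assert p == pytest.approx(0.358, abs=0.001)
        d = aggregate_size_distribution(p=p)
        assert d.prob_less_than(7) == pytest.approx(0.93, abs=1e-6)

    def test_degenerate_limit_all_singletons(self):
        d = aggregate_size_distribution(p=0.999999)
        assert d.pmf[0] == pytest.approx(1.0, abs=1e-5)

    def test_normalized(self):
        d = aggregate_size_distribution()
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sampled_cdf_matches_table(self, rng):
        d = aggregate_size_distribution()
        draws = d.sample(rng, 10_000)
        ks = _ks_discrete(draws, d)
        assert ks < 0.02


class TestCellDistribution:
    def test_calibrated_anchors(self):
        d = beads_per_cell_distribution()
        assert d.mean == pytest.approx(50.0, abs=0.5)
        assert d.prob_greater_than(7) == pytest.approx(0.98, abs=0.005)

    def test_large_dispersion_recovers_poisson(self):
        d = beads_per_cell_distribution(mean=50.0, dispersion=1e9)
        pois = stats.poisson.pmf(d.n, 50.0)
        np.testing.assert_allclose(d.pmf, pois / pois.sum(), atol=1e-6)

    def test_sampled_cdf_matches_table(self, rng):
        d = beads_per_cell_distribution()
        draws = d.sample(rng, 10_000)
        ks = _ks_discrete(draws, d)
        assert ks < 0.02


def _ks_discrete(draws, dist):
    emp = np.searchsorted(np.sort(draws), dist.n, side="right") / len(draws)
    return float(np.max(np.abs(emp - dist.cdf)))


class TestMakeObject:
    def test_aggregate_colocated_vertical(self, bead, rng):
        agg = make_object("aggregate", 7, rng, bead)
        assert np.all(agg.bead_offsets == 0.0)
        assert np.all(agg.bead_thetas == 0.0)
        assert np.all(agg.bead_moments == bead.moment_operating)

    def test_cell_beads_on_sphere_surface(self, bead, rng):
        cell = make_object("cell", 25, rng, bead, cell_diameter=6e-6)
        radii = np.linalg.norm(cell.bead_offsets, axis=1)
        np.testing.assert_allclose(radii, 3e-6, rtol=1e-12)

    def test_cell_reproducible_by_seed(self, bead):
        a = make_object("cell", 10, np.random.default_rng(7), bead)
        b = make_object("cell", 10, np.random.default_rng(7), bead)
        c = make_object("cell", 10, np.random.default_rng(8), bead)
        np.testing.assert_array_equal(a.bead_offsets, b.bead_offsets)
        assert np.any(a.bead_offsets != c.bead_offsets)
        assert a.n_beads == c.n_beads == 10

    def test_tilt_sampler_matches_operating_moment(self, bead, rng):
        # mean vertical moment projection must equal the measured 90 mT moment
        tmax = tilt_angle_max(bead)
        thetas = rng.uniform(0.0, tmax, size=10_000)
        target = bead.moment_operating / bead.moment_saturation
        assert np.cos(thetas).mean() == pytest.approx(target, rel=0.02)

    def test_zero_beads_rejected(self, bead, rng):
        with pytest.raises(ValueError):
            make_object("cell", 0, rng, bead)


class TestGenerateSample:
    def test_no_cells_in_bead_only_composition(self, channel, bead, rng):
        comp = SampleComposition(label="beads only", cell_concentration=0.0)
        events = generate_sample(comp, channel, 0.2, rng, bead)
        assert all(e.obj.kind in ("bead", "aggregate") for e in events)

    def test_poisson_arrival_rate(self, channel, bead):
        comp = SampleComposition(cell_concentration=0.0, bead_concentration=2e7)
        from gmrcyto.sample import aggregate_size_distribution

        agg = aggregate_size_distribution()
        duration = 0.05
        lam = 2e7 / agg.mean * channel.flow_mL_per_s * duration
        total = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            total += len(generate_sample(comp, channel, duration, rng, bead, aggregate_dist=agg))
        expect = n_seeds * lam
        assert abs(total - expect) < 3.0 * np.sqrt(expect)

    def test_heights_within_channel(self, channel, bead, rng):
        comp = SampleComposition(cell_concentration=5e5, bead_concentration=5e7)
        events = generate_sample(comp, channel, 0.05, rng, bead)
        lo = channel.spacer_thickness
        hi = channel.spacer_thickness + channel.height
        assert events
        for e in events:
            assert lo <= e.height <= hi

    def test_event_counts_scale_with_concentration_and_duration(self, channel, bead):
        base = SampleComposition(cell_concentration=0.0, bead_concentration=1e7)
        double = SampleComposition(cell_concentration=0.0, bead_concentration=2e7)
        n_base = np.mean([
            len(generate_sample(base, channel, 0.05, np.random.default_rng(s), bead))
            for s in range(10)
        ])
        n_double = np.mean([
            len(generate_sample(double, channel, 0.05, np.random.default_rng(s), bead))
            for s in range(10)
        ])
        n_long = np.mean([
            len(generate_sample(base, channel, 0.10, np.random.default_rng(s), bead))
            for s in range(10)
        ])
        assert n_double / n_base == pytest.approx(2.0, rel=0.2)
        assert n_long / n_base == pytest.approx(2.0, rel=0.2)

    def test_fixed_seed_reproducible(self, channel, bead):
        comp = SampleComposition(cell_concentration=1e5, bead_concentration=1e7)
        a = generate_sample(comp, channel, 0.05, np.random.default_rng(5), bead)
        b = generate_sample(comp, channel, 0.05, np.random.default_rng(5), bead)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert ea.t_arrival == eb.t_arrival
            assert ea.height == eb.height
            assert ea.obj.n_beads == eb.obj.n_beads
            np.testing.assert_array_equal(ea.obj.bead_offsets, eb.obj.bead_offsets)

    def test_mean_speed_matches_hand_value(self, channel):
        # 1 mL / 30 min through a 25 x 100 um cross-section
        assert channel.mean_speed == pytest.approx(0.222, rel=0.01)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SampleComposition(cell_concentration=-1.0)
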