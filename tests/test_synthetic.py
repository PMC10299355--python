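"""Synthetic-scene generator: determinism, truth bookkeeping, limiting cases."""

import numpy as np
import pytest
from scipy import stats

from soyscout.geostats import empirical_semivariogram
from soyscout.synthetic import (
    GaussianRandomField,
    GridSpec,
    NdviSimConfig,
    RenderConfig,
    VariogramParams,
    generate_damage_field,
    generate_ndvi_triplet,
    render_scene,
)


class TestVariogramParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="cubic", nugget=0.1, partial_sill=0.9, range_eff=10),
            dict(model="exponential", nugget=-0.1, partial_sill=0.9, range_eff=10),
            dict(model="exponential", nugget=0.0, partial_sill=0.0, range_eff=10),
            dict(model="exponential", nugget=0.1, partial_sill=0.9, range_eff=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariogramParams(**kwargs)

    def test_sill_is_nugget_plus_partial(self):
        p = VariogramParams("spherical", 0.3, 0.7, 50.0)
        assert p.sill == pytest.approx(1.0)


class TestGridSpec:
    def test_centroid_lattice(self):
        g = GridSpec(n_rows=2, n_cols=3, cell_size=10.0, origin_x=5.0, origin_y=-5.0)
        xy = g.centroids()
        assert xy.shape == (6, 2)
        # row-major: first centroid is cell (0, 0)
        np.testing.assert_allclose(xy[0], [10.0, 0.0])
        np.testing.assert_allclose(xy[-1], [30.0, 10.0])

    def test_invalid_cell_size(self):
        with pytest.raises(ValueError):
            GridSpec(n_rows=2, n_cols=2, cell_size=0.0)


class TestDamageField:
    def test_seed_determinism(self):
        p = VariogramParams("exponential", 0.2, 0.8, 60.0)
        g = GridSpec(n_rows=12, n_cols=12, cell_size=10.0)
        a = generate_damage_field(p, g, seed=42)
        b = generate_damage_field(p, g, seed=42)
        np.testing.assert_array_equal(a, b)
        c = generate_damage_field(p, g, seed=43)
        assert not np.array_equal(a, c)

    def test_bounds_respected(self):
        p = VariogramParams("gaussian", 0.5, 0.5, 40.0)
        g = GridSpec(n_rows=10, n_cols=10, cell_size=10.0)
        f = generate_damage_field(p, g, seed=0, low=0.1, high=0.9)
        assert f.min() >= 0.1 and f.max() <= 0.9

    def test_pure_nugget_has_flat_semivariogram(self):
        """With zero structured variance the empirical semivariogram shows no
        trend with lag: the regression slope over the lag span is a small
        fraction of the sill."""
        p = VariogramParams("exponential", 1.0, 0.0, 50.0)
        g = GridSpec(n_rows=40, n_cols=40, cell_size=10.0)
        f = generate_damage_field(p, g, seed=3, transform="none")
        sv = empirical_semivariogram(g.centroids(), f.ravel(), n_bins=10)
        slope = stats.linregress(sv.lags, sv.gamma).slope
        assert abs(slope) * sv.max_lag < 0.1 * sv.gamma.mean()

    def test_vanishing_variance_gives_constant_field(self):
        p = VariogramParams("exponential", 0.0, 1e-12, 50.0)
        g = GridSpec(n_rows=8, n_cols=8, cell_size=10.0)
        f = generate_damage_field(p, g, seed=0, transform="none")
        assert np.abs(f).max() < 1e-4

    def test_grf_sample_variance_near_sill(self):
        p = VariogramParams("spherical", 0.4, 0.6, 30.0)
        g = GridSpec(n_rows=20, n_cols=20, cell_size=10.0)
        grf = GaussianRandomField(p, g)
        samples = np.stack([grf.sample(s) for s in range(50)])
        # pointwise variance across replicates approaches the total sill
        v = samples.var(axis=0).mean()
        assert v == pytest.approx(p.sill, rel=0.25)


class TestRenderScene:
    def _scene(self, value, seed=0, px=10, jitter=0):
        g = GridSpec(n_rows=6, n_cols=6, cell_size=10.0)
        f = np.full((6, 6), value)
        return render_scene(f, g, RenderConfig(px_per_cell=px, jitter=jitter), seed=seed)

    def test_all_healthy(self):
        sc = self._scene(0.0)
        assert not sc.truth_mask.any()
        assert sc.realized_fraction.max() == 0.0

    def test_all_defoliated(self):
        sc = self._scene(1.0)
        assert sc.truth_mask.all()
        assert sc.realized_fraction.min() == 1.0

    def test_realized_fraction_within_binomial_interval(self):
        """Each cell's realized defoliated fraction sits inside the 99%
        binomial interval around the requested intensity (400 px/cell)."""
        g = GridSpec(n_rows=5, n_cols=5, cell_size=10.0)
        f = np.full((5, 5), 0.4)
        sc = render_scene(f, g, RenderConfig(px_per_cell=20, jitter=0), seed=11)
        half = 2.576 * np.sqrt(0.4 * 0.6 / 400)
        assert np.all(np.abs(sc.realized_fraction - 0.4) <= half)

    def test_truth_conservation(self):
        g = GridSpec(n_rows=4, n_cols=4, cell_size=10.0)
        f = np.linspace(0, 1, 16).reshape(4, 4)
        sc = render_scene(f, g, RenderConfig(px_per_cell=8), seed=5)
        per_cell = sc.realized_fraction * 64
        assert per_cell.sum() == sc.truth_mask.sum()

    def test_determinism_and_shape(self):
        a = self._scene(0.5, seed=9, jitter=10)
        b = self._scene(0.5, seed=9, jitter=10)
        np.testing.assert_array_equal(a.rgb, b.rgb)
        assert a.rgb.shape == (60, 60, 3)
        assert a.truth_mask.shape == (60, 60)

    def test_zero_pixels_per_cell_rejected(self):
        with pytest.raises(ValueError):
            RenderConfig(px_per_cell=0)


class TestNdviTriplet:
    def test_zero_noise_exact_difference(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:12, 3:9] = True
        cfg = NdviSimConfig(healthy_ndvi=0.8, damaged_ndvi=0.2, noise_sd=0.0)
        tr = generate_ndvi_triplet(mask, cfg, seed=0)
        ndvi = {
            e: (tr.nir[e] - tr.red[e]) / (tr.nir[e] + tr.red[e])
            for e in ("before", "during")
        }
        diff = ndvi["before"] - ndvi["during"]
        np.testing.assert_allclose(diff[mask], 0.6)
        np.testing.assert_allclose(diff[~mask], 0.0, atol=1e-12)

    def test_zero_regrowth_leaves_after_equal_to_during(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:3] = True
        cfg = NdviSimConfig(noise_sd=0.0, regrowth_fraction=0.0)
        tr = generate_ndvi_triplet(mask, cfg, seed=1)
        np.testing.assert_array_equal(tr.nir["after"], tr.nir["during"])
        assert not tr.regrown_mask.any()

    def test_regrowth_count_exact(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:10] = True  # 300 damaged pixels
        cfg = NdviSimConfig(noise_sd=0.0, regrowth_fraction=0.5)
        tr = generate_ndvi_triplet(mask, cfg, seed=2)
        assert tr.regrown_mask.sum() == 150
        assert (tr.regrown_mask & ~mask).sum() == 0

    def test_reflectances_bounded(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[::2] = True
        tr = generate_ndvi_triplet(mask, NdviSimConfig(noise_sd=0.2), seed=3)
        for stack in (tr.nir, tr.red):
            for arr in stack.values():
                assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            NdviSimConfig(healthy_ndvi=1.2)

    def test_seed_determinism(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5] = True
        a = generate_ndvi_triplet(mask, seed=7)
        b = generate_ndvi_triplet(mask, seed=7)
        for e in ("before", "during", "after"):
            np.testing.assert_array_equal(a.nir[e], b.nir[e])
        np.testing.assert_array_equal(a.regrown_mask, b.regrown_mask)
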