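import numpy as np
import pandas as pd
import pytest

from eamap import ActivationMap, build_maps, isochrones, mapped_cycle_span
from eamap.maps import EmptyMapError


def feature_frame(positions, lats, volts):
    positions = np.asarray(positions, float)
    return pd.DataFrame(dict(
        point_id=np.arange(len(positions)),
        x_mm=positions[:, 0], y_mm=positions[:, 1], z_mm=positions[:, 2],
        lat_ms=lats, p2p_mv=volts,
    ))


class TestInterpolation:
    def test_point_on_vertex_takes_point_value(self, small_mesh):
        pos = small_mesh.vertices[[4]]
        feats = feature_frame(pos, [42.0], [1.3])
        amap, vmap = build_maps(small_mesh, feats, 300.0)
        assert amap.lat[4] == pytest.approx(42.0)
        assert vmap.voltage[4] == pytest.approx(1.3)

    def test_vertices_beyond_fill_threshold_unmapped(self, small_mesh):
        far = small_mesh.vertices[0] + np.array([100.0, 0, 0])
        feats = feature_frame([far], [10.0], [1.0])
        amap, vmap = build_maps(small_mesh, feats, 300.0)
        assert not amap.mapped.any()
        assert not vmap.mapped.any()

    def test_constant_values_interpolate_to_constant(self, small_mesh):
        rng = np.random.default_rng(0)
        pos = small_mesh.vertices[rng.choice(small_mesh.n_vertices, 10, replace=False)]
        feats = feature_frame(pos, np.full(10, 55.0), np.full(10, 2.0))
        amap, _ = build_maps(small_mesh, feats, 300.0)
        assert np.allclose(amap.lat[amap.mapped], 55.0)

    def test_values_bounded_by_point_extrema(self, small_mesh):
        rng = np.random.default_rng(1)
        pos = small_mesh.vertices + rng.normal(0, 0.1, small_mesh.vertices.shape)
        lats = rng.uniform(10, 90, len(pos))
        feats = feature_frame(pos, lats, rng.uniform(0.5, 3, len(pos)))
        amap, _ = build_maps(small_mesh, feats, 300.0)
        m = amap.mapped
        assert amap.lat[m].min() >= lats.min() - 1e-9
        assert amap.lat[m].max() <= lats.max() + 1e-9

    def test_shrinking_fill_threshold_never_adds_vertices(self, small_mesh):
        rng = np.random.default_rng(2)
        pos = small_mesh.vertices[rng.choice(small_mesh.n_vertices, 6, replace=False)]
        feats = feature_frame(pos, np.arange(6.0), np.ones(6))
        mapped = [
            build_maps(small_mesh, feats, 300.0, fill_threshold=f)[0].mapped.sum()
            for f in (5.0, 3.0, 1.5, 0.5)
        ]
        assert all(a >= b for a, b in zip(mapped, mapped[1:]))

    def test_points_at_every_vertex_reproduce_field(self, small_mesh):
        lats = np.linspace(0, 100, small_mesh.n_vertices)
        feats = feature_frame(small_mesh.vertices, lats, np.ones(small_mesh.n_vertices))
        amap, _ = build_maps(small_mesh, feats, 300.0)
        np.testing.assert_allclose(amap.lat, lats, atol=1e-9)

    def test_empty_point_set_raises(self, small_mesh):
        with pytest.raises(EmptyMapError):
            build_maps(small_mesh, feature_frame(np.empty((0, 3)), [], []), 300.0)

    def test_voltage_and_activation_masks_identical(self, default_scenario):
        from eamap.features import annotate_points

        mesh, substrate, truth, points = default_scenario
        amap, vmap = build_maps(mesh, annotate_points(points), truth.tcl)
        np.testing.assert_array_equal(amap.mapped, vmap.mapped)


class TestSpan:
    def test_span_is_max_minus_min(self):
        amap = ActivationMap(lat=np.array([0.0, 90.0, 210.0]), tcl=300.0)
        assert mapped_cycle_span(amap) == 210.0

    def test_translation_invariance(self):
        lat = np.array([5.0, 40.0, 95.0, np.nan])
        a = mapped_cycle_span(ActivationMap(lat=lat, tcl=300.0))
        b = mapped_cycle_span(ActivationMap(lat=lat + 50.0, tcl=300.0))
        assert a == pytest.approx(b)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        lat = rng.uniform(0, 250, 40)
        lat[rng.choice(40, 5, replace=False)] = np.nan
        amap = ActivationMap(lat=lat, tcl=300.0)
        vals = [x for x in lat if not np.isnan(x)]
        brute = max(vals) - min(vals)
        assert mapped_cycle_span(amap) == pytest.approx(brute)

    def test_single_vertex_raises(self):
        with pytest.raises(EmptyMapError):
            mapped_cycle_span(ActivationMap(lat=np.array([1.0, np.nan]), tcl=300.0))


class TestIsochrones:
    def test_band_arithmetic(self):
        lat = np.concatenate([[0.0, 80.0], [35.0], np.full(5, np.nan)])
        iso = isochrones(ActivationMap(lat=lat, tcl=300.0), n_bands=8)
        assert np.allclose(np.diff(iso.band_edges), 10.0)
        assert iso.band_index[2] == 3  # 35 ms falls in [30, 40)

    def test_every_mapped_vertex_in_exactly_one_band(self):
        rng = np.random.default_rng(5)
        lat = rng.uniform(0, 200, 50)
        iso = isochrones(ActivationMap(lat=lat, tcl=300.0), n_bands=6)
        assert ((iso.band_index >= 0) & (iso.band_index < 6)).all()

    def test_band_counts_conserve_mapped_vertices(self):
        rng = np.random.default_rng(6)
        lat = rng.uniform(0, 200, 50)
        lat[:7] = np.nan
        iso = isochrones(ActivationMap(lat=lat, tcl=300.0), n_bands=5)
        counts = np.bincount(iso.band_index[iso.band_index >= 0], minlength=5)
        assert counts.sum() == 43

    def test_zero_span_degenerates_to_single_band(self):
        iso = isochrones(ActivationMap(lat=np.full(4, 10.0), tcl=300.0), n_bands=8)
        assert (iso.band_index == 0).all()

    def test_band_index_increases_with_lat(self):
        lat = np.linspace(0, 100, 30)
        iso = isochrones(ActivationMap(lat=lat, tcl=300.0), n_bands=4)
        assert (np.diff(iso.band_index) >= 0).all()
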