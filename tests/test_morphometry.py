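import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gocquant.equatorial import OocyteModel
from gocquant.image_io import ImageVolume
from gocquant.morphometry import (Filament, aggregate_per_cell,
                                  distance_to_surface, filament_length,
                                  filament_mean_width, filament_to_spots,
                                  measure_cell, orientation_delta,
                                  segment_cells, sphericity)

OOCYTE = OocyteModel(center=(0.0, 0.0, 0.0), radius=30.0, zona_thickness=7.0)


def digitized_sphere(radius_um=5.0, voxel=0.2):
    n = int(2 * radius_um / voxel) + 5
    c = (n - 1) / 2.0 * voxel
    zz, yy, xx = np.ogrid[:n, :n, :n]
    r2 = (zz * voxel - c) ** 2 + (yy * voxel - c) ** 2 + (xx * voxel - c) ** 2
    return r2 <= radius_um**2


class TestSphericity:
    def test_digitized_sphere_near_one(self):
        mask = digitized_sphere(5.0, 0.2)
        _, _, psi = measure_cell(mask, (0.2, 0.2, 0.2))
        assert psi == pytest.approx(1.0, abs=0.03)

    def test_cube_closed_form(self):
        """Analytic cube (V = s³, A = 6s²) gives Ψ = (π/6)^(1/3)."""
        s = 3.7
        assert sphericity(s**3, 6 * s**2) == pytest.approx((np.pi / 6) ** (1 / 3),
                                                           rel=1e-12)

    def test_scale_invariance(self):
        # double the volume at fixed shape: A scales as V^(2/3)
        v, a = 100.0, 120.0
        c = 2.0
        assert sphericity(v * c**3, a * c**2) == pytest.approx(sphericity(v, a))

    def test_anisotropy_decreases_sphericity(self):
        """Equal-volume ellipsoids: more elongated → lower Ψ."""
        psis = []
        for stretch in (1.0, 1.5, 2.5):
            a, b = 4.0 * stretch, 4.0 / np.sqrt(stretch)
            n = int(2 * a / 0.2) + 6
            c = (n - 1) / 2.0 * 0.2
            zz, yy, xx = np.ogrid[:n, :n, :n]
            mask = (((zz * 0.2 - c) / a) ** 2 + ((yy * 0.2 - c) / b) ** 2
                    + ((xx * 0.2 - c) / b) ** 2) <= 1.0
            _, _, psi = measure_cell(mask, (0.2, 0.2, 0.2))
            psis.append(psi)
        assert psis[0] > psis[1] > psis[2]

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            measure_cell(np.zeros((4, 4, 4), dtype=bool), (0.2, 0.2, 0.2))


class TestSegmentation:
    def test_two_cells_recovered(self, small_3d):
        _, channels, truth = small_3d
        segs = segment_cells(channels["gfp"], 75.0, min_volume=100.0)
        assert len(segs) == 2
        measured = sorted(s.volume for s in segs)
        expected = sorted(truth.cell_volumes)
        for m, e in zip(measured, expected):
            assert m == pytest.approx(e, rel=0.05)

    def test_all_background_volume(self):
        vol = ImageVolume(np.full((10, 20, 20), 5.0), (0.2, 0.1, 0.1))
        assert segment_cells(vol, 50.0) == []

    def test_volume_filter_boundary_exclusive(self):
        """A 99 µm³ cell is deleted at min_volume=100; 100 µm³ is kept."""
        data = np.zeros((10, 12, 12))
        data[3:7, 3:8, 3:8] = 100.0  # 4*5*5 = 100 voxels
        vol99 = ImageVolume(data, voxel_size=(1.0, 1.0, 0.99))
        assert segment_cells(vol99, 50.0, min_volume=100.0) == []
        vol100 = ImageVolume(data, voxel_size=(1.0, 1.0, 1.0))
        assert len(segment_cells(vol100, 50.0, min_volume=100.0)) == 1

    def test_empty_volume_rejected(self):
        vol = ImageVolume(np.zeros((1, 1, 1)), (1, 1, 1))
        vol.intensities = np.zeros((0, 0, 0))
        with pytest.raises(ValueError):
            segment_cells(vol, 1.0)

    def test_threshold_below_data_rejected(self):
        vol = ImageVolume(np.full((6, 6, 6), 5.0), (1, 1, 1))
        with pytest.raises(ValueError):
            segment_cells(vol, 1.0)


class TestFilamentMetrics:
    def test_length_three_four_five(self):
        f = Filament(points=[[0, 0, 0], [0, 3, 4]])
        assert filament_length(f) == pytest.approx(5.0)

    def test_length_single_point(self):
        assert filament_length(Filament(points=[[1, 2, 3]])) == 0.0

    def test_length_right_angle_path(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 1], [0, 1, 1]])
        assert filament_length(f) == pytest.approx(2.0)

    def test_width_constant_radius(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 1]], radii=[0.2, 0.2])
        assert filament_mean_width(f) == pytest.approx(0.4)

    def test_width_floor(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 1]], radii=[0.01, 0.01])
        assert filament_mean_width(f) == pytest.approx(0.1)

    def test_width_mixed(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 1]], radii=[0.1, 0.3])
        assert filament_mean_width(f) == pytest.approx(0.4)

    def test_missing_radii_rejected(self):
        with pytest.raises(ValueError):
            filament_mean_width(Filament(points=[[0, 0, 0], [0, 0, 1]]))


class TestSpots:
    def test_straight_filament_counts(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 5.0]])
        chain = filament_to_spots(f, spacing=1.0)
        assert len(chain) == 6
        np.testing.assert_allclose(chain.spots[:, 2], np.arange(6.0))

    def test_short_filament_two_spots(self):
        f = Filament(points=[[0, 0, 0], [0, 0, 0.05]])
        chain = filament_to_spots(f, spacing=0.2)
        assert len(chain) == 2
        np.testing.assert_allclose(chain.spots[0], f.start)
        np.testing.assert_allclose(chain.spots[-1], f.tip)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            filament_to_spots(Filament(points=[[0, 0, 0], [0, 0, 1]]), 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 12), st.integers(0, 10_000),
           st.floats(0.05, 2.0))
    def test_count_spacing_bound(self, n_pts, seed, spacing):
        """spot count × spacing ≥ L − spacing on random polylines."""
        rng = np.random.default_rng(seed)
        f = Filament(points=rng.random((n_pts, 3)) * 10)
        chain = filament_to_spots(f, spacing)
        assert len(chain) * spacing >= filament_length(f) - spacing

    def test_radial_spot_distances_affine_in_index(self):
        """Along a straight radial filament the spot distances to the
        oocyte surface are affine in the spot index."""
        f = Filament(points=[[0, 0, 40.0], [0, 0, 34.0]])
        chain = filament_to_spots(f, spacing=1.0, oocyte=OOCYTE)
        d = chain.distances
        np.testing.assert_allclose(np.diff(d), -1.0, atol=1e-9)


class TestOrientation:
    def test_distance_outside(self):
        assert distance_to_surface([0, 0, 40.0], OOCYTE) == pytest.approx(10.0)

    def test_distance_on_surface(self):
        assert distance_to_surface([0, 30.0, 0], OOCYTE) == pytest.approx(0.0)

    def test_distance_center_signed(self):
        assert distance_to_surface([0, 0, 0], OOCYTE) == pytest.approx(-30.0)

    def test_radial_toward(self):
        f = Filament(points=[[0, 0, 40.0], [0, 0, 36.0]])
        m = orientation_delta(f, OOCYTE)
        assert m.delta == pytest.approx(4.0)
        assert m.orientation_class == "toward"

    def test_radial_away(self):
        f = Filament(points=[[0, 0, 38.0], [0, 0, 42.0]])
        m = orientation_delta(f, OOCYTE)
        assert m.delta == pytest.approx(-4.0)
        assert m.orientation_class == "away"

    def test_tangential_neutral(self):
        r = 35.0
        f = Filament(points=[[0, r * np.cos(0.3), r * np.sin(0.3)],
                             [0, r * np.cos(-0.3), r * np.sin(-0.3)]])
        m = orientation_delta(f, OOCYTE)
        assert m.delta == pytest.approx(0.0, abs=1e-12)
        assert m.orientation_class in ("neutral", "toward", "away")

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_delta_bounded_by_length(self, seed):
        """|Δ| ≤ L: the distance change cannot exceed the path length."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 20, (rng.integers(2, 10), 3))
        f = Filament(points=pts)
        m = orientation_delta(f, OOCYTE)
        assert abs(m.delta) <= m.length + 1e-9

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        """Translating and rotating filament + oocyte together leaves
        L, w, and Δ unchanged to machine precision."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 15, (6, 3)) + [0, 0, 38.0]
        radii = 0.1 + rng.random(6) * 0.2
        f = Filament(points=pts, radii=radii)
        m0 = orientation_delta(f, OOCYTE)
        # random rotation (QR) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(0, 50, 3)
        f2 = Filament(points=pts @ q.T + t, radii=radii)
        oo2 = OocyteModel(center=tuple(np.asarray(OOCYTE.center) @ q.T + t),
                          radius=OOCYTE.radius, zona_thickness=OOCYTE.zona_thickness)
        m1 = orientation_delta(f2, oo2)
        assert m1.length == pytest.approx(m0.length, rel=1e-12)
        assert m1.mean_width == pytest.approx(m0.mean_width, rel=1e-12)
        assert m1.delta == pytest.approx(m0.delta, abs=1e-9)


class TestAggregation:
    def _filament(self, start_r, tip_r, cell):
        return Filament(points=[[0, 0, start_r], [0, 0, tip_r]],
                        radii=[0.2, 0.2], parent_cell=cell)

    def test_away_proportion(self):
        fils = [self._filament(40, 36, 1), self._filament(40, 35, 1),
                self._filament(38, 42, 1)]
        table = aggregate_per_cell(fils, OOCYTE)
        row = table.iloc[0]
        assert row["n_tzp"] == 3
        assert row["away_proportion"] == pytest.approx(1 / 3)

    def test_empty_cell_reported_missing(self):
        fils = [self._filament(40, 36, 1)]
        table = aggregate_per_cell(fils, OOCYTE, cells=[1, 2])
        row2 = table[table["parent_cell"] == 2].iloc[0]
        assert row2["n_tzp"] == 0
        assert np.isnan(row2["away_proportion"])
        assert np.isnan(row2["mean_length_um"])

    def test_orphan_rejected(self):
        with pytest.raises(ValueError, match="parent_cell"):
            aggregate_per_cell([Filament(points=[[0, 0, 40], [0, 0, 36]])], OOCYTE)

    def test_counts_conserved(self, rng):
        fils = []
        for _ in range(40):
            cell = int(rng.integers(0, 5))
            r0, r1 = rng.uniform(31, 45, 2)
            fils.append(self._filament(r0, r1, cell))
        table = aggregate_per_cell(fils, OOCYTE)
        assert table["n_tzp"].sum() == 40
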