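import numpy as np
import pytest

from gocquant.equatorial import (count_equatorial_tzps,
                                 extract_equatorial_profile)
from gocquant.image_io import read_filaments_swc, write_filaments_swc
from gocquant.morphometry import filament_length, orientation_delta
from gocquant.synthetic import (GeometryError, GOCSpec, GroupEffectSpec,
                                SyntheticTruth, experiment_table,
                                generate_goc_2d, generate_goc_3d,
                                measure_specimen, simulate_group_experiment)


class TestSpecValidation:
    def test_defaults_valid(self):
        GOCSpec()

    @pytest.mark.parametrize("kwargs", [
        {"oocyte_radius": -1.0},
        {"zona_thickness": 0.0},
        {"away_fraction": 1.5},
        {"tzp_intensity": 40.0, "cytoplasm_intensity": 50.0},
        {"pixel_size": 0.0},
        {"noise_sd": -1.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GOCSpec(**kwargs)


class TestGenerate2D:
    def test_deterministic_given_seed(self):
        spec = GOCSpec(n_tzp=15, noise_sd=8.0, seed=5, image_shape=(1024, 1024))
        img1, truth1 = generate_goc_2d(spec)
        img2, truth2 = generate_goc_2d(spec)
        assert img1.intensities.tobytes() == img2.intensities.tobytes()
        for p1, p2 in zip(truth1.polylines, truth2.polylines):
            np.testing.assert_array_equal(p1, p2)

    def test_no_tzp_constant_mid_zona_profile(self):
        spec = GOCSpec(n_tzp=0, noise_sd=0.0, seed=1)
        image, truth = generate_goc_2d(spec)
        prof = extract_equatorial_profile(image, truth.oocyte)
        np.testing.assert_allclose(prof.samples, spec.background_intensity,
                                   atol=1e-9)

    def test_truth_counts_match_polylines(self, noiseless_2d):
        _, _, truth = noiseless_2d
        assert truth.n_tzp == len(truth.polylines) == len(truth.radii)

    def test_truth_filaments_measurable(self, noiseless_2d):
        """Measuring the truth polylines reproduces the stored lengths and
        Δ values exactly."""
        _, _, truth = noiseless_2d
        oocyte3 = type(truth.oocyte)(center=(0.0, *truth.oocyte_center),
                                     radius=truth.oocyte_radius,
                                     zona_thickness=truth.zona_thickness)
        for fil, length, delta in zip(truth.filaments(), truth.lengths,
                                      truth.deltas):
            assert filament_length(fil) == pytest.approx(length)
            assert orientation_delta(fil, oocyte3).delta == pytest.approx(delta)

    def test_intensity_scaling_leaves_geometry(self):
        base = GOCSpec(n_tzp=10, noise_sd=0.0, seed=9)
        scaled = base.replace(tzp_intensity=600.0, cytoplasm_intensity=150.0,
                              background_intensity=30.0)
        _, t1 = generate_goc_2d(base)
        _, t2 = generate_goc_2d(scaled)
        for p1, p2 in zip(t1.polylines, t2.polylines):
            np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(t1.widths, t2.widths)

    def test_geometry_exceeding_image_rejected(self):
        with pytest.raises(GeometryError, match="exceeds"):
            generate_goc_2d(GOCSpec(image_shape=(256, 256)))

    def test_unresolvable_density_rejected(self):
        with pytest.raises(GeometryError, match="unresolvable"):
            generate_goc_2d(GOCSpec(n_tzp=500))

    def test_truth_json_round_trip(self, tmp_path, noiseless_2d):
        _, _, truth = noiseless_2d
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.n_tzp == truth.n_tzp
        np.testing.assert_array_equal(back.lengths, truth.lengths)
        np.testing.assert_array_equal(back.deltas, truth.deltas)
        for p1, p2 in zip(truth.polylines, back.polylines):
            np.testing.assert_array_equal(p1, p2)
        assert back.orientation_classes == truth.orientation_classes

    def test_truth_swc_round_trip(self, tmp_path, noiseless_2d):
        _, _, truth = noiseless_2d
        path = tmp_path / "t.swc"
        write_filaments_swc(truth.filaments(), path)
        back = read_filaments_swc(path)
        assert len(back) == truth.n_tzp
        for fil, length in zip(back, truth.lengths):
            assert filament_length(fil) == pytest.approx(length, rel=1e-6)


class TestGenerate3D:
    def test_radial_filament_delta_equals_length(self):
        """tortuosity 0, fan 0: a straight radial 5 µm filament has Δ = 5."""
        spec = GOCSpec(oocyte_radius=5.0, zona_thickness=5.0, n_tzp=1,
                       tzp_length_mean=5.0, tzp_length_sd=0.0, tortuosity=0.0,
                       noise_sd=0.0, image_shape=(40, 340, 340), seed=2)
        _, truth = generate_goc_3d(spec, n_cells=1, cell_radius=3.0,
                                   cell_radius_sd=0.0, fan_sd=0.0)
        assert truth.n_tzp == 1
        assert truth.lengths[0] == pytest.approx(5.0, abs=1e-9)
        assert truth.deltas[0] == pytest.approx(5.0, abs=1e-6)
        assert truth.orientation_classes[0] == "toward"

    def test_away_fraction_one(self):
        spec = GOCSpec(oocyte_radius=3.0, zona_thickness=1.5, n_tzp=4,
                       tzp_length_mean=1.5, tzp_length_sd=0.2,
                       away_fraction=1.0, noise_sd=0.0,
                       image_shape=(40, 220, 220), seed=6)
        _, truth = generate_goc_3d(spec, n_cells=2, cell_radius=2.0)
        assert truth.n_tzp == 8
        assert all(c == "away" for c in truth.orientation_classes)
        assert np.all(truth.deltas < 0)

    def test_overlapping_cells_rejected(self):
        spec = GOCSpec(oocyte_radius=3.0, zona_thickness=1.5, n_tzp=1,
                       noise_sd=0.0, image_shape=(40, 220, 220), seed=1)
        centers = np.array([[3.9, 11.0, 8.0], [3.9, 11.0, 9.0]])
        with pytest.raises(GeometryError, match="overlap"):
            generate_goc_3d(spec, n_cells=2, cell_centers=centers,
                            cell_radius=2.0)

    def test_truth_parent_cells(self, small_3d):
        _, _, truth = small_3d
        assert truth.n_tzp == len(truth.polylines)
        assert set(truth.parent_cells) == {0, 1}


class TestGroupExperiment:
    def test_null_effects_small_difference(self):
        geff = GroupEffectSpec(effect_tzp_count=0.0, seed=4)
        table = experiment_table(simulate_group_experiment(geff))
        ctrl = table[table.group == "control"]["n_tzp"]
        treat = table[table.group == "treated"]["n_tzp"]
        pct = 100 * (ctrl.mean() - treat.mean()) / ctrl.mean()
        assert abs(pct) < 12.0  # Poisson noise only

    def test_imposed_count_effect_recovered(self):
        geff = GroupEffectSpec(effect_tzp_count=-0.35, seed=8)
        table = experiment_table(simulate_group_experiment(geff))
        ctrl = table[table.group == "control"]["n_tzp"]
        treat = table[table.group == "treated"]["n_tzp"]
        pct = 100 * (ctrl.mean() - treat.mean()) / ctrl.mean()
        assert pct == pytest.approx(35.0, abs=12.0)

    def test_length_effect_direction(self):
        geff = GroupEffectSpec(effect_tzp_count=0.0, effect_tzp_length=0.2,
                               seed=10)
        table = experiment_table(simulate_group_experiment(geff))
        ctrl = table[table.group == "control"]["mean_length_um"].mean()
        treat = table[table.group == "treated"]["mean_length_um"].mean()
        assert treat > ctrl

    def test_minimal_n(self):
        geff = GroupEffectSpec(n_per_group=2, seed=1)
        exp = simulate_group_experiment(geff)
        assert len(exp.control) == len(exp.treated) == 2
        table = experiment_table(exp)
        assert len(table) == 4

    def test_deterministic(self):
        geff = GroupEffectSpec(seed=12)
        t1 = experiment_table(simulate_group_experiment(geff))
        t2 = experiment_table(simulate_group_experiment(geff))
        assert t1.equals(t2)

    def test_away_fraction_propagates(self):
        base = GOCSpec(n_tzp=10, away_fraction=1.0)
        geff = GroupEffectSpec(base=base, n_per_group=3, seed=2)
        exp = simulate_group_experiment(geff)
        for specimen in exp.control + exp.treated:
            if specimen.true_n_tzp:
                assert measure_specimen(specimen)["away_proportion"] == 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GroupEffectSpec(n_per_group=1)
        with pytest.raises(ValueError):
            GroupEffectSpec(effect_tzp_count=-1.5)


class TestPipelineConsistency:
    def test_noiseless_count_recovery(self, noiseless_2d):
        _, image, truth = noiseless_2d
        assert count_equatorial_tzps(image, truth.oocyte).raw_count == truth.n_tzp
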