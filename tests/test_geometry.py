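import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindletomo.core import Filament
from spindletomo.geometry import (
    AngleRecord,
    containment,
    estimate_tilt,
    filament_angles,
    filament_length,
    fraction_within_cone,
    length_histogram,
    percent_change,
    rotate_scene,
    spatial_length_map,
    tilt_correct,
    angle_table,
)
from spindletomo.simulate import ClassSpec, SceneSpec, generate_scene

from conftest import straight, two_mass_scene

AXIS_X = np.array([1.0, 0.0, 0.0])


def central_only_spec(seed, n, cone, tilt=None):
    return SceneSpec(
        seed=seed,
        central=ClassSpec(n=n, mean_length_nm=665, sd_length_nm=330, cone_half_angle_deg=cone),
        chromosomal_pb=ClassSpec(n=0),
        chromosomal_pn=ClassSpec(n=0),
        both_contact=ClassSpec(n=0),
        pole=ClassSpec(n=0),
        tilt_deg=tilt,
    )


class TestLength:
    def test_straight_two_point(self):
        assert filament_length(straight("f", [0, 0, 0], [500, 0, 0])) == 500.0

    def test_right_angle_path(self):
        f = Filament("f", [[0, 0, 0], [300, 0, 0], [300, 400, 0]])
        assert filament_length(f) == pytest.approx(700.0)

    def test_matches_bruteforce_segment_sum(self):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(0, 50, (50, 3)), axis=0)
        f = Filament("f", pts)
        brute = sum(
            float(np.sqrt(np.sum((pts[i + 1] - pts[i]) ** 2)))
            for i in range(len(pts) - 1)
        )
        assert filament_length(f) == pytest.approx(brute, rel=1e-12)

    def test_length_at_least_chord(self):
        rng = np.random.default_rng(12)
        pts = np.cumsum(rng.normal(0, 50, (20, 3)), axis=0)
        f = Filament("f", pts)
        assert f.length >= np.linalg.norm(f.chord) - 1e-9


class TestAngles:
    def test_parallel_to_axis_is_zero(self):
        rec = filament_angles(straight("f", [0, 0, 0], [600, 0, 0]), AXIS_X)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)
        assert rec.phi == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_folds_to_zero(self):
        rec = filament_angles(straight("f", [600, 0, 0], [0, 0, 0]), AXIS_X)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)
        assert rec.phi == pytest.approx(0.0, abs=1e-9)

    def test_planar_45_degrees(self):
        rec = filament_angles(straight("f", [0, 0, 0], [500, 500, 0]), AXIS_X)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)
        assert rec.phi == pytest.approx(45.0, abs=1e-9)

    def test_inclination_in_axis_z_plane(self):
        rec = filament_angles(straight("f", [0, 0, 0], [500, 0, 500]), AXIS_X)
        assert rec.theta == pytest.approx(45.0, abs=1e-9)
        assert rec.phi == pytest.approx(0.0, abs=1e-9)

    def test_zero_chord_raises(self):
        loop = Filament("f", [[0, 0, 0], [100, 0, 0], [100, 100, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            filament_angles(loop, AXIS_X)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reversal_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 60, (8, 3)), axis=0)
        f = Filament("f", pts)
        if np.linalg.norm(f.chord) < 1e-6:
            return
        a = filament_angles(f, AXIS_X)
        b = filament_angles(f.reversed(), AXIS_X)
        assert a.theta == pytest.approx(b.theta, abs=1e-9)
        assert a.phi == pytest.approx(b.phi, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 60, (6, 3)), axis=0)
        a = filament_angles(Filament("f", pts), AXIS_X)
        b = filament_angles(Filament("f", pts + [1234.5, -99.0, 42.0]), AXIS_X)
        assert a.theta == pytest.approx(b.theta)
        assert a.phi == pytest.approx(b.phi)


class TestConeFraction:
    def test_all_parallel_is_one(self):
        recs = [AngleRecord(i, 0.0, 0.0) for i in range(10)]
        assert fraction_within_cone(recs, 30.0) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fraction_within_cone([], 30.0)

    def test_isotropic_matches_monte_carlo_oracle(self):
        # oracle: direct evaluation of the double planar constraint on the
        # same isotropic sample, via an independent vectorized formula
        rng = np.random.default_rng(123)
        v = rng.normal(size=(20_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[v[:, 0] < 0] *= -1.0
        tan30 = np.tan(np.radians(30.0))
        vx = np.where(v[:, 0] == 0, 1e-300, v[:, 0])
        oracle = np.mean(
            (np.abs(v[:, 2] / vx) <= tan30) & (np.abs(v[:, 1] / vx) <= tan30)
        )
        recs = [
            filament_angles(Filament(i, [[0, 0, 0], d * 500]), AXIS_X)
            for i, d in enumerate(v)
        ]
        assert fraction_within_cone(recs, 30.0) == pytest.approx(oracle, abs=1e-12)

    def test_cone20_scene_fully_within_30(self):
        scene, _ = generate_scene(central_only_spec(seed=8, n=500, cone=20))
        tab = angle_table(scene)
        recs = [AngleRecord(r.filament_id, r.theta_deg, r.phi_deg) for r in tab.itertuples()]
        assert fraction_within_cone(recs, 30.0) == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=44.0), st.floats(min_value=45.0, max_value=89.0))
    def test_monotone_in_bound(self, lo, hi):
        rng = np.random.default_rng(77)
        v = rng.normal(size=(300, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        recs = [
            filament_angles(Filament(i, [[0, 0, 0], d * 500]), AXIS_X)
            for i, d in enumerate(v)
            if abs(d @ AXIS_X) > 1e-6
        ]
        assert fraction_within_cone(recs, lo) <= fraction_within_cone(recs, hi)


class TestTilt:
    def test_axis_aligned_scene_is_zero(self):
        fils = [straight(f"f{i}", [-300, i * 10, 0], [300, i * 10, 0]) for i in range(5)]
        scene = two_mass_scene(fils)
        ty, tz = estimate_tilt(scene, {f.id for f in fils})
        assert ty == pytest.approx(0.0, abs=1e-9)
        assert tz == pytest.approx(0.0, abs=1e-9)

    def test_recovers_10_degree_z_rotation(self):
        scene, truth = generate_scene(central_only_spec(seed=7, n=200, cone=15, tilt=(0.0, 10.0)))
        ty, tz = estimate_tilt(scene, set(truth.labels.index))
        assert tz == pytest.approx(10.0, abs=2.0)
        assert ty == pytest.approx(0.0, abs=2.0)

    def test_correct_then_measure_residual_below_one_degree(self):
        scene, truth = generate_scene(central_only_spec(seed=11, n=250, cone=15, tilt=(4.0, 10.0)))
        ids = set(truth.labels.index)
        corrected = tilt_correct(scene, ids)
        corrected.axis = AXIS_X.copy()
        tab = angle_table(corrected)
        assert abs(tab["theta_deg"].mean()) < 1.0
        assert abs(tab["phi_deg"].mean()) < 1.0

    def test_empty_id_set_raises(self):
        scene = two_mass_scene([straight("f", [-300, 0, 0], [300, 0, 0])])
        with pytest.raises(ValueError):
            estimate_tilt(scene, set())


class TestContainment:
    def test_boundary_endpoint_not_contained(self, scene_factory):
        # slab x-max is 5000: an endpoint exactly on the face is outside
        fils = [
            straight("on_face", [4000, 0, 0], [5000, 0, 0]),
            straight("inside", [4000, 10, 0], [4999, 10, 0]),
        ]
        scene = scene_factory(fils)
        flags, summary = containment(scene)
        assert not flags["on_face"]
        assert flags["inside"]
        assert summary.n_total == 2
        assert summary.n_fully_contained == 1

    def test_constructed_75_of_100(self, scene_factory):
        fils = []
        for i in range(75):
            fils.append(straight(f"in{i}", [-400, i, 0], [400, i, 0]))
        for i in range(25):
            # one endpoint beyond the slab x-max of 5000
            fils.append(straight(f"out{i}", [4500, i, 0], [5600, i, 0]))
        scene = scene_factory(fils)
        flags, summary = containment(scene)
        assert summary.n_fully_contained == 75
        assert summary.n_fully_contained / summary.n_total == pytest.approx(0.75)

    def test_total_length_matches_independent_sum(self, scene_factory):
        scene, _ = generate_scene(SceneSpec(seed=2))
        _, summary = containment(scene)
        indep = sum(f.length for f in scene.filaments) / 1000.0
        assert summary.total_length_um == pytest.approx(indep, rel=1e-4)


class TestPercentChange:
    def test_published_length_totals(self):
        assert round(percent_change(1499.0, 1102.0)) == 26

    def test_published_intensities(self):
        assert percent_change(0.28, 0.21) == pytest.approx(25.0)

    def test_no_change_is_zero(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_nonpositive_before_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestLengthHistogram:
    def test_boundary_convention(self):
        fils = [
            straight("a", [0, 0, 0], [100, 0, 0]),
            straight("b", [0, 0, 0], [499, 0, 0]),
            straight("c", [0, 0, 0], [500, 0, 0]),
        ]
        s = length_histogram(fils, 500.0)
        assert s.hist_counts.tolist() == [2, 1]
        assert s.hist_counts.sum() == s.n_total

    def test_empty_input(self):
        s = length_histogram([], 500.0)
        assert s.n_total == 0
        assert s.hist_counts.sum() == 0

    def test_gamma_lengths_mode_below_1000(self):
        scene, _ = generate_scene(central_only_spec(seed=4, n=400, cone=25))
        s = length_histogram(scene.filaments, 500.0)
        mode_bin = int(np.argmax(s.hist_counts))
        assert s.hist_edges_nm[mode_bin + 1] <= 1000.0


class TestSpatialLengthMap:
    def test_occupancy_conserves_count(self, scene_factory):
        scene, _ = generate_scene(SceneSpec(seed=6))
        classes, occ, edges = spatial_length_map(scene, 500.0)
        assert occ.sum() == len(scene.filaments)
        assert len(classes) == len(scene.filaments)

    def test_class_matches_bruteforce_binning(self):
        rng = np.random.default_rng(9)
        fils = [
            straight(f"f{i}", [0, 10 * i, 0], [rng.uniform(100, 2000), 10 * i, 0])
            for i in range(30)
        ]
        scene = two_mass_scene(fils)
        classes, _, _ = spatial_length_map(scene, 500.0)
        for f in fils:
            assert classes[f.id] == int(f.length // 500.0)

    def test_single_filament_single_cell(self, scene_factory):
        scene = two_mass_scene([straight("f", [-100, 0, 0], [100, 0, 0])])
        _, occ, _ = spatial_length_map(scene, 500.0)
        assert occ.sum() == 1
        assert (occ > 0).sum() == 1
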