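import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spindletomo.core import Filament
from spindletomo.overlaps import (
    OverlapParams,
    detect_overlaps,
    min_expected_overlap,
    overlap_fraction_table,
    overlap_spatial_map,
)
from spindletomo.simulate import ClassSpec, SceneSpec, generate_scene

from conftest import straight, two_mass_scene


# ---- independent dense-sampling brute-force oracle -----------------------


def _dense_points(f, step):
    seg = np.diff(f.points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(1, int(np.ceil(cum[-1] / step)))
    s = np.linspace(0.0, cum[-1], n + 1)
    pts = np.column_stack([np.interp(s, cum, f.points[:, k]) for k in range(3)])
    return pts, s


def oracle_overlaps(scene, cutoff=45.0, min_length=200.0, step=1.0):
    """All-pairs dense-sampling overlap detection (no spatial index)."""
    fils = sorted(scene.filaments, key=lambda f: str(f.id))
    sampled = [(f.id, *_dense_points(f, step)) for f in fils]
    found = []
    for i in range(len(sampled)):
        for j in range(i + 1, len(sampled)):
            ida, pa, sa = sampled[i]
            idb, pb, sb = sampled[j]
            # bounding-box prefilter
            if np.any(pa.min(0) - cutoff > pb.max(0)) or np.any(
                pb.min(0) - cutoff > pa.max(0)
            ):
                continue
            d = cdist(pa, pb)
            close = d.min(axis=1) < cutoff
            if not close.any():
                continue
            idx = np.flatnonzero(close)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[idx[0]], idx[breaks + 1]])
            stops = np.concatenate([idx[breaks], [idx[-1]]])
            for a0, a1 in zip(starts, stops):
                span_a = sa[a1] - sa[a0]
                nearest = d[a0 : a1 + 1].argmin(axis=1)
                span_b = sb[nearest].max() - sb[nearest].min()
                length = min(span_a, span_b)
                if length >= min_length:
                    found.append((ida, idb, length))
    return found


class TestMinExpectedOverlap:
    def test_published_bound(self):
        assert round(min_expected_overlap(45.0, 30.0)) == 156

    def test_45_degree_cone(self):
        assert min_expected_overlap(45.0, 45.0) == pytest.approx(90.0)

    def test_monotonicity(self):
        assert min_expected_overlap(45.0, 20.0) > min_expected_overlap(45.0, 30.0)
        assert min_expected_overlap(60.0, 30.0) > min_expected_overlap(45.0, 30.0)

    def test_invalid_angle(self):
        for bad in (0.0, 90.0, -5.0):
            with pytest.raises(ValueError):
                min_expected_overlap(45.0, bad)


class TestDetect:
    def test_parallel_segments_one_overlap(self, scene_factory):
        fils = [
            straight("a", [-150, 0, 0], [150, 0, 0]),
            straight("b", [-150, 40, 0], [150, 40, 0]),
        ]
        scene = scene_factory(fils)
        segs = detect_overlaps(scene)
        assert len(segs) == 1
        assert segs[0].pair == ("a", "b")
        assert segs[0].length == pytest.approx(300.0, abs=5.0)

    def test_perpendicular_crossing_rejected(self, scene_factory):
        # min distance 0 at the crossing, but the proximal stretch is only
        # ~2*45/tan(45 deg) = 90 nm < 200 nm
        fils = [
            straight("a", [-500, 0, 0], [500, 0, 0]),
            straight("b", [0, -500, 0], [0, 500, 0]),
        ]
        scene = scene_factory(fils)
        assert detect_overlaps(scene) == []

    def test_no_self_overlap(self, scene_factory):
        # a hairpin running back along itself stays one filament
        f = Filament(
            "hairpin",
            [[0, 0, 0], [600, 0, 0], [600, 10, 0], [0, 10, 0]],
        )
        scene = scene_factory([f])
        assert detect_overlaps(scene) == []

    def test_symmetry_under_reversal_and_order(self, scene_factory):
        a = straight("a", [-300, 0, 0], [300, 0, 0])
        b = straight("b", [-250, 38, 0], [350, 38, 0])
        for fils in ([a, b], [b, a], [a.reversed(), b], [a, b.reversed()]):
            segs = detect_overlaps(two_mass_scene(fils))
            assert len(segs) == 1
            assert segs[0].pair == ("a", "b")
            assert segs[0].length == pytest.approx(550.0, abs=10.0)

    def test_monotone_in_thresholds(self, scene_factory):
        scene, _ = generate_scene(SceneSpec(seed=31, n_overlap_pairs=8))
        base = detect_overlaps(scene)
        tighter = detect_overlaps(scene, OverlapParams(lateral_cutoff=35.0))
        longer = detect_overlaps(scene, OverlapParams(min_length=300.0))
        assert len(tighter) <= len(base)
        assert len(longer) <= len(base)
        assert {s.pair for s in longer} <= {s.pair for s in base}

    def test_matches_bruteforce_oracle_50_filaments(self):
        spec = SceneSpec(
            seed=0,
            central=ClassSpec(n=30, mean_length_nm=665, sd_length_nm=330),
            chromosomal_pb=ClassSpec(n=5, mean_length_nm=508, sd_length_nm=254),
            chromosomal_pn=ClassSpec(n=5, mean_length_nm=508, sd_length_nm=254),
            both_contact=ClassSpec(n=2),
            pole=ClassSpec(n=0),
            n_overlap_pairs=4,
        )
        scene, _ = generate_scene(spec)
        assert len(scene.filaments) == 50
        params = OverlapParams()
        segs = detect_overlaps(scene, params)
        brute = oracle_overlaps(scene)
        assert {s.pair for s in segs} == {(a, b) for a, b, _ in brute}
        brute_by_pair = {}
        for a, b, length in brute:
            brute_by_pair.setdefault((a, b), []).append(length)
        for s in segs:
            candidates = brute_by_pair[s.pair]
            assert min(abs(s.length - c) for c in candidates) <= 2 * params.resample_step

    def test_constructed_pairs_recovered(self):
        scene, truth = generate_scene(SceneSpec(seed=41, n_overlap_pairs=6))
        segs = detect_overlaps(scene)
        pairs = {s.pair for s in segs}
        for a, b, length in truth.overlap_pairs:
            assert tuple(sorted((a, b))) in pairs
        by_pair = {s.pair: s for s in segs}
        for a, b, length in truth.overlap_pairs:
            got = by_pair[tuple(sorted((a, b)))].length
            assert got == pytest.approx(length, abs=35.0)


class TestFractionTable:
    def test_single_class(self):
        scene, _ = generate_scene(SceneSpec(seed=43, n_overlap_pairs=3))
        segs = detect_overlaps(scene)
        labels = {fid: "central_spindle" for fid in scene.filament_ids}
        table = overlap_fraction_table(segs, labels)
        assert len(table) == 1
        assert table["fraction"].iloc[0] == 1.0

    def test_90_10_split(self):
        from spindletomo.overlaps import OverlapSegment

        segs = [
            OverlapSegment(f"a{i}", f"b{i}", 250.0, (0, 0, 0), (0, 250), (0, 250))
            for i in range(10)
        ]
        labels = {}
        for i in range(10):
            labels[f"a{i}"] = "central_spindle"
            labels[f"b{i}"] = "central_spindle" if i < 9 else "pole"
        table = overlap_fraction_table(segs, labels).set_index(["label_a", "label_b"])
        assert table.loc[("central_spindle", "central_spindle"), "fraction"] == pytest.approx(0.9)
        assert table.loc[("central_spindle", "pole"), "fraction"] == pytest.approx(0.1)
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_unlabeled_id_raises(self):
        from spindletomo.overlaps import OverlapSegment

        segs = [OverlapSegment("a", "b", 250.0, (0, 0, 0), (0, 250), (0, 250))]
        with pytest.raises(ValueError):
            overlap_fraction_table(segs, {"a": "central_spindle"})

    def test_central_only_overlaps_give_full_central_fraction(self):
        # overlaps constructed only inside the central spindle: the
        # central-central fraction is 100% (cf. the published 92-100%)
        from spindletomo.classify import classify_scene

        scene, truth = generate_scene(
            SceneSpec(seed=47, n_overlap_pairs=5, pole=ClassSpec(n=40))
        )
        labels = classify_scene(scene)
        segs = detect_overlaps(scene)
        constructed = {tuple(sorted(p[:2])) for p in truth.overlap_pairs}
        segs = [s for s in segs if s.pair in constructed]
        table = overlap_fraction_table(segs, labels["population"])
        assert len(table) == 1
        assert table["label_a"].iloc[0] == "central_spindle"
        assert table["fraction"].iloc[0] == 1.0


class TestSpatialMap:
    def test_empty_list(self):
        occ, classes = overlap_spatial_map([], [-1000] * 3, [1000] * 3, 500.0)
        assert occ.sum() == 0
        assert classes == []

    def test_single_overlap_single_cell(self):
        from spindletomo.overlaps import OverlapSegment

        seg = OverlapSegment("a", "b", 260.0, (10, 10, 10), (0, 260), (0, 260))
        occ, classes = overlap_spatial_map([seg], [-1000] * 3, [1000] * 3, 500.0)
        assert occ.sum() == 1
        assert (occ > 0).sum() == 1
        assert classes == [0]

    def test_uniform_midpoints_near_uniform_occupancy(self):
        from spindletomo.overlaps import OverlapSegment
        from scipy.stats import chisquare

        rng = np.random.default_rng(55)
        mids = rng.uniform(-1000, 1000, size=(4000, 3))
        segs = [
            OverlapSegment(f"a{i}", f"b{i}", 250.0, tuple(m), (0, 250), (0, 250))
            for i, m in enumerate(mids)
        ]
        occ, _ = overlap_spatial_map(segs, [-1000] * 3, [1000] * 3, 500.0)
        assert occ.sum() == 4000
        stat, p = chisquare(occ.ravel())
        assert p > 0.01
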