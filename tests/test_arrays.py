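"""Stacking metrics, H1 classification and the steric screen."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucarray.arrays import (
    H1Footprint,
    NucleosomeUnit,
    classify_h1,
    detect_stacks,
    disc_normal,
    stack_metrics,
    steric_screen,
)
from nucarray.frames import build_frame
from nucarray.io import BasePairCentroidTrack
from nucarray.trajectory import DeltaAngles

from conftest import random_rotation


def _delta(entry=None, exit=None, reference_id="ref"):
    beta = {"entry": entry, "exit": exit}
    defined = [v for v in beta.values() if v is not None]
    avg = float(np.mean(defined)) if defined else None
    return DeltaAngles(
        delta_alpha=dict(beta), delta_beta=dict(beta),
        avg_delta_alpha=avg, avg_delta_beta=avg, reference_id=reference_id,
    )


def _unit(core_geometry, label, rotation=None, translation=None):
    rot = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    pts = core_geometry.centroids @ rot.T + t
    track = BasePairCentroidTrack(pts, 1, 147, label)
    return NucleosomeUnit(label, build_frame(track), track.core_centroids)


class TestStackMetrics:
    def test_translation_along_shared_normal(self, core_geometry):
        normal = disc_normal(core_geometry.centroids)
        a = _unit(core_geometry, "a")
        b = _unit(core_geometry, "b", translation=60.0 * normal)
        geom = stack_metrics(a, b)
        assert geom.normal_angle < 1e-6
        assert geom.dyad_tilt < 1e-6
        assert geom.lateral_offset < 1e-6
        assert abs(geom.center_distance - 60.0) < 1e-9
        assert geom.interface_class == "face-to-face aligned"

    def test_rotation_about_normal_shows_as_dyad_tilt(self, core_geometry):
        normal = disc_normal(core_geometry.centroids)
        rot = Rotation.from_rotvec(np.radians(10.0) * normal).as_matrix()
        center = core_geometry.centroids.mean(axis=0)
        a = _unit(core_geometry, "a")
        b_pts = (core_geometry.centroids - center) @ rot.T + center + 60.0 * normal
        b_track = BasePairCentroidTrack(b_pts, 1, 147, "b")
        b = NucleosomeUnit("b", build_frame(b_track), b_track.core_centroids)
        geom = stack_metrics(a, b)
        # u carries a tiny component along the PCA normal, so the exact
        # expectation is the folded angle between u and its rotated image.
        u = a.frame.u
        expected = np.degrees(np.arccos(abs(np.clip(u @ (rot @ u), -1, 1))))
        assert abs(geom.dyad_tilt - expected) < 1e-9
        assert abs(geom.dyad_tilt - 10.0) < 1e-4
        assert geom.normal_angle < 1e-6

    def test_distant_pair_not_stacked(self, core_geometry):
        a = _unit(core_geometry, "a")
        b = _unit(core_geometry, "b", translation=[200.0, 0, 0])
        assert stack_metrics(a, b).interface_class == "not stacked"

    def test_symmetric_under_pair_exchange(self, core_geometry, rng):
        a = _unit(core_geometry, "a")
        b = _unit(core_geometry, "b", rotation=random_rotation(rng),
                  translation=rng.normal(0, 40, 3))
        g1 = stack_metrics(a, b)
        g2 = stack_metrics(b, a)
        assert g1.pair == g2.pair
        for field in ("center_distance", "normal_angle", "dyad_tilt", "lateral_offset"):
            assert abs(getattr(g1, field) - getattr(g2, field)) < 1e-9
        assert g1.interface_class == g2.interface_class

    def test_angles_folded_to_quadrant(self, core_geometry, rng):
        for _ in range(5):
            a = _unit(core_geometry, "a")
            b = _unit(core_geometry, "b", rotation=random_rotation(rng),
                      translation=rng.normal(0, 50, 3))
            g = stack_metrics(a, b)
            assert 0.0 <= g.normal_angle <= 90.0
            assert 0.0 <= g.dyad_tilt <= 90.0
            assert g.lateral_offset >= 0.0 and g.center_distance >= 0.0


class TestDetectStacks:
    def _units(self, array):
        return [
            NucleosomeUnit(t.label, build_frame(t), t.core_centroids)
            for t in array.tracks()
        ]

    def test_zigzag_preset_yields_exactly_nuc1_nuc3(self, preset_arrays):
        for nrl, array in preset_arrays.items():
            stacks = detect_stacks(self._units(array))
            assert [g.pair for g in stacks] == [("nuc1", "nuc3")], f"NRL {nrl}"

    def test_extended_array_has_no_stacks(self):
        from nucarray.synthetic import SyntheticArraySpec, build_array
        array = build_array(SyntheticArraySpec(n_nucleosomes=4, linker_len=30))
        assert detect_stacks(self._units(array)) == []

    def test_large_normal_tilt_breaks_the_stack(self, core_geometry):
        normal = disc_normal(core_geometry.centroids)
        in_plane = core_geometry.frame.u
        rot = Rotation.from_rotvec(np.radians(45.0) * in_plane).as_matrix()
        a = _unit(core_geometry, "a")
        b = _unit(core_geometry, "b", rotation=rot, translation=60.0 * normal)
        assert detect_stacks([a, b]) == []

    def test_needs_two_units(self, core_geometry):
        with pytest.raises(ValueError, match="at least 2"):
            detect_stacks([_unit(core_geometry, "a")])


class TestClassifyH1:
    def test_both_sides_near_zero_is_compatible(self):
        assert classify_h1(_delta(0.0, 0.0)).compatible is True

    def test_one_bad_side_suffices_for_incompatibility(self):
        call = classify_h1(_delta(2.0, 30.0))
        assert call.compatible is False

    def test_boundary_is_inclusive(self):
        assert classify_h1(_delta(5.9, 5.9)).compatible is True
        assert classify_h1(_delta(6.0, 6.0)).compatible is True
        assert classify_h1(_delta(6.0, 6.01)).compatible is False

    def test_single_defined_side_is_classified(self):
        assert classify_h1(_delta(entry=None, exit=3.0)).compatible is True

    def test_no_defined_side_is_indeterminate_not_false(self):
        call = classify_h1(_delta(None, None))
        assert call.compatible is None
        assert call.status == "indeterminate"

    @pytest.mark.parametrize("base", [(0.0, 0.0), (3.0, 5.0), (5.0, 7.0), (10.0, 1.0)])
    def test_monotone_raising_delta_never_restores_compatibility(self, base):
        for bump in (0.5, 2.0, 10.0, 40.0):
            for side in range(2):
                lo = classify_h1(_delta(*base))
                hi_vals = list(base)
                hi_vals[side] += bump
                hi = classify_h1(_delta(*hi_vals))
                if lo.compatible is False:
                    assert hi.compatible is False

    def test_threshold_recorded(self):
        call = classify_h1(_delta(1.0, 1.0), threshold=4.5)
        assert call.threshold == 4.5


class TestStericScreen:
    def test_empty_environment_has_no_clashes(self, reference_array, reference_track):
        fp = reference_array.h1_footprints["nuc1"]
        report = steric_screen(reference_track, reference_track, fp,
                               np.empty((0, 3)))
        assert report.clash_count == 0

    def test_point_at_footprint_center_clashes(self, reference_array, reference_track):
        fp = reference_array.h1_footprints["nuc1"]
        report = steric_screen(reference_track, reference_track, fp,
                               fp.centers[:1])
        assert report.clash_count >= 1

    def test_missing_footprint_is_error(self, reference_track):
        with pytest.raises(ValueError, match="footprint"):
            steric_screen(reference_track, reference_track, None, np.zeros((1, 3)))

    def test_bent_short_nrl_clashes_relaxed_long_nrl_does_not(
        self, preset_arrays, reference_array, reference_track
    ):
        """The short-repeat array's bent stacked-nucleosome linker collides
        with the mapped H1 footprint; the relaxed long-repeat geometry is
        contact-free everywhere."""
        fp = reference_array.h1_footprints["nuc1"]
        bent = steric_screen(
            preset_arrays[177].track("nuc1"), reference_track, fp,
            preset_arrays[177].environment("nuc1"),
        )
        relaxed_counts = [
            steric_screen(
                preset_arrays[207].track(label), reference_track, fp,
                preset_arrays[207].environment(label),
            ).clash_count
            for label in ("nuc1", "nuc2", "nuc3", "nuc4")
        ]
        assert bent.clash_count >= 1
        assert all(c == 0 for c in relaxed_counts)
        assert bent.clash_count > max(relaxed_counts)

    def test_h1_bound_nucleosomes_are_contact_free(self, preset_arrays,
                                                   reference_array, reference_track):
        from nucarray.synthetic import PRESET_H1_PATTERN
        fp = reference_array.h1_footprints["nuc1"]
        for nrl, array in preset_arrays.items():
            for label, bound in PRESET_H1_PATTERN[nrl].items():
                if not bound:
                    continue
                report = steric_screen(array.track(label), reference_track, fp,
                                       array.environment(label))
                assert report.clash_count == 0, f"NRL {nrl} {label}"

    def test_invariant_under_common_rigid_motion(self, preset_arrays,
                                                 reference_array, reference_track, rng):
        fp = reference_array.h1_footprints["nuc1"]
        array = preset_arrays[177]
        env = array.environment("nuc1")
        base = steric_screen(array.track("nuc1"), reference_track, fp, env)
        rot = random_rotation(rng)
        t = rng.normal(0, 60, 3)
        moved = steric_screen(array.track("nuc1").transformed(rot, t),
                              reference_track, fp, env @ rot.T + t)
        assert moved.clash_count == base.clash_count

    def test_count_non_decreasing_with_cutoff(self, preset_arrays,
                                              reference_array, reference_track):
        fp = reference_array.h1_footprints["nuc1"]
        array = preset_arrays[177]
        env = array.environment("nuc1")
        counts = [
            steric_screen(array.track("nuc1"), reference_track, fp, env,
                          cutoff=c).clash_count
            for c in (0.0, 2.0, 4.0, 8.0, 16.0)
        ]
        assert counts == sorted(counts)
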