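"""ROI construction, dilation, head-ellipse fitting, equalization, assignment."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from gazeroi.io_formats import GazeRecording, ROI_LABELS, ScreenGeometry
from gazeroi.roi_engine import (
    DEFAULT_PRIORITY,
    assign_samples,
    deg_to_px,
    dilate_roi,
    elliptical_kernel,
    equalize_roi_sizes,
    fit_head_ellipse,
    scale_mask,
)
from gazeroi.timecourse import OTHER_LABEL

from conftest import make_tiny_track


class TestDegToPx:
    def test_zero_maps_to_zero(self, geometry):
        assert deg_to_px(0.0, geometry, "horizontal") == 0.0
        assert deg_to_px(0.0, geometry, "vertical") == 0.0

    def test_full_extent_maps_to_frame(self, geometry):
        assert deg_to_px(47.5, geometry, "horizontal") == pytest.approx(1920.0)
        assert deg_to_px(27.8, geometry, "vertical") == pytest.approx(1080.0)

    def test_half_degree(self, geometry):
        assert deg_to_px(0.5, geometry, "horizontal") == pytest.approx(1920.0 / 47.5 * 0.5)

    def test_negative_rejected(self, geometry):
        with pytest.raises(ValueError):
            deg_to_px(-0.1, geometry)


class TestDilate:
    def test_zero_margin_is_identity(self, small_geometry):
        rng = np.random.default_rng(0)
        mask = rng.random((108, 192)) < 0.2
        np.testing.assert_array_equal(dilate_roi(mask, 0.0, small_geometry), mask)

    def test_single_pixel_grows_to_kernel_area(self, geometry):
        # oracle: enumerate the discrete elliptical kernel's pixels
        rx = deg_to_px(0.5, geometry, "horizontal")
        ry = deg_to_px(0.5, geometry, "vertical")
        kernel = elliptical_kernel(rx, ry)
        mask = np.zeros((200, 200), bool)
        mask[100, 100] = True
        dil = dilate_roi(mask, 0.5, geometry)
        assert dil.sum() == kernel.sum()

    def test_equivalent_to_brute_force_kernel_dilation(self, small_geometry):
        rng = np.random.default_rng(1)
        rx = deg_to_px(0.5, small_geometry, "horizontal")
        ry = deg_to_px(0.5, small_geometry, "vertical")
        kernel = elliptical_kernel(rx, ry)
        for _ in range(5):
            mask = np.zeros((108, 192), bool)
            ys = rng.integers(0, 108, size=30)
            xs = rng.integers(0, 192, size=30)
            mask[ys, xs] = True
            expected = ndimage.binary_dilation(mask, structure=kernel)
            np.testing.assert_array_equal(dilate_roi(mask, 0.5, small_geometry), expected)

    def test_contains_input_and_stays_in_frame(self, small_geometry):
        mask = np.zeros((108, 192), bool)
        mask[0:5, 188:192] = True  # touches the frame corner
        dil = dilate_roi(mask, 1.0, small_geometry)
        assert dil.shape == mask.shape
        assert (dil | mask).sum() == dil.sum()  # superset

    def test_empty_mask_warns_and_returns_empty(self, small_geometry):
        with pytest.warns(UserWarning, match="empty"):
            out = dilate_roi(np.zeros((10, 10), bool), 0.5, small_geometry)
        assert not out.any()


class TestHeadEllipse:
    def test_rectangle_full_fraction_centered_unrotated(self):
        mask = np.zeros((100, 100), bool)
        mask[20:80, 30:50] = True
        e = fit_head_ellipse(mask, top_fraction=1.0)
        assert e.center[0] == pytest.approx(39.5, abs=0.01)
        assert e.center[1] == pytest.approx(49.5, abs=0.01)
        assert abs(e.rotation) % (np.pi / 2) == pytest.approx(0.0, abs=1e-6)

    def test_disk_gives_equal_axes(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disk = (xx - 50) ** 2 + (yy - 50) ** 2 <= 20**2
        body = np.zeros((300, 101), bool)
        body[:101] = disk
        body[150:, 30:70] = True  # torso far below; top fraction selects the disk
        e = fit_head_ellipse(body, top_fraction=0.4)
        a, b = e.semi_axes
        assert abs(a - b) / max(a, b) < 0.02
        # area preserved: pi*a*b equals the disk's pixel count
        assert np.pi * a * b == pytest.approx(disk.sum(), rel=0.01)

    def test_two_lobe_mask_uses_joint_centroid(self):
        mask = np.zeros((50, 100), bool)
        mask[0:10, 10:20] = True
        mask[0:10, 80:90] = True
        e = fit_head_ellipse(mask, top_fraction=1.0)
        assert e.center[0] == pytest.approx((14.5 + 84.5) / 2, abs=0.01)

    def test_tiny_region_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[0, 0:3] = True
        mask[40:50, 0:30] = True
        with pytest.raises(ValueError, match="degenerate"):
            fit_head_ellipse(mask, top_fraction=0.05)


def _disk_track(radius, width=400, height=400):
    yy, xx = np.mgrid[0:height, 0:width]
    mask = (xx - 200) ** 2 + (yy - 200) ** 2 <= radius**2
    return make_tiny_track({"critical_object": mask}, width=width, height=height)


class TestEqualize:
    def test_identical_tracks_scale_by_one(self):
        tracks = {"a": _disk_track(40), "b": _disk_track(40)}
        _, factors = equalize_roi_sizes(tracks, "critical_object")
        assert factors["a"] == pytest.approx(1.0, abs=0.01)
        assert factors["b"] == pytest.approx(1.0, abs=0.01)

    def test_areas_a_and_3a_meet_at_2a(self):
        small = _disk_track(30)
        big = _disk_track(30 * np.sqrt(3))
        a_small = small.mask_area(0, "critical_object")
        a_big = big.mask_area(0, "critical_object")
        target = (a_small + a_big) / 2
        out, _ = equalize_roi_sizes({"s": small, "b": big}, "critical_object")
        for cond in ("s", "b"):
            area = out[cond].mask_area(0, "critical_object")
            assert area == pytest.approx(target, rel=0.01)

    def test_scaling_preserves_centroid(self):
        mask = np.zeros((200, 200), bool)
        mask[60:140, 80:130] = True
        scaled = scale_mask(mask, 1.4)
        ys, xs = np.nonzero(mask)
        ys2, xs2 = np.nonzero(scaled)
        assert abs(xs2.mean() - xs.mean()) <= 0.5
        assert abs(ys2.mean() - ys.mean()) <= 0.5

    def test_zero_area_rejected(self):
        empty = make_tiny_track({}, width=30, height=30)
        with pytest.raises(ValueError, match="zero-area"):
            equalize_roi_sizes({"a": empty}, "critical_object")


def _point_recording(points, events=None):
    n = len(points)
    events = events or ["fixation"] * n
    return GazeRecording(
        t_ms=np.arange(n, dtype=float),
        x_px=[p[0] for p in points],
        y_px=[p[1] for p in points],
        events=np.array(events, dtype=object),
        sampling_rate_hz=1000.0,
    )


class TestAssign:
    @pytest.fixture()
    def overlap_track(self):
        body = np.zeros((20, 20), bool)
        body[2:18, 4:12] = True
        head = np.zeros((20, 20), bool)
        head[2:6, 5:11] = True  # inside body top
        obj = np.zeros((20, 20), bool)
        obj[10:14, 8:16] = True  # overlaps body on its right flank
        return make_tiny_track(
            {"perpetrator_body": body, "perpetrator_head": head, "critical_object": obj}
        )

    def test_critical_object_beats_body(self, overlap_track):
        stream = assign_samples(
            _point_recording([(10, 12)]), overlap_track, margin_deg=0.0
        )
        assert stream.labels[0] == "critical_object"

    def test_head_beats_body(self, overlap_track):
        stream = assign_samples(_point_recording([(8, 4)]), overlap_track, margin_deg=0.0)
        assert stream.labels[0] == "perpetrator_head"

    def test_unmatched_sample_is_other(self, overlap_track):
        stream = assign_samples(_point_recording([(1, 1)]), overlap_track, margin_deg=0.0)
        assert stream.labels[0] == OTHER_LABEL

    def test_saccade_and_missing_carry_event_and_are_excluded(self, overlap_track):
        rec = _point_recording(
            [(10, 12), (10, 12), (np.nan, np.nan)],
            events=["fixation", "saccade", "missing"],
        )
        stream = assign_samples(rec, overlap_track, margin_deg=0.0)
        assert list(stream.labels) == ["critical_object", "saccade", "missing"]
        assert list(stream.excluded) == [False, True, True]

    def test_out_of_window_samples_dropped_and_counted(self, overlap_track):
        rec = GazeRecording(
            t_ms=[0.0, 10.0, 500.0],
            x_px=[10, 10, 10],
            y_px=[12, 12, 12],
            events=np.array(["fixation"] * 3, dtype=object),
        )
        stream = assign_samples(rec, overlap_track, margin_deg=0.0)
        assert len(stream) == 2
        assert stream.n_dropped == 1

    def test_margin_monotonicity_never_moves_roi_to_other(self, overlap_track):
        rng = np.random.default_rng(3)
        pts = list(zip(rng.uniform(0, 20, 80), rng.uniform(0, 20, 80)))
        small = assign_samples(_point_recording(pts), overlap_track, margin_deg=0.1)
        large = assign_samples(_point_recording(pts), overlap_track, margin_deg=0.8)
        for ls, ll in zip(small.labels, large.labels):
            if ls != OTHER_LABEL:
                assert ll != OTHER_LABEL

    def test_priority_permutation_matches_membership_oracle(self, overlap_track):
        """Permuting priority changes labels only for samples in >= 2 dilated
        masks, and every label equals the first member of the permuted order
        (brute-force membership oracle)."""
        rng = np.random.default_rng(4)
        pts = list(zip(rng.uniform(0, 20, 60), rng.uniform(0, 20, 60)))
        rec = _point_recording(pts)
        margin = 0.3
        from gazeroi.roi_engine import dilate_roi as _dil

        memberships = []
        for x, y in pts:
            xi, yi = int(round(x)), int(round(y))
            labs = set()
            for label in ROI_LABELS:
                mask = overlap_track.mask(0, label)
                if mask.any():
                    dil = _dil(mask, margin, overlap_track.geometry)
                    if 0 <= yi < 20 and 0 <= xi < 20 and dil[yi, xi]:
                        labs.add(label)
            memberships.append(labs)

        base = assign_samples(rec, overlap_track, DEFAULT_PRIORITY, margin).labels
        for perm in itertools.permutations(
            ["critical_object", "perpetrator_head", "perpetrator_body"]
        ):
            priority = list(perm) + ["victim_head", "victim_body"]
            got = assign_samples(rec, overlap_track, priority, margin).labels
            for labs, g, b in zip(memberships, got, base):
                expected = next((l for l in priority if l in labs), OTHER_LABEL)
                assert g == expected
                if len(labs) < 2:
                    assert g == b  # only multi-membership samples may change

    def test_assignment_total_and_single_valued(self, overlap_track):
        rng = np.random.default_rng(5)
        pts = list(zip(rng.uniform(-5, 25, 100), rng.uniform(-5, 25, 100)))
        stream = assign_samples(_point_recording(pts), overlap_track)
        retained = stream.labels[~stream.excluded]
        assert all(l in set(ROI_LABELS) | {OTHER_LABEL} for l in retained)
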