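"""Generator determinism, geometry and closed-loop ground-truth recovery."""

import numpy as np
import pytest

from gazeroi.io_formats import ScreenGeometry
from gazeroi.roi_engine import assign_samples, dilate_roi
from gazeroi.synthetic_data import (
    CohortConfig,
    SessionConfig,
    default_motion_spec,
    generate_cohort,
    generate_roi_track,
    generate_session,
)
from gazeroi.timecourse import OTHER_LABEL, compute_tvt


@pytest.fixture(scope="module")
def fast_static(geometry_module=None):
    geom = ScreenGeometry()
    track, spec = generate_roi_track(
        seed=3, motion_spec=default_motion_spec(geom, moving=False), window_ms=12_000.0
    )
    return track, spec


class TestTrackGeneration:
    def test_same_seed_identical_tracks(self):
        t1, _ = generate_roi_track(seed=5, window_ms=1000.0)
        t2, _ = generate_roi_track(seed=5, window_ms=1000.0)
        assert t1.frames == t2.frames

    def test_different_seed_differs(self):
        t1, _ = generate_roi_track(seed=5, window_ms=1000.0)
        t2, _ = generate_roi_track(seed=6, window_ms=1000.0)
        assert t1.frames != t2.frames

    def test_static_spec_identical_masks_every_frame(self, fast_static):
        track, _ = fast_static
        first = track.frames[0]
        assert all(track.frames[i] == first for i in track.frame_range())

    def test_head_inside_dilated_body_region(self):
        track, _ = generate_roi_track(seed=9, window_ms=400.0)
        for i in track.frame_range():
            for person in ("perpetrator", "victim"):
                head = track.mask(i, f"{person}_head")
                body = dilate_roi(track.mask(i, f"{person}_body"), 1.5, track.geometry)
                assert (head & ~body).sum() / head.sum() < 0.35  # head rides the body top

    def test_offscreen_trajectory_rejected(self):
        geom = ScreenGeometry()
        spec = default_motion_spec(geom)
        fast = {k: type(v)(v.kind, v.center, v.size, (2000.0, 0.0)) for k, v in spec.items()}
        with pytest.raises(ValueError, match="leaves the screen"):
            generate_roi_track(seed=1, motion_spec=fast, window_ms=12_000.0)


class TestSessionGeneration:
    def test_same_seed_bit_identical(self, fast_static):
        track, spec = fast_static
        cfg = SessionConfig(seed=42, window_ms=2000.0)
        r1, t1 = generate_session(cfg, track, spec)
        r2, t2 = generate_session(cfg, track, spec)
        np.testing.assert_array_equal(r1.x_px, r2.x_px)
        np.testing.assert_array_equal(r1.events, r2.events)
        assert t1.dwell_proportions == t2.dwell_proportions

    def test_pure_critical_object_closed_loop(self, fast_static):
        track, spec = fast_static
        cfg = SessionConfig(
            seed=1,
            dwell={"critical_object": 1.0},
            noise_sd_deg=0.0,
            jitter_sd_deg=0.0,
            missing_rate=0.0,
            window_ms=3000.0,
        )
        rec, truth = generate_session(cfg, track, spec)
        stream = assign_samples(rec, track)
        assert compute_tvt(stream)["critical_object"] == pytest.approx(100.0)

    def test_60_40_schedule_recovered_within_2pct(self, fast_static):
        track, spec = fast_static
        cfg = SessionConfig(
            seed=2,
            dwell={"perpetrator_head": 0.6, "critical_object": 0.4},
            window_ms=12_000.0,
        )
        rec, truth = generate_session(cfg, track, spec)
        stream = assign_samples(rec, track)
        tvt = compute_tvt(stream)
        assert tvt["perpetrator_head"] == pytest.approx(60.0, abs=2.0)
        assert tvt["critical_object"] == pytest.approx(40.0, abs=2.0)

    def test_missing_rate_matches_configured_regime(self, fast_static):
        track, spec = fast_static
        cfg = SessionConfig(seed=3, missing_rate=0.017, window_ms=12_000.0)
        rec, _ = generate_session(cfg, track, spec)
        from gazeroi.gaze_quality import data_loss

        n = len(rec)
        se = 100 * np.sqrt(0.017 * (1 - 0.017) / n)
        assert data_loss(rec) == pytest.approx(1.7, abs=4 * se)

    def test_ground_truth_matches_pipeline_tvt(self, fast_static):
        """Core closed-loop property: manifest dwell proportions equal the
        pipeline's TVT estimates (static scene, modest noise)."""
        track, spec = fast_static
        cfg = SessionConfig(seed=4, window_ms=6000.0)
        rec, truth = generate_session(cfg, track, spec)
        tvt = compute_tvt(assign_samples(rec, track))
        for label, p in truth.dwell_proportions.items():
            assert tvt[label] == pytest.approx(100 * p, abs=1.0)

    def test_moving_track_pursuit_stays_on_target(self):
        track, spec = generate_roi_track(seed=12, window_ms=2000.0)
        cfg = SessionConfig(
            seed=5,
            dwell={"perpetrator_head": 1.0},
            noise_sd_deg=0.05,
            missing_rate=0.0,
            window_ms=2000.0,
        )
        rec, truth = generate_session(cfg, track, spec)
        tvt = compute_tvt(assign_samples(rec, track))
        assert tvt["perpetrator_head"] == pytest.approx(100.0, abs=0.5)

    def test_truth_stream_matches_scheduled_labels(self, fast_static):
        track, spec = fast_static
        cfg = SessionConfig(seed=6, window_ms=2000.0)
        _, truth = generate_session(cfg, track, spec)
        stream = truth.stream()
        assert len(stream) == 2000
        np.testing.assert_array_equal(
            stream.excluded, np.isin(truth.scheduled_labels.astype(str), ("saccade", "missing"))
        )

    def test_infeasible_dwell_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SessionConfig(seed=1, dwell={"critical_object": 0.5})


class TestCohort:
    def test_binomial_memory_accuracy_mean(self, fast_static):
        track, spec = fast_static
        base = {"critical_object": 0.2, "perpetrator_head": 0.5, OTHER_LABEL: 0.3}
        cfg = CohortConfig(
            seed=13,
            conditions={"a": base},
            n_per_condition=40,
            memory_accuracy_p=0.77,
            n_details=40,
            between_sd=0.05,
            session_kwargs={"window_ms": 1000.0, "sampling_rate_hz": 250.0},
        )
        participants, manifest = generate_cohort(cfg, track, spec)
        acc = np.array([100 * p.n_correct / (p.n_correct + p.n_incorrect) for p in participants])
        se = 100 * np.sqrt(0.77 * 0.23 / 40) / np.sqrt(40)
        assert acc.mean() == pytest.approx(77.0, abs=4 * se)
        assert len(manifest["participants"]) == 40

    def test_cohort_deterministic_given_seed(self, fast_static):
        track, spec = fast_static
        base = {"critical_object": 0.3, OTHER_LABEL: 0.7}
        cfg = CohortConfig(
            seed=14,
            conditions={"a": base},
            n_per_condition=3,
            session_kwargs={"window_ms": 500.0, "sampling_rate_hz": 250.0},
        )
        p1, m1 = generate_cohort(cfg, track, spec)
        p2, m2 = generate_cohort(cfg, track, spec)
        assert m1 == m2
        np.testing.assert_array_equal(p1[0].recording.x_px, p2[0].recording.x_px)

    def test_manifest_truth_matches_drawn_share(self, fast_static):
        track, spec = fast_static
        base = {"critical_object": 0.25, OTHER_LABEL: 0.75}
        cfg = CohortConfig(
            seed=15,
            conditions={"a": base},
            n_per_condition=5,
            between_sd=0.05,
            session_kwargs={"window_ms": 12_000.0},
        )
        _, manifest = generate_cohort(cfg, track, spec)
        # proportional allocation tracks the target within about one long
        # fixation (~600 ms) over the ~11.4 s of retained fixation time
        for rec in manifest["participants"].values():
            drawn = rec["target_share_drawn"]
            realized = rec["dwell_proportions"]["critical_object"]
            assert realized == pytest.approx(drawn, abs=600.0 / 11_400.0)
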