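"""Synthetic gaze recordings, ROI tracks and memory tallies with known truth.

The generator emulates the recording conditions of the staged-robbery study:
a 1920x1080 scene at 25 fps watched for a 12-s analysis window while gaze is
sampled at 1000 Hz, with alternating fixation/saccade episodes, positional
noise, occasional missing samples, and fixations that track the centroid of
a (possibly moving) target ROI — the smooth-pursuit regime that motivates
sample-based ROI matching.

Dwell behaviour is controlled by a per-label dwell-probability vector.  By
default fixations are allocated to targets by a deterministic
largest-deficit rule, so the realized share of retained samples per label
tracks the configured share to within about one fixation duration; a
stochastic per-fixation multinomial mode is also available.  Each session
returns a ground-truth manifest (the scheduled label of every sample and the
realized retained-sample dwell proportions), which is what closed-loop tests
compare pipeline output against.

Every public entry point is deterministic given its seed; sub-streams
(scheduling, placement noise, missingness, tallies) are derived from the
session seed by fixed offsets so components can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .io_formats import (
    ROI_LABELS,
    GazeRecording,
    RoiTrack,
    ScreenGeometry,
    DEFAULT_GEOMETRY,
    rle_encode,
)
from .timecourse import OTHER_LABEL, AssignedStream

__all__ = [
    "MotionSpec",
    "SessionConfig",
    "CohortConfig",
    "SessionTruth",
    "default_motion_spec",
    "generate_roi_track",
    "generate_session",
    "generate_cohort",
]

# fixed offsets deriving per-component RNG sub-streams from a session seed
_SUB_SCHEDULE, _SUB_NOISE, _SUB_MISSING, _SUB_TALLY = 0, 1, 2, 3


def _rng(seed: int, sub: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), sub])


@dataclass(frozen=True)
class MotionSpec:
    """One ROI as a translating shape: rectangle or ellipse, px and px/s."""

    kind: str  # "rect" | "ellipse"
    center: tuple[float, float]  # at window start
    size: tuple[float, float]  # full width, full height
    velocity: tuple[float, float] = (0.0, 0.0)

    def center_at(self, t_ms: float) -> tuple[float, float]:
        return (
            self.center[0] + self.velocity[0] * t_ms / 1000.0,
            self.center[1] + self.velocity[1] * t_ms / 1000.0,
        )


def default_motion_spec(
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    moving: bool = True,
) -> dict[str, MotionSpec]:
    """Plausible scene layout: two standing people and a hand-held object.

    The perpetrator (with the critical object near her hand) drifts slowly
    across the scene; the victim is seated and nearly static.  Heads sit
    inside the top of the body regions.  Sizes scale with the frame.
    """
    w, h = geometry.width_px, geometry.height_px
    drift = (0.012 * w, 0.0) if moving else (0.0, 0.0)
    sway = (-0.004 * w, 0.0) if moving else (0.0, 0.0)
    body_w, body_h = 0.10 * w, 0.55 * h
    head_w, head_h = 0.055 * w, 0.10 * h
    return {
        "perpetrator_body": MotionSpec("rect", (0.32 * w, 0.55 * h), (body_w, body_h), drift),
        "perpetrator_head": MotionSpec(
            "ellipse", (0.32 * w, 0.32 * h), (head_w, head_h), drift
        ),
        "victim_body": MotionSpec("rect", (0.68 * w, 0.60 * h), (body_w, 0.45 * h), sway),
        "victim_head": MotionSpec("ellipse", (0.68 * w, 0.42 * h), (head_w, head_h), sway),
        "critical_object": MotionSpec(
            "ellipse", (0.40 * w, 0.62 * h), (0.045 * w, 0.08 * h), drift
        ),
    }


def _rasterize(spec: MotionSpec, t_ms: float, shape: tuple[int, int]) -> np.ndarray:
    cx, cy = spec.center_at(t_ms)
    hw, hh = spec.size[0] / 2.0, spec.size[1] / 2.0
    mask = np.zeros(shape, dtype=bool)
    r0 = max(int(np.ceil(cy - hh)), 0)
    r1 = min(int(np.floor(cy + hh)) + 1, shape[0])
    c0 = max(int(np.ceil(cx - hw)), 0)
    c1 = min(int(np.floor(cx + hw)) + 1, shape[1])
    if r1 <= r0 or c1 <= c0:
        return mask
    if spec.kind == "rect":
        mask[r0:r1, c0:c1] = True
    elif spec.kind == "ellipse":
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] = ((xx - cx) / hw) ** 2 + ((yy - cy) / hh) ** 2 <= 1.0
    else:
        raise ValueError(f"unknown shape kind {spec.kind!r}")
    return mask


def generate_roi_track(
    seed: int,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    motion_spec: Mapping[str, MotionSpec] | None = None,
    window_ms: float = 12_000.0,
    jitter: float = 0.02,
) -> tuple[RoiTrack, dict[str, MotionSpec]]:
    """Build a dynamic ROI track from translating shapes; deterministic per seed.

    The seed perturbs the default layout's positions (by up to ``jitter`` of
    the frame) and velocities (+-20%), so different seeds give different but
    valid scenes.  Raises if any trajectory leaves the screen during the
    window.  Returns the track and the resolved motion spec (the generator's
    ground truth for centroid positions).
    """
    rng = _rng(seed, _SUB_SCHEDULE)
    base = dict(motion_spec) if motion_spec is not None else default_motion_spec(geometry)
    resolved: dict[str, MotionSpec] = {}
    w, h = geometry.width_px, geometry.height_px
    for label, spec in base.items():
        if motion_spec is None:
            dx = rng.uniform(-jitter, jitter) * w
            dy = rng.uniform(-jitter, jitter) * h
            vf = rng.uniform(0.8, 1.2)
            # heads ride on their body's perturbation so containment survives
            if label.endswith("_head"):
                body = resolved[label.replace("_head", "_body")]
                bbase = base[label.replace("_head", "_body")]
                dx = body.center[0] - bbase.center[0]
                dy = body.center[1] - bbase.center[1]
                spec = replace(spec, velocity=body.velocity)
                vf = 1.0
            spec = replace(
                spec,
                center=(spec.center[0] + dx, spec.center[1] + dy),
                velocity=(spec.velocity[0] * vf, spec.velocity[1] * vf),
            )
        resolved[label] = spec
    # validate trajectories stay on-screen across the window
    for label, spec in resolved.items():
        for t in (0.0, window_ms):
            cx, cy = spec.center_at(t)
            if not (0 <= cx - spec.size[0] / 2 and cx + spec.size[0] / 2 <= w
                    and 0 <= cy - spec.size[1] / 2 and cy + spec.size[1] / 2 <= h):
                raise ValueError(
                    f"{label}: trajectory leaves the screen at t={t} ms (centre {cx:.0f},{cy:.0f})"
                )
    fps = geometry.frame_rate_hz
    n_frames = int(np.ceil(window_ms * fps / 1000.0))
    shape = (geometry.height_px, geometry.width_px)
    static = all(s.velocity == (0.0, 0.0) for s in resolved.values())
    frames: dict[int, dict[str, str]] = {}
    first: dict[str, str] = {}
    for i in range(n_frames):
        if static and i > 0:
            frames[i] = first
            continue
        t_frame = i * 1000.0 / fps
        frames[i] = {
            label: rle_encode(_rasterize(spec, t_frame, shape))
            for label, spec in resolved.items()
        }
        if i == 0:
            first = frames[0]
    track = RoiTrack(geometry=geometry, window=(0.0, float(window_ms)), frames=frames)
    return track, resolved


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic recording session.

    ``dwell`` maps labels (ROI vocabulary plus ``"other"``) to target shares
    of retained viewing time; it must sum to 1.  Fixation durations are
    lognormal on the millisecond scale (defaults exp(5.5) ~ 245 ms median,
    a conventional scene-viewing shape); saccades have fixed duration.
    ``noise_sd_deg`` is the per-fixation placement error around the target
    centroid and ``jitter_sd_deg`` the per-sample tremor (the default gives
    an RMS sample-to-sample precision of about 0.019 deg, the regime of a
    tower-mounted research tracker).
    """

    seed: int
    dwell: Mapping[str, float] = field(
        default_factory=lambda: {
            "perpetrator_head": 0.40,
            "perpetrator_body": 0.10,
            "critical_object": 0.11,
            "victim_head": 0.08,
            "victim_body": 0.11,
            OTHER_LABEL: 0.20,
        }
    )
    window_ms: float = 12_000.0
    sampling_rate_hz: float = 1000.0
    schedule_mode: str = "proportional"  # or "multinomial"
    fixation_log_mu: float = 5.5
    fixation_log_sigma: float = 0.35
    min_fixation_ms: float = 60.0
    saccade_ms: float = 30.0
    noise_sd_deg: float = 0.1
    jitter_sd_deg: float = 0.0096
    missing_rate: float = 0.017
    eye: str = "left"
    validation_error_deg: float = 0.32

    def __post_init__(self) -> None:
        total = sum(self.dwell.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dwell probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.dwell.values()):
            raise ValueError("dwell probabilities must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.schedule_mode not in ("proportional", "multinomial"):
            raise ValueError(f"unknown schedule_mode {self.schedule_mode!r}")
        if self.min_fixation_ms * self.sampling_rate_hz / 1000.0 < 1:
            raise ValueError("minimum fixation shorter than one sample: infeasible schedule")


@dataclass
class SessionTruth:
    """Ground truth of a generated session.

    ``scheduled_labels`` gives every sample's intended label (ROI label or
    ``other`` for fixation samples; ``saccade``/``missing`` otherwise);
    ``dwell_proportions`` are the realized shares of retained samples per
    label — the quantity pipeline TVTs should recover.
    """

    scheduled_labels: np.ndarray
    dwell_proportions: dict[str, float]
    window: tuple[float, float]
    t_ms: np.ndarray

    def stream(self, vocabulary: tuple[str, ...] = ROI_LABELS) -> AssignedStream:
        """The truth as an AssignedStream (bypasses mask-based assignment)."""
        excluded = np.isin(self.scheduled_labels.astype(str), ("saccade", "missing"))
        return AssignedStream(
            t_ms=self.t_ms,
            labels=self.scheduled_labels,
            excluded=excluded,
            window=self.window,
            vocabulary=vocabulary,
        )


def _other_anchor(track: RoiTrack, margin_px: float = 60.0) -> tuple[float, float]:
    """A point far from every ROI across the whole track (for 'other' dwell).

    The result is memoized on the track instance: it is a property of the
    track alone and the distance transform over an HD frame is not free.
    """
    cached = getattr(track, "_other_anchor_cache", None)
    if cached is not None:
        return cached
    shape = (track.geometry.height_px, track.geometry.width_px)
    union = np.zeros(shape, dtype=bool)
    seen: set[str] = set()
    for i in track.frame_range():
        for label in track.frames[i]:
            rle = track.frames[i][label]
            if rle not in seen:
                seen.add(rle)
                union |= track.mask(i, label)
    dist = ndimage.distance_transform_edt(~union)
    r, c = np.unravel_index(np.argmax(dist), shape)
    if dist[r, c] < margin_px:
        raise ValueError("no screen region sufficiently far from all ROIs for 'other' dwell")
    anchor = (float(c), float(r))
    track._other_anchor_cache = anchor
    return anchor


def _centroids(track: RoiTrack, spec: Mapping[str, MotionSpec] | None):
    """centroids(label, frames) -> (x[], y[]), analytic when the spec is known."""
    cache: dict[str, tuple[float, float]] = {}
    fps = track.geometry.frame_rate_hz

    def mask_centroid(label: str, frame: int) -> tuple[float, float]:
        key = track.frames[frame][label]
        if key not in cache:
            m = track.mask(frame, label)
            ys, xs = np.nonzero(m)
            if len(xs) == 0:
                raise ValueError(f"label {label!r} empty at frame {frame}")
            cache[key] = (float(xs.mean()), float(ys.mean()))
        return cache[key]

    def centroids(label: str, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if spec is not None and label in spec:
            s = spec[label]
            t = frames * 1000.0 / fps
            return (
                s.center[0] + s.velocity[0] * t / 1000.0,
                s.center[1] + s.velocity[1] * t / 1000.0,
            )
        uniq, inv = np.unique(frames, return_inverse=True)
        pts = np.array([mask_centroid(label, int(f)) for f in uniq])
        return pts[inv, 0], pts[inv, 1]

    return centroids


def generate_session(
    config: SessionConfig,
    track: RoiTrack,
    motion_spec: Mapping[str, MotionSpec] | None = None,
) -> tuple[GazeRecording, SessionTruth]:
    """Simulate one participant's gaze stream over a ROI track.

    Fixations are placed on the scheduled label's centroid (tracking it
    across frames, emulating smooth pursuit of moving ROIs) plus Gaussian
    placement noise; saccade samples interpolate between fixations and are
    labelled ``saccade``; missing samples are injected i.i.d. at
    ``missing_rate`` with NaN coordinates.
    """
    geom = track.geometry
    rng_sched = _rng(config.seed, _SUB_SCHEDULE)
    rng_noise = _rng(config.seed, _SUB_NOISE)
    rng_miss = _rng(config.seed, _SUB_MISSING)

    labels = [l for l in config.dwell if config.dwell[l] > 0]
    probs = np.array([config.dwell[l] for l in labels])
    probs = probs / probs.sum()

    n_samples = int(round(config.window_ms * config.sampling_rate_hz / 1000.0))
    dt = 1000.0 / config.sampling_rate_hz
    t_ms = np.arange(n_samples) * dt

    # --- segment schedule: fixation / saccade alternation ---------------
    segments: list[tuple[float, float, str]] = []  # (start, end, kind)
    t = 0.0
    while t < config.window_ms - 1e-9:
        dur = float(
            np.clip(
                rng_sched.lognormal(config.fixation_log_mu, config.fixation_log_sigma),
                config.min_fixation_ms,
                None,
            )
        )
        dur = min(dur, config.window_ms - t)
        segments.append((t, t + dur, "fixation"))
        t += dur
        if t >= config.window_ms - 1e-9:
            break
        sac = min(config.saccade_ms, config.window_ms - t)
        segments.append((t, t + sac, "saccade"))
        t += sac

    # --- allocate fixations to target labels ----------------------------
    fix_segments = [s for s in segments if s[2] == "fixation"]
    targets: list[str] = []
    if config.schedule_mode == "multinomial":
        targets = list(rng_sched.choice(labels, size=len(fix_segments), p=probs))
    else:  # proportional: greedy largest-deficit allocation
        alloc = {l: 0.0 for l in labels}
        total = 0.0
        for start, end, _ in fix_segments:
            dur = end - start
            deficits = {l: probs[i] * (total + dur) - alloc[l] for i, l in enumerate(labels)}
            choice = max(deficits, key=lambda l: (deficits[l], l))
            targets.append(choice)
            alloc[choice] += dur
            total += dur

    anchor = None
    centroid = _centroids(track, motion_spec)
    fps = geom.frame_rate_hz

    x = np.empty(n_samples)
    y = np.empty(n_samples)
    events = np.empty(n_samples, dtype=object)
    scheduled = np.empty(n_samples, dtype=object)

    sample_frames = np.floor(t_ms * fps / 1000.0).astype(int)
    last_frame = max(track.frames)
    np.clip(sample_frames, min(track.frames), last_frame, out=sample_frames)

    sd_x = config.noise_sd_deg * geom.px_per_deg_x
    sd_y = config.noise_sd_deg * geom.px_per_deg_y
    jit_x = config.jitter_sd_deg * geom.px_per_deg_x
    jit_y = config.jitter_sd_deg * geom.px_per_deg_y

    fix_i = 0
    seg_bounds = []
    for start, end, kind in segments:
        i0 = int(np.ceil(start / dt - 1e-9))
        i1 = min(int(np.ceil(end / dt - 1e-9)), n_samples)
        seg_bounds.append((i0, i1, kind))

    # fixation positions first (saccades interpolate between them)
    seg_pos: list[tuple[np.ndarray, np.ndarray] | None] = [None] * len(segments)
    for si, ((start, end, kind), (i0, i1, _)) in enumerate(zip(segments, seg_bounds)):
        if kind != "fixation" or i1 <= i0:
            if kind == "fixation":
                fix_i += 1
            continue
        label = targets[fix_i]
        fix_i += 1
        idx = np.arange(i0, i1)
        if label == OTHER_LABEL:
            if anchor is None:
                anchor = _other_anchor(track)
            cx = np.full(len(idx), anchor[0])
            cy = np.full(len(idx), anchor[1])
        else:
            cx, cy = centroid(label, sample_frames[idx])
        ox = rng_noise.normal(0.0, sd_x)
        oy = rng_noise.normal(0.0, sd_y)
        px = cx + ox + rng_noise.normal(0.0, jit_x, len(idx))
        py = cy + oy + rng_noise.normal(0.0, jit_y, len(idx))
        x[idx], y[idx] = px, py
        events[idx] = "fixation"
        scheduled[idx] = label
        seg_pos[si] = (px, py)

    for si, ((start, end, kind), (i0, i1, _)) in enumerate(zip(segments, seg_bounds)):
        if kind != "saccade" or i1 <= i0:
            continue
        prev_xy = next(
            (seg_pos[j] for j in range(si - 1, -1, -1) if seg_pos[j] is not None), None
        )
        next_xy = next(
            (seg_pos[j] for j in range(si + 1, len(segments)) if seg_pos[j] is not None), None
        )
        p0 = (prev_xy[0][-1], prev_xy[1][-1]) if prev_xy else (next_xy[0][0], next_xy[1][0])
        p1 = (next_xy[0][0], next_xy[1][0]) if next_xy else p0
        frac = (np.arange(i0, i1) - i0 + 1) / (i1 - i0 + 1)
        x[i0:i1] = p0[0] + frac * (p1[0] - p0[0])
        y[i0:i1] = p0[1] + frac * (p1[1] - p0[1])
        events[i0:i1] = "saccade"
        scheduled[i0:i1] = "saccade"

    missing = rng_miss.random(n_samples) < config.missing_rate
    x[missing] = np.nan
    y[missing] = np.nan
    events[missing] = "missing"
    scheduled[missing] = "missing"

    recording = GazeRecording(
        t_ms=t_ms,
        x_px=x,
        y_px=y,
        events=events,
        sampling_rate_hz=config.sampling_rate_hz,
        eye=config.eye,
        validation_error_deg=config.validation_error_deg,
    )
    retained = events == "fixation"
    n_ret = int(retained.sum())
    dwell = {
        lab: float(np.count_nonzero(scheduled[retained] == lab)) / n_ret
        for lab in list(ROI_LABELS) + [OTHER_LABEL]
    }
    truth = SessionTruth(
        scheduled_labels=scheduled,
        dwell_proportions=dwell,
        window=(0.0, float(config.window_ms)),
        t_ms=t_ms,
    )
    return recording, truth


@dataclass(frozen=True)
class CohortConfig:
    """A cohort: per-condition mean dwell vectors plus memory parameters.

    ``conditions`` maps condition name -> mean dwell vector.  Individual
    participants vary around the condition mean on ``target_label`` with SD
    ``between_sd`` (other labels are rescaled to keep the vector a
    distribution).  Memory tallies are binomial draws of ``n_details``
    details at the condition's accuracy probability.
    """

    seed: int
    conditions: Mapping[str, Mapping[str, float]]
    n_per_condition: int = 54
    target_label: str = "critical_object"
    between_sd: float = 0.08
    memory_accuracy_p: float | Mapping[str, float] = 0.77
    n_details: int = 40
    session_kwargs: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ValueError("need at least 2 participants per condition")


@dataclass
class CohortParticipant:
    participant: str
    condition: str
    recording: GazeRecording
    truth: SessionTruth
    n_correct: int
    n_incorrect: int


def _participant_dwell(
    base: Mapping[str, float], target: str, share: float
) -> dict[str, float]:
    base = dict(base)
    p0 = base[target]
    rest = 1.0 - p0
    share = float(np.clip(share, 0.01, 0.95))
    out = {}
    for lab, p in base.items():
        out[lab] = share if lab == target else p * (1.0 - share) / rest
    return out


def generate_cohort(
    config: CohortConfig,
    track: RoiTrack,
    motion_spec: Mapping[str, MotionSpec] | None = None,
) -> tuple[list[CohortParticipant], dict]:
    """Generate independent sessions and memory tallies for a whole cohort.

    Returns the participants and a ground-truth manifest: per participant,
    the drawn dwell share on the target label, the realized retained-sample
    dwell proportions, the memory parameters and the derived session seed.
    """
    rng = _rng(config.seed, _SUB_TALLY)
    participants: list[CohortParticipant] = []
    manifest: dict = {"seed": config.seed, "participants": {}}
    k = 0
    for cond, base_dwell in config.conditions.items():
        acc_p = (
            config.memory_accuracy_p[cond]
            if isinstance(config.memory_accuracy_p, Mapping)
            else config.memory_accuracy_p
        )
        for j in range(config.n_per_condition):
            pid = f"{cond}_{j:03d}"
            share = rng.normal(base_dwell[config.target_label], config.between_sd)
            dwell = _participant_dwell(base_dwell, config.target_label, share)
            session_seed = (config.seed * 1_000_003 + k) % (2**31)
            k += 1
            scfg = SessionConfig(seed=session_seed, dwell=dwell, **dict(config.session_kwargs))
            recording, truth = generate_session(scfg, track, motion_spec)
            n_correct = int(rng.binomial(config.n_details, acc_p))
            participants.append(
                CohortParticipant(
                    participant=pid,
                    condition=cond,
                    recording=recording,
                    truth=truth,
                    n_correct=n_correct,
                    n_incorrect=config.n_details - n_correct,
                )
            )
            manifest["participants"][pid] = {
                "condition": cond,
                "target_share_drawn": float(dwell[config.target_label]),
                "dwell_proportions": truth.dwell_proportions,
                "memory_accuracy_p": acc_p,
                "session_seed": session_seed,
            }
    return participants, manifest
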