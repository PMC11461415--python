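"""Dynamic-ROI construction, transformation and per-sample gaze assignment.

The scene vocabulary is fixed (critical object, perpetrator head/body,
victim head/body).  ROIs arrive as per-frame binary masks; this module

* converts degrees of visual angle to pixels per screen axis,
* dilates masks by a safety margin (default 0.5 deg per axis) to absorb
  eye-tracker inaccuracy,
* derives head ellipses from whole-body masks by image moments of the top
  region of the mask's vertical extent,
* equalizes the time-averaged size of a label's masks across experimental
  conditions, and
* assigns each gaze sample to exactly one label by priority order
  (critical object first, then heads before bodies), sample-by-sample rather
  than per fixation so that smooth-pursuit episodes stay inside moving ROIs.

Dilation with an elliptical structuring element is computed as a thresholded
anisotropically weighted Euclidean distance transform restricted to the
mask's padded bounding box; this is pixel-for-pixel identical to classical
morphological dilation with the discrete elliptical kernel and much cheaper
on HD frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import ROI_LABELS, GazeRecording, RoiTrack, ScreenGeometry
from .timecourse import OTHER_LABEL, AssignedStream

__all__ = [
    "DEFAULT_PRIORITY",
    "EllipseSpec",
    "deg_to_px",
    "elliptical_kernel",
    "dilate_roi",
    "fit_head_ellipse",
    "ellipse_mask",
    "scale_mask",
    "equalize_roi_sizes",
    "assign_samples",
]

#: Label priority for overlap resolution: critical object beats people;
#: within a person the head beats the body.  Unmatched samples -> "other".
DEFAULT_PRIORITY: tuple[str, ...] = ROI_LABELS

# process-wide dilation memo (see assign_samples); bounded to ~2000 entries
_DILATION_MEMO: dict = {}
_DILATION_MEMO_MAX = 2000


def deg_to_px(d: float, geometry: ScreenGeometry, axis: str = "horizontal") -> float:
    """Convert a visual angle to pixels along one screen axis (linear scaling)."""
    if d < 0:
        raise ValueError(f"visual angle must be non-negative, got {d}")
    if axis in ("horizontal", "x"):
        return d * geometry.px_per_deg_x
    if axis in ("vertical", "y"):
        return d * geometry.px_per_deg_y
    raise ValueError(f"axis must be horizontal or vertical, got {axis!r}")


def elliptical_kernel(rx: float, ry: float) -> np.ndarray:
    """Discrete elliptical structuring element {(dx,dy): (dx/rx)^2+(dy/ry)^2 <= 1}.

    Degenerate radii (< half a pixel) collapse that axis to the centre row or
    column.
    """
    hx, hy = int(np.floor(rx)), int(np.floor(ry))
    dy, dx = np.mgrid[-hy : hy + 1, -hx : hx + 1]
    fx = dx / rx if rx > 0 else np.where(dx == 0, 0.0, np.inf)
    fy = dy / ry if ry > 0 else np.where(dy == 0, 0.0, np.inf)
    return fx**2 + fy**2 <= 1.0 + 1e-12


def dilate_roi(mask: np.ndarray, margin_deg: float, geometry: ScreenGeometry) -> np.ndarray:
    """Dilate a binary mask by an elliptical margin given in degrees.

    The margin is converted to per-axis pixel radii, so it is exactly
    ``margin_deg`` in visual angle along both axes even though the pixel grid
    is anisotropic.  The result always contains the input and is clipped to
    the frame.  An empty mask is returned unchanged with a warning.
    """
    if margin_deg < 0:
        raise ValueError(f"margin_deg must be non-negative, got {margin_deg}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("dilate_roi: empty mask", stacklevel=2)
        return mask.copy()
    rx = deg_to_px(margin_deg, geometry, "horizontal")
    ry = deg_to_px(margin_deg, geometry, "vertical")
    if rx < 1.0 and ry < 1.0:
        return mask.copy()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    pr, pc = int(np.floor(ry)) + 1, int(np.floor(rx)) + 1
    r0, r1 = max(rows[0] - pr, 0), min(rows[-1] + pr + 1, mask.shape[0])
    c0, c1 = max(cols[0] - pc, 0), min(cols[-1] + pc + 1, mask.shape[1])
    crop = mask[r0:r1, c0:c1]
    # weighted distance from each background pixel to the nearest mask pixel;
    # sampling (1/ry, 1/rx) makes the unit ball the elliptical kernel
    sy = 1.0 / ry if ry > 0 else np.inf
    sx = 1.0 / rx if rx > 0 else np.inf
    dist = ndimage.distance_transform_edt(~crop, sampling=(sy, sx))
    out = mask.copy()
    out[r0:r1, c0:c1] |= dist <= 1.0 + 1e-9
    return out


@dataclass(frozen=True)
class EllipseSpec:
    """An ellipse in pixel coordinates: centre (x, y), semi-axes, rotation (rad)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        a, b = self.semi_axes
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = (np.asarray(x, float) - cx) * c + (np.asarray(y, float) - cy) * s
        v = -(np.asarray(x, float) - cx) * s + (np.asarray(y, float) - cy) * c
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ellipse_mask(spec: EllipseSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ellipse onto a frame of the given (height, width)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return spec.contains(xx, yy)


def fit_head_ellipse(body_mask: np.ndarray, top_fraction: float = 0.15) -> EllipseSpec:
    """Fit an ellipse to the top region of a body mask by image moments.

    The top ``top_fraction`` of the mask's vertical extent is selected; the
    ellipse takes the region's centroid and second-moment orientation, with
    axes scaled so the ellipse area equals the region's pixel area.  The
    moment covariance carries a 1/12 pixel-extent correction so single-pixel
    rows do not degenerate.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("body mask is empty")
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    rows = np.flatnonzero(body_mask.any(axis=1))
    extent = rows[-1] - rows[0] + 1
    cut = rows[0] + int(np.ceil(top_fraction * extent))
    region = body_mask.copy()
    region[cut:, :] = False
    ys, xs = np.nonzero(region)
    if len(xs) < 5:
        raise ValueError(f"selected top region has {len(xs)} px (< 5): degenerate region")
    pts = np.column_stack([xs, ys]).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    # for a filled ellipse the coordinate variances are (semi-axis)^2 / 4
    axes = 2.0 * np.sqrt(evals)
    area = float(len(xs))
    scale = np.sqrt(area / (np.pi * axes[0] * axes[1]))
    axes *= scale
    major = evecs[:, 1]  # eigh sorts ascending
    rotation = float(np.arctan2(major[1], major[0]))
    # report (major, minor) with rotation of the major axis, normalized to (-pi/2, pi/2]
    if rotation <= -np.pi / 2:
        rotation += np.pi
    elif rotation > np.pi / 2:
        rotation -= np.pi
    return EllipseSpec(
        center=(float(centroid[0]), float(centroid[1])),
        semi_axes=(float(axes[1]), float(axes[0])),
        rotation=rotation,
    )


def scale_mask(mask: np.ndarray, factor: float, center: tuple[float, float] | None = None) -> np.ndarray:
    """Scale a binary mask isotropically about a centre (default its centroid).

    Uses inverse nearest-neighbour mapping, so the realized area tracks
    ``factor**2`` up to boundary discretization.
    """
    mask = np.asarray(mask, dtype=bool)
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    if not mask.any():
        return mask.copy()
    if center is None:
        ys, xs = np.nonzero(mask)
        center = (float(xs.mean()), float(ys.mean()))
    cx, cy = center
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    src_x = np.rint(cx + (xx - cx) / factor).astype(int)
    src_y = np.rint(cy + (yy - cy) / factor).astype(int)
    valid = (src_x >= 0) & (src_x < mask.shape[1]) & (src_y >= 0) & (src_y < mask.shape[0])
    out = np.zeros_like(mask)
    out[valid] = mask[src_y[valid], src_x[valid]]
    return out


def _mean_area(track: RoiTrack, label: str) -> float:
    areas = [float(track.mask_area(i, label)) for i in track.frame_range()]
    return float(np.mean(areas))


def equalize_roi_sizes(
    tracks: Mapping[str, RoiTrack],
    label: str,
    tol: float = 0.01,
    max_iter: int = 12,
) -> tuple[dict[str, RoiTrack], dict[str, float]]:
    """Equalize one label's time-averaged mask area across conditions.

    Each condition's masks are rescaled isotropically about their per-frame
    centroids by a single condition-constant factor so that the time-averaged
    area matches the grand mean of the conditions' averages within ``tol``
    (relative).  Returns the adjusted tracks and the factors used.
    """
    for cond, track in tracks.items():
        for i in track.frame_range():
            if label not in track.frames[i]:
                raise ValueError(f"condition {cond!r}: frame {i} lacks label {label!r}")
    avg = {cond: _mean_area(track, label) for cond, track in tracks.items()}
    if min(avg.values()) <= 0:
        raise ValueError("zero-area time-averaged mask: cannot equalize")
    target = float(np.mean(list(avg.values())))

    from .io_formats import rle_encode as _enc

    out_tracks: dict[str, RoiTrack] = {}
    factors: dict[str, float] = {}
    for cond, track in tracks.items():
        f = float(np.sqrt(target / avg[cond]))
        for _ in range(max_iter):
            # identical encoded frames are scaled once
            by_rle: dict[str, str] = {}
            areas = []
            for i in track.frame_range():
                rle = track.frames[i][label]
                if rle not in by_rle:
                    by_rle[rle] = _enc(scale_mask(track.mask(i, label), f))
                areas.append(sum(int(r.split(":")[1]) for r in by_rle[rle].split()) if by_rle[rle] else 0)
            realized = float(np.mean(areas))
            if realized > 0 and abs(realized - target) / target <= tol * 0.5:
                break
            if realized <= 0:
                raise ValueError(f"condition {cond!r}: scaling by {f} emptied the mask")
            f *= float(np.sqrt(target / realized))
        new_frames = {
            i: {**track.frames[i], label: by_rle[track.frames[i][label]]}
            for i in track.frame_range()
        }
        out_tracks[cond] = RoiTrack(
            geometry=track.geometry,
            window=track.window,
            frames=new_frames,
            labels=track.labels,
        )
        factors[cond] = f
    return out_tracks, factors


def _validate_priority(priority: Sequence[str], track: RoiTrack) -> tuple[str, ...]:
    priority = tuple(priority)
    if len(set(priority)) != len(priority):
        raise ValueError("priority labels must be unique")
    missing = set(track.labels) - set(priority)
    if missing:
        raise ValueError(f"priority order does not cover track labels: {sorted(missing)}")
    return priority


def assign_samples(
    recording: GazeRecording,
    track: RoiTrack,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    margin_deg: float = 0.5,
) -> AssignedStream:
    """Assign every in-window gaze sample to exactly one ROI label.

    Fixation samples get the first label in ``priority`` whose margin-dilated
    mask (of the frame holding the sample time) contains the sample, else
    ``"other"``; saccade and missing samples carry their event label and are
    flagged excluded.  Samples outside the track window are dropped and
    counted in ``n_dropped``.
    """
    priority = _validate_priority(priority, track)
    start, end = track.window
    t = recording.t_ms
    in_window = (t >= start) & (t < end)
    n_dropped = int(len(t) - in_window.sum())
    if in_window.sum() == 0:
        raise ValueError("recording does not overlap the track window")
    t_in = t[in_window]
    x_in = recording.x_px[in_window]
    y_in = recording.y_px[in_window]
    ev_in = recording.events[in_window]

    labels = np.empty(len(t_in), dtype=object)
    excluded = np.zeros(len(t_in), dtype=bool)
    is_fix = ev_in == "fixation"
    excluded[~is_fix] = True
    labels[~is_fix] = ev_in[~is_fix]

    geom = track.geometry
    frames_of = np.floor(t_in * geom.frame_rate_hz / 1000.0).astype(int)
    frame_ids = sorted(set(frames_of[is_fix]))
    last_frame = max(track.frames)
    first_frame = min(track.frames)

    # memo keyed by (RLE encoding, margin, geometry): frames sharing masks
    # dilate once, and repeated runs over the same track pay nothing
    def dilated_crop(frame: int, label: str):
        if label not in track.frames[frame]:
            return None
        key = (track.frames[frame][label], margin_deg, geom)
        if key not in _DILATION_MEMO:
            if track.mask_area(frame, label) == 0:
                _DILATION_MEMO[key] = None
            else:
                dil = dilate_roi(track.mask(frame, label), margin_deg, geom)
                rows = np.flatnonzero(dil.any(axis=1))
                cols = np.flatnonzero(dil.any(axis=0))
                crop = dil[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
                if len(_DILATION_MEMO) >= _DILATION_MEMO_MAX:
                    _DILATION_MEMO.clear()
                _DILATION_MEMO[key] = (crop, int(rows[0]), int(cols[0]))
        return _DILATION_MEMO[key]

    for frame in frame_ids:
        frame_clamped = min(max(frame, first_frame), last_frame)
        sel = np.flatnonzero(is_fix & (frames_of == frame))
        xi = np.rint(x_in[sel]).astype(float)
        yi = np.rint(y_in[sel]).astype(float)
        frame_labels = np.full(len(sel), OTHER_LABEL, dtype=object)
        unassigned = np.ones(len(sel), dtype=bool)
        for label in priority:
            if not unassigned.any():
                break
            entry = dilated_crop(frame_clamped, label)
            if entry is None:
                continue
            crop, r0, c0 = entry
            rr = yi - r0
            cc = xi - c0
            inside_bbox = (
                unassigned
                & np.isfinite(rr)
                & np.isfinite(cc)
                & (rr >= 0)
                & (rr < crop.shape[0])
                & (cc >= 0)
                & (cc < crop.shape[1])
            )
            idx = np.flatnonzero(inside_bbox)
            if len(idx) == 0:
                continue
            hit = crop[rr[idx].astype(int), cc[idx].astype(int)]
            frame_labels[idx[hit]] = label
            unassigned[idx[hit]] = False
        labels[sel] = frame_labels

    return AssignedStream(
        t_ms=t_in,
        labels=labels,
        excluded=excluded,
        window=(float(start), float(end)),
        vocabulary=track.labels,
        n_dropped=n_dropped,
    )
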