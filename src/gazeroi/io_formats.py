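"""File dialects and in-memory containers for gaze streams and dynamic ROI tracks.

Three formats are defined here and consumed by the rest of the package:

* **Gaze samples** — tab-separated text with one row per sample (time in ms,
  x/y in pixels, an event label), with configurable column names and a map
  from vendor event strings onto the three-label vocabulary
  ``fixation / saccade / missing``.
* **ROI tracks** — a single streamable text file: a JSON header line holding
  the screen geometry, analysis window and label vocabulary, followed by one
  line per (frame, label) carrying a run-length-encoded binary mask.
* **Results tables** — plain CSV written at full precision.

Coordinates are 0-based pixel centres, origin at the top-left corner, y
increasing downward.  Timestamps are milliseconds relative to the start of
the analysis window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROI_LABELS",
    "EVENT_LABELS",
    "ScreenGeometry",
    "DEFAULT_GEOMETRY",
    "GazeRecording",
    "RoiTrack",
    "GazeDialect",
    "FormatError",
    "IntegrityError",
    "rle_encode",
    "rle_decode",
    "read_gaze_samples",
    "write_gaze_samples",
    "read_roi_track",
    "write_roi_track",
    "write_results_table",
    "read_results_table",
]

#: Fixed ROI vocabulary of the staged-robbery scene.
ROI_LABELS = (
    "critical_object",
    "perpetrator_head",
    "perpetrator_body",
    "victim_head",
    "victim_body",
)

EVENT_LABELS = ("fixation", "saccade", "missing")


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class IntegrityError(ValueError):
    """A file parses but violates an invariant (ordering, coverage...)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Stimulus screen geometry linking pixels to degrees of visual angle.

    The defaults describe a 1920x1080 video shown at 25 fps subtending
    47.5 deg horizontally and 27.8 deg vertically at 62 cm viewing distance.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_deg: float = 47.5
    height_deg: float = 27.8
    viewing_distance_cm: float = 62.0
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "width_deg",
            "height_deg",
            "viewing_distance_cm",
            "frame_rate_hz",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_deg

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "width_deg": self.width_deg,
            "height_deg": self.height_deg,
            "viewing_distance_cm": self.viewing_distance_cm,
            "frame_rate_hz": self.frame_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenGeometry":
        return cls(**d)


DEFAULT_GEOMETRY = ScreenGeometry()


@dataclass
class GazeRecording:
    """One participant's time-stamped gaze sample stream for one eye.

    ``t_ms`` must be strictly increasing.  Coordinates may lie off-screen
    (recorded as valid, they simply fall outside every ROI).  ``events`` is a
    total labelling: every sample is one of ``fixation``, ``saccade`` or
    ``missing``; coordinates of missing samples are NaN.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    events: np.ndarray  # dtype object/str, values in EVENT_LABELS
    sampling_rate_hz: float = 1000.0
    eye: str = "left"
    validation_error_deg: float | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.events = np.asarray(self.events, dtype=object)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.events) == n):
            raise ValueError("sample arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise IntegrityError(
                    f"timestamps must be strictly increasing; first violation at row {i + 1} "
                    f"(t={self.t_ms[i + 1]!r} after t={self.t_ms[i]!r})"
                )
        unknown = set(self.events) - set(EVENT_LABELS)
        if unknown:
            raise FormatError(f"unknown event labels: {sorted(unknown)}")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def window(self) -> tuple[float, float]:
        """(start, end) in ms; end is start of the last sample interval + one period."""
        if len(self) == 0:
            return (0.0, 0.0)
        return (float(self.t_ms[0]), float(self.t_ms[-1]) + 1000.0 / self.sampling_rate_hz)


@dataclass
class RoiTrack:
    """Per-frame binary masks for every ROI label over an analysis window.

    Masks are held run-length encoded (``frames`` maps frame index ->
    {label -> RLE string}); identical frames can share the same string, so a
    static 300-frame HD track costs almost nothing.  :meth:`mask` decodes to
    a dense bool array of shape (height_px, width_px), memoized per distinct
    encoding.  Every frame index spanned by ``window`` at the geometry's
    frame rate must be present.  Construct from dense arrays with
    :meth:`from_masks`.
    """

    geometry: ScreenGeometry
    window: tuple[float, float]  # (start_ms, end_ms)
    frames: dict[int, dict[str, str]]
    labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self) -> None:
        start, end = self.window
        if not end > start:
            raise ValueError(f"window must be increasing, got {self.window}")
        missing = [i for i in self.frame_range() if i not in self.frames]
        if missing:
            raise IntegrityError(f"track is missing frames {missing} inside window {self.window}")
        for idx, masks in self.frames.items():
            for label in masks:
                if label not in self.labels:
                    raise FormatError(f"frame {idx}: label {label!r} not in {self.labels}")
        self._decode_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_masks(
        cls,
        geometry: ScreenGeometry,
        window: tuple[float, float],
        frames: Mapping[int, Mapping[str, np.ndarray]],
        labels: tuple[str, ...] = ROI_LABELS,
    ) -> "RoiTrack":
        shape = (geometry.height_px, geometry.width_px)
        encoded: dict[int, dict[str, str]] = {}
        for idx, masks in frames.items():
            encoded[idx] = {}
            for label, m in masks.items():
                m = np.asarray(m, dtype=bool)
                if m.shape != shape:
                    raise IntegrityError(
                        f"frame {idx} label {label}: mask shape {m.shape} != frame shape {shape}"
                    )
                encoded[idx][label] = rle_encode(m)
        return cls(geometry=geometry, window=window, frames=encoded, labels=labels)

    def frame_range(self) -> range:
        fps = self.geometry.frame_rate_hz
        start, end = self.window
        first = int(np.floor(start * fps / 1000.0))
        last = int(np.ceil(end * fps / 1000.0))
        return range(first, last)

    def frame_index(self, t_ms: float) -> int:
        """Frame holding time t: floor(t * fps / 1000), constant within a frame."""
        return int(np.floor(t_ms * self.geometry.frame_rate_hz / 1000.0))

    def mask(self, frame: int, label: str) -> np.ndarray:
        """Dense bool mask for one frame and label (decoded, memoized)."""
        rle = self.frames[frame][label]
        cached = self._decode_cache.get(rle)
        if cached is None:
            shape = (self.geometry.height_px, self.geometry.width_px)
            cached = rle_decode(rle, shape)
            if len(self._decode_cache) > 32:
                self._decode_cache.clear()
            self._decode_cache[rle] = cached
        return cached

    def mask_area(self, frame: int, label: str) -> int:
        """Pixel area straight from the encoding, without decoding."""
        rle = self.frames[frame][label]
        if not rle.strip():
            return 0
        return sum(int(run.split(":")[1]) for run in rle.split())


# ---------------------------------------------------------------------------
# Run-length encoding of binary masks
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> str:
    """Encode a 2-D binary mask as ``start:length`` runs of True pixels.

    The mask is flattened row-major; starts are 0-based.  The empty mask
    encodes to the empty string.
    """
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return ""
    padded = np.concatenate(([False], flat, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]
    return " ".join(f"{s}:{e - s}" for s, e in zip(starts, ends))


def rle_decode(encoded: str, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    mask = np.zeros(int(shape[0]) * int(shape[1]), dtype=bool)
    if encoded.strip():
        for run in encoded.split():
            s_str, l_str = run.split(":")
            s, l = int(s_str), int(l_str)
            if s < 0 or s + l > mask.size:
                raise FormatError(f"RLE run {run!r} exceeds mask of shape {shape}")
            mask[s : s + l] = True
    return mask.reshape(shape)


# ---------------------------------------------------------------------------
# Gaze sample TSV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeDialect:
    """Column names and event-string mapping for gaze sample files.

    Vendor sample reports differ in column naming and in how events are
    labelled, so both are configurable.  ``event_map`` maps raw event strings
    to the canonical vocabulary; raw strings absent from the map are rejected
    unless ``unmapped`` says how to treat them.
    """

    time_col: str = "time"
    x_col: str = "x"
    y_col: str = "y"
    event_col: str = "event"
    eye_col: str | None = None
    event_map: Mapping[str, str] = field(
        default_factory=lambda: {e: e for e in EVENT_LABELS}
    )
    unmapped: str = "reject"  # or one of EVENT_LABELS to coerce

    def map_event(self, raw: str) -> str:
        if raw in self.event_map:
            return self.event_map[raw]
        if self.unmapped in EVENT_LABELS:
            return self.unmapped
        raise FormatError(f"unknown event string {raw!r} and dialect rejects unmapped events")


DEFAULT_DIALECT = GazeDialect()


def read_gaze_samples(
    path: str | Path,
    dialect: GazeDialect = DEFAULT_DIALECT,
    *,
    sampling_rate_hz: float = 1000.0,
    eye: str = "left",
    validation_error_deg: float | None = None,
) -> GazeRecording:
    """Read a tab-separated gaze sample file into a :class:`GazeRecording`."""
    df = pd.read_csv(path, sep="\t")
    for col in (dialect.time_col, dialect.x_col, dialect.y_col, dialect.event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events = np.array([dialect.map_event(str(e)) for e in df[dialect.event_col]], dtype=object)
    return GazeRecording(
        t_ms=df[dialect.time_col].to_numpy(dtype=float),
        x_px=df[dialect.x_col].to_numpy(dtype=float),
        y_px=df[dialect.y_col].to_numpy(dtype=float),
        events=events,
        sampling_rate_hz=sampling_rate_hz,
        eye=eye,
        validation_error_deg=validation_error_deg,
    )


def write_gaze_samples(recording: GazeRecording, path: str | Path,
                       dialect: GazeDialect = DEFAULT_DIALECT) -> None:
    df = pd.DataFrame(
        {
            dialect.time_col: recording.t_ms,
            dialect.x_col: recording.x_px,
            dialect.y_col: recording.y_px,
            dialect.event_col: recording.events,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ROI track file: JSON header + RLE mask lines
# ---------------------------------------------------------------------------

def write_roi_track(track: RoiTrack, path: str | Path) -> None:
    header = {
        "format": "gazeroi-track/1",
        "geometry": track.geometry.to_dict(),
        "window_ms": list(track.window),
        "labels": list(track.labels),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for idx in sorted(track.frames):
            for label in track.labels:
                if label in track.frames[idx]:
                    fh.write(f"{idx}\t{label}\t{track.frames[idx][label]}\n")


def read_roi_track(path: str | Path) -> RoiTrack:
    with open(path) as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: first line is not a JSON header ({exc})") from exc
        if header.get("format") != "gazeroi-track/1":
            raise FormatError(f"{path}: unrecognised track format {header.get('format')!r}")
        geometry = ScreenGeometry.from_dict(header["geometry"])
        labels = tuple(header["labels"])
        frames: dict[int, dict[str, str]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'frame<TAB>label<TAB>rle'")
            idx = int(parts[0])
            label = parts[1]
            frames.setdefault(idx, {})[label] = parts[2] if len(parts) > 2 else ""
    return RoiTrack(
        geometry=geometry,
        window=tuple(header["window_ms"]),
        frames=frames,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def write_results_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV with a header; numbers at full precision.

    An empty record list produces a header-only file when a DataFrame with
    columns is given, or an empty file for a bare empty list.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, index=False, float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
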