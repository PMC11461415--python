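"""Eye-tracking data-quality metrics and per-participant eye selection.

Three standard metrics:

* **accuracy** — the validation error reported by the tracker's calibration
  check, in degrees;
* **precision** — root-mean-square sample-to-sample (RMS-S2S) angular
  displacement between consecutive valid samples, by default within
  fixation-labelled samples only;
* **data loss** — percentage of missing samples relative to the number of
  samples nominally expected in the analysis window.

When both eyes were recorded, only the eye with the lower average validation
error is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GazeRecording, ScreenGeometry, DEFAULT_GEOMETRY

__all__ = ["QualityReport", "select_eye", "precision_rms_s2s", "data_loss", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    accuracy_deg: float | None
    precision_rms_s2s_deg: float
    data_loss_pct: float
    selected_eye: str

    def __post_init__(self) -> None:
        if self.precision_rms_s2s_deg < 0:
            raise ValueError("precision must be non-negative")
        if not 0 <= self.data_loss_pct <= 100:
            raise ValueError("data loss must be a percentage in [0, 100]")


def select_eye(
    validation_error_left: float | None,
    validation_error_right: float | None,
    tie: str = "left",
) -> str:
    """Pick the eye with the lower average validation error.

    An eye with a missing error value is never selected; ties go to ``tie``
    (left by default).
    """
    left, right = validation_error_left, validation_error_right
    if left is None and right is None:
        raise ValueError("validation error missing for both eyes")
    for name, v in (("left", left), ("right", right)):
        if v is not None and v < 0:
            raise ValueError(f"{name} validation error must be non-negative, got {v}")
    if left is None:
        return "right"
    if right is None:
        return "left"
    if left == right:
        return tie
    return "left" if left < right else "right"


def precision_rms_s2s(
    recording: GazeRecording,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    scope: str = "fixations_only",
) -> float:
    """RMS sample-to-sample deviation in degrees of visual angle.

    Displacements between consecutive valid samples are converted to degrees
    per axis (the pixel grid is anisotropic) before taking the Euclidean
    norm.  ``scope`` restricts the pairs: ``fixations_only`` (default) uses
    consecutive samples both labelled fixation; ``all_valid`` uses any
    consecutive non-missing pair.
    """
    if scope == "fixations_only":
        valid = recording.events == "fixation"
    elif scope == "all_valid":
        valid = recording.events != "missing"
    else:
        raise ValueError(f"unknown scope {scope!r}")
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise ValueError("no consecutive valid sample pair in scope: precision undefined")
    dx = np.diff(recording.x_px)[pair] / geometry.px_per_deg_x
    dy = np.diff(recording.y_px)[pair] / geometry.px_per_deg_y
    return float(np.sqrt(np.mean(dx**2 + dy**2)))


def data_loss(recording: GazeRecording, window: tuple[float, float] | None = None) -> float:
    """Percentage of missing samples out of those nominally expected.

    The expected count is the nominal sampling rate times the window
    duration (missing samples carry no timestamps of their own in some
    exports, so the denominator cannot be the observed sample count).
    """
    if window is None:
        window = recording.window
    start, end = window
    if not end > start:
        raise ValueError(f"window must be non-empty, got {window}")
    expected = (end - start) * recording.sampling_rate_hz / 1000.0
    if expected <= 0:
        raise ValueError("zero expected samples in window")
    in_win = (recording.t_ms >= start) & (recording.t_ms < end)
    n_missing = int(np.count_nonzero(recording.events[in_win] == "missing"))
    n_missing += int(round(expected)) - int(np.count_nonzero(in_win))  # absent rows
    return 100.0 * max(n_missing, 0) / expected


def quality_report(
    recording: GazeRecording,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    window: tuple[float, float] | None = None,
    scope: str = "fixations_only",
) -> QualityReport:
    return QualityReport(
        accuracy_deg=recording.validation_error_deg,
        precision_rms_s2s_deg=precision_rms_s2s(recording, geometry, scope),
        data_loss_pct=data_loss(recording, window),
        selected_eye=recording.eye,
    )
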