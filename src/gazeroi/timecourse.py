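"""Total viewing times and cumulative / non-cumulative time-course statistics.

All statistics operate on an :class:`AssignedStream`: a gaze stream whose
samples have already been assigned to a single ROI label each.  Samples
flagged *excluded* (saccade or missing events) are dropped from every
denominator; the remaining *retained* samples are the ``S_t`` of the
cumulative time-course definition, and those carrying ROI label *r* are the
``S_{t,r}``.

The cumulative statistic for ROI *r* at bin *k* is the proportion of all
retained samples up to and including bin *k* that fell in *r*:

    DCTC_r(k) = sum_{t in T_k} S_{t,r} / sum_{t in T_k} S_t

with bins of width ``bin_ms`` (default 100 ms) anchored at the window start.
``CTC_r`` is the same curve expressed in percent; its value at the final bin
equals the ROI's relative total viewing time.  The non-cumulative variant
uses each bin's own samples only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ROI_LABELS

__all__ = [
    "AssignedStream",
    "OTHER_LABEL",
    "compute_tvt",
    "compute_dctc",
    "compute_ctc",
    "compute_noncumulative",
    "n_bins",
]

#: Label for retained samples that fall inside no ROI (including off-screen).
OTHER_LABEL = "other"


@dataclass
class AssignedStream:
    """Per-sample ROI assignment over an analysis window.

    ``labels[i]`` is the ROI label of sample ``i`` (or ``"other"``); excluded
    samples (saccade/missing events) instead carry their event label and have
    ``excluded[i] = True``.  ``n_dropped`` counts samples outside the track
    window that were discarded during assignment.
    """

    t_ms: np.ndarray
    labels: np.ndarray  # object dtype
    excluded: np.ndarray  # bool
    window: tuple[float, float]
    vocabulary: tuple[str, ...] = ROI_LABELS
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.t_ms) == len(self.labels) == len(self.excluded)):
            raise ValueError("t_ms, labels and excluded must have equal length")
        allowed = set(self.vocabulary) | {OTHER_LABEL, "saccade", "missing"}
        bad = set(self.labels) - allowed
        if bad:
            raise ValueError(f"labels outside vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def all_labels(self) -> tuple[str, ...]:
        """The full label partition of retained samples: vocabulary + other."""
        return tuple(self.vocabulary) + (OTHER_LABEL,)

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded

    def bin_index(self, bin_ms: float) -> np.ndarray:
        """0-based bin of each sample: left-closed intervals of width bin_ms
        anchored at the window start."""
        start = self.window[0]
        return np.floor((self.t_ms - start) / bin_ms).astype(int)


def n_bins(stream: AssignedStream, bin_ms: float) -> int:
    start, end = stream.window
    return int(np.ceil((end - start) / bin_ms))


def compute_tvt(stream: AssignedStream, denominator_mode: str = "retained") -> dict[str, float]:
    """Relative total viewing time (percent) per label, including ``other``.

    ``denominator_mode="retained"`` divides by the number of retained
    (fixation) samples, so the label partition sums to exactly 100.
    ``"window"`` divides by the nominal sample count of the whole window
    (saccade and missing samples then dilute every label).
    """
    ret = stream.retained
    n_ret = int(ret.sum())
    if n_ret == 0:
        raise ValueError("no retained samples: TVT undefined")
    if denominator_mode == "retained":
        denom = n_ret
    elif denominator_mode == "window":
        denom = len(stream)
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    labels = stream.labels[ret]
    return {
        lab: 100.0 * float(np.count_nonzero(labels == lab)) / denom
        for lab in stream.all_labels
    }


def _bin_counts(stream: AssignedStream, bin_ms: float, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin retained-sample counts: (in label, total)."""
    k = n_bins(stream, bin_ms)
    ret = stream.retained
    bins = stream.bin_index(bin_ms)[ret]
    if np.any((bins < 0) | (bins >= k)):
        raise ValueError("samples outside the stream window")
    labels = stream.labels[ret]
    total = np.bincount(bins, minlength=k).astype(float)
    in_label = np.bincount(bins[labels == label], minlength=k).astype(float)
    return in_label, total


def compute_dctc(stream: AssignedStream, label: str, bin_ms: float = 100.0) -> np.ndarray:
    """Discrete cumulative time course: per-bin running proportion in ``label``.

    Bins with an empty cumulative denominator yield NaN.
    """
    in_label, total = _bin_counts(stream, bin_ms, label)
    cum_in, cum_tot = np.cumsum(in_label), np.cumsum(total)
    out = np.full(len(total), np.nan)
    nz = cum_tot > 0
    out[nz] = cum_in[nz] / cum_tot[nz]
    return out


def compute_ctc(stream: AssignedStream, label: str, bin_ms: float = 100.0) -> np.ndarray:
    """Cumulative time course in percent: ``100 * DCTC``.

    The final value equals the label's relative TVT under the retained-sample
    denominator.
    """
    return 100.0 * compute_dctc(stream, label, bin_ms)


def compute_noncumulative(stream: AssignedStream, label: str, bin_ms: float = 100.0) -> np.ndarray:
    """Per-bin percent of that bin's retained samples in ``label``.

    Empty bins yield NaN.
    """
    in_label, total = _bin_counts(stream, bin_ms, label)
    out = np.full(len(total), np.nan)
    nz = total > 0
    out[nz] = 100.0 * in_label[nz] / total[nz]
    return out


def tvt_table(streams: dict, denominator_mode: str = "retained") -> pd.DataFrame:
    """Tidy TVT table over participants: one row per (participant, label).

    ``streams`` maps participant id -> AssignedStream (or (condition, stream)
    tuples, in which case a condition column is added).
    """
    rows = []
    for pid, value in streams.items():
        condition = None
        stream = value
        if isinstance(value, tuple):
            condition, stream = value
        tvt = compute_tvt(stream, denominator_mode)
        for lab, pct in tvt.items():
            row = {"participant": pid, "label": lab, "tvt_pct": pct}
            if condition is not None:
                row["condition"] = condition
            rows.append(row)
    return pd.DataFrame(rows)
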