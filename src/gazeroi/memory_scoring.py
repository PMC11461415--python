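"""Detail-level memory accuracy and inter-rater agreement.

Scoring of free-text responses against an answer key is human work; this
module starts from per-participant tallies of correct and incorrect details.
Accuracy is the proportion of correct details (in percent); inter-rater
agreement is the Pearson correlation of two raters' counts over shared
participants, computed separately for correct and incorrect details.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MemoryTally", "accuracy", "interrater_agreement", "accuracy_table"]


@dataclass(frozen=True)
class MemoryTally:
    participant: str
    rater: str
    n_correct: int
    n_incorrect: int

    def __post_init__(self) -> None:
        if self.n_correct < 0 or self.n_incorrect < 0:
            raise ValueError("detail counts must be non-negative")


def accuracy(tally: MemoryTally) -> float:
    """Percent correct: n_correct / (n_correct + n_incorrect) * 100."""
    total = tally.n_correct + tally.n_incorrect
    if total < 1:
        raise ValueError(f"participant {tally.participant}: no scored details, accuracy undefined")
    return 100.0 * tally.n_correct / total


def interrater_agreement(
    tallies_r1: list[MemoryTally], tallies_r2: list[MemoryTally]
) -> tuple[float, float]:
    """Pearson r between two raters' correct counts and incorrect counts.

    Only participants scored by both raters enter; at least 3 are required,
    and each count series needs nonzero variance.
    """
    by1 = {t.participant: t for t in tallies_r1}
    by2 = {t.participant: t for t in tallies_r2}
    shared = sorted(set(by1) & set(by2))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared participants, got {len(shared)}")
    out = []
    for attr in ("n_correct", "n_incorrect"):
        a = np.array([getattr(by1[p], attr) for p in shared], dtype=float)
        b = np.array([getattr(by2[p], attr) for p in shared], dtype=float)
        if np.var(a) == 0 or np.var(b) == 0:
            raise ValueError(f"zero variance in {attr} series: correlation undefined")
        out.append(float(stats.pearsonr(a, b).statistic))
    return out[0], out[1]


def accuracy_table(tallies: list[MemoryTally]) -> pd.DataFrame:
    """One row per tally with the accuracy percentage appended."""
    return pd.DataFrame(
        {
            "participant": [t.participant for t in tallies],
            "rater": [t.rater for t in tallies],
            "n_correct": [t.n_correct for t in tallies],
            "n_incorrect": [t.n_incorrect for t in tallies],
            "accuracy_pct": [accuracy(t) for t in tallies],
        }
    )


def read_tally_csv(path) -> list[MemoryTally]:
    df = pd.read_csv(path)
    required = {"participant", "rater", "n_correct", "n_incorrect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tally file missing columns {sorted(missing)}")
    return [
        MemoryTally(str(r.participant), str(r.rater), int(r.n_correct), int(r.n_incorrect))
        for r in df.itertuples()
    ]
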