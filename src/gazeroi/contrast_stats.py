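"""Planned two-group contrasts from summary statistics, with JZS Bayes factors.

Every comparison uses only the two groups involved (pooled variance,
``df = nA + nB - 2``), matching a planned-contrast design without an omnibus
error term.  For one-tailed tests the t statistic is oriented so that the
predicted direction is positive; the directional p-value is then the upper
tail of ``t_signed``.

Bayes factors use the default Jeffreys–Zellner–Siow setup: a Cauchy prior
with scale ``r = sqrt(2)/2`` on the standardized effect size ``delta``.  The
marginal likelihood under H1 is

    m1(t) = integral  T_df(t; delta * sqrt(nA*nB/(nA+nB))) Cauchy(delta; 0, r) d delta

evaluated by adaptive quadrature over the noncentral-t density, and

    BF01 = T_df(t; 0) / m1(t).

One-sided alternatives truncate the prior to the predicted sign (density
doubled on that half-line), so an effect observed *opposite* to the
prediction yields strong evidence for the null rather than a value near 1.

Evidence is banded on ``B = max(BF01, 1/BF01)``: below 1.5 inconclusive,
then weak / moderate / strong / very strong / extreme at 3, 10, 30, 100,
signed for or against H1 by whether BF01 is below 1.  Rendered symbols use
``+`` (for H1), ``-`` (against H1) repeated once per band, and ``o`` for
inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "DEFAULT_BF_SCALE",
    "EVIDENCE_BANDS",
    "ContrastInput",
    "ContrastResult",
    "GroupSummary",
    "pooled_t",
    "jzs_bf01",
    "classify_evidence",
    "evidence_symbol",
    "contrast_table",
]

DEFAULT_BF_SCALE = math.sqrt(2.0) / 2.0

#: (upper bound of B = max(BF01, 1/BF01), strength name, symbol count)
EVIDENCE_BANDS = (
    (1.5, "inconclusive", 0),
    (3.0, "weak", 1),
    (10.0, "moderate", 2),
    (30.0, "strong", 3),
    (100.0, "very strong", 4),
    (math.inf, "extreme", 5),
)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: mean, SD and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class ContrastInput:
    """One planned comparison between groups A and B.

    ``predicted_direction`` is required for one-tailed tests and must be
    ``"A<B"`` or ``"A>B"``; two-tailed tests use ``None``.
    """

    group_a: GroupSummary
    group_b: GroupSummary
    tails: int = 2
    predicted_direction: str | None = None
    bf_scale: float = DEFAULT_BF_SCALE

    def __post_init__(self) -> None:
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.tails == 1 and self.predicted_direction not in ("A<B", "A>B"):
            raise ValueError("one-tailed contrasts need predicted_direction 'A<B' or 'A>B'")
        if self.tails == 2 and self.predicted_direction is not None:
            raise ValueError("two-tailed contrasts take no predicted_direction")


@dataclass(frozen=True)
class ContrastResult:
    name: str
    t_signed: float
    t_abs: float
    df: int
    p: float
    d: float
    bf01: float
    evidence: str
    symbol: str
    extras: dict = field(default_factory=dict)


def pooled_t(inp: ContrastInput) -> tuple[float, int, float, float]:
    """Pooled two-sample t-test from summary statistics.

    Returns ``(t_signed, df, p, d)`` where ``t_signed`` is oriented so the
    predicted direction (if any) is positive, ``p`` is one- or two-tailed per
    the input, and ``d`` is the absolute pooled-SD standardized difference.
    """
    a, b = inp.group_a, inp.group_b
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    sp = math.sqrt(sp2)
    diff = a.mean - b.mean
    se = sp * math.sqrt(1.0 / a.n + 1.0 / b.n)
    if sp == 0.0:
        if diff == 0.0:
            t_signed = 0.0
        else:
            raise ValueError("zero pooled SD with unequal means: t undefined")
        d = 0.0
    else:
        oriented = -diff if inp.predicted_direction == "A<B" else diff
        t_signed = oriented / se
        d = abs(diff) / sp
    if inp.tails == 1:
        p = float(stats.t.sf(t_signed, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t_signed), df))
    return float(t_signed), int(df), p, float(d)


def _h1_marginal(t: float, df: int, neff: float, scale: float,
                 lo: float, hi: float) -> tuple[float, float]:
    """Integral of nct-density times Cauchy prior over (lo, hi) in delta."""

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * neff) * stats.cauchy.pdf(delta, 0.0, scale)

    # split at 0 and at the likelihood peak so quad sees every mass lobe
    peak = t / neff if neff > 0 else 0.0
    cuts = sorted(p for p in (0.0, peak) if lo < p < hi)
    bounds = [lo, *cuts, hi]
    val = err = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        v, e = integrate.quad(integrand, a, b, epsabs=0.0, epsrel=1e-9, limit=500)
        val += v
        err += e
    return val, err


def jzs_bf01(
    t_signed: float,
    n_a: int,
    n_b: int,
    tails: int = 2,
    scale: float = DEFAULT_BF_SCALE,
) -> float:
    """Default-prior (JZS) Bayes factor in favour of the null, from t and ns.

    ``tails=2`` uses the full Cauchy(0, scale) prior on delta; ``tails=1``
    truncates it to ``delta > 0`` — the predicted sign under the orientation
    of :func:`pooled_t`.  Quadrature is adaptive with relative tolerance
    1e-9 on the H1 marginal; non-convergence raises with diagnostics.
    """
    if not np.isfinite(t_signed):
        raise ValueError(f"t must be finite, got {t_signed}")
    if min(n_a, n_b) < 2:
        raise ValueError("both group sizes must be at least 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n_a + n_b - 2
    neff = math.sqrt(n_a * n_b / (n_a + n_b))
    if tails == 2:
        m1, err = _h1_marginal(t_signed, df, neff, scale, -np.inf, np.inf)
    else:
        m1, err = _h1_marginal(t_signed, df, neff, scale, 0.0, np.inf)
        m1, err = 2.0 * m1, 2.0 * err
    if m1 <= 0 or (err > 0 and err / m1 > 1e-6):
        raise ArithmeticError(
            f"quadrature failed: marginal={m1!r}, abs err={err!r}, "
            f"t={t_signed}, df={df}, neff={neff}, tails={tails}"
        )
    m0 = stats.t.pdf(t_signed, df)
    return float(m0 / m1)


def classify_evidence(bf01: float) -> tuple[str, str]:
    """Band a Bayes factor into an evidence class.

    Returns ``(description, symbol)``; e.g. ``("moderate evidence against H1",
    "- -")`` for BF01 = 5, or ``("inconclusive", "o")`` near 1.
    """
    if not bf01 > 0:
        raise ValueError(f"BF01 must be positive, got {bf01}")
    b = max(bf01, 1.0 / bf01)
    for upper, name, count in EVIDENCE_BANDS:
        if b < upper:
            break
    if count == 0:
        return "inconclusive", "o"
    side = "against" if bf01 > 1 else "for"
    sym = " ".join(("-" if bf01 > 1 else "+",) * count)
    return f"{name} evidence {side} H1", sym


def evidence_symbol(bf01: float) -> str:
    return classify_evidence(bf01)[1]


def contrast_table(
    group_summaries: dict[str, GroupSummary],
    contrast_plan: list[dict],
    bf_scale: float = DEFAULT_BF_SCALE,
) -> pd.DataFrame:
    """Run a declarative plan of planned contrasts over named group summaries.

    Each plan entry is a dict with keys ``a``, ``b`` (group names), ``tails``
    (1 or 2), optional ``direction`` (``"A<B"``/``"A>B"``) and optional
    ``name``.  Returns one row per contrast with full-precision statistics
    plus display columns rounded the way such tables are printed (t, d, BF01
    to 2 dp; p to 3 dp).
    """
    rows = []
    for entry in contrast_plan:
        for key in ("a", "b"):
            if entry[key] not in group_summaries:
                raise KeyError(f"unknown group {entry[key]!r} in contrast plan")
        inp = ContrastInput(
            group_a=group_summaries[entry["a"]],
            group_b=group_summaries[entry["b"]],
            tails=int(entry.get("tails", 2)),
            predicted_direction=entry.get("direction"),
            bf_scale=bf_scale,
        )
        t_signed, df, p, d = pooled_t(inp)
        bf = jzs_bf01(t_signed, inp.group_a.n, inp.group_b.n, inp.tails, bf_scale)
        evidence, symbol = classify_evidence(bf)
        rows.append(
            {
                "name": entry.get("name", f"{entry['a']} vs. {entry['b']}"),
                "a": entry["a"],
                "b": entry["b"],
                "tails": inp.tails,
                "t_signed": t_signed,
                "t_abs": abs(t_signed),
                "df": df,
                "p": p,
                "d": d,
                "bf01": bf,
                "evidence": evidence,
                "symbol": symbol,
                "t_display": round(abs(t_signed), 2),
                "p_display": round(p, 3),
                "d_display": round(d, 2),
                "bf01_display": round(bf, 2),
            }
        )
    columns = [
        "name", "a", "b", "tails", "t_signed", "t_abs", "df", "p", "d",
        "bf01", "evidence", "symbol", "t_display", "p_display", "d_display",
        "bf01_display",
    ]
    return pd.DataFrame(rows, columns=columns)
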