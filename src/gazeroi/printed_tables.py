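"""Bundled group summaries and contrast plans for the staged-robbery study.

These are the published per-condition means and standard deviations of the
relative total viewing times (laboratory eye-tracking experiment, three
object conditions — knife / water bottle / plunger — with n = 54 each) and
of detail-memory accuracy (the same experiment, and an online follow-up
crossing object type with audio presence, n = 38 per cell).  They serve as
fixed inputs so the planned-contrast tables can be regenerated offline from
summary statistics alone.

Contrast plans encode the study's directional hypotheses: attention-shift
accounts predict *less* viewing time on the perpetrator — and worse memory
for her appearance — when she holds a weapon or an unusual object than when
she holds a neutral object, and *more* viewing time on the critical object
itself; weapon-vs-unusual-object comparisons are two-tailed.
"""

from __future__ import annotations

from .contrast_stats import GroupSummary

__all__ = [
    "EXP1_TVT_SUMMARIES",
    "EXP1_TVT_PLANS",
    "EXP1_MEMORY_SUMMARIES",
    "EXP1_MEMORY_PLAN",
    "EXP2_MEMORY_SUMMARIES",
    "EXP2_MEMORY_PLANS",
    "all_table_specs",
]

_N1 = 54  # participants per object condition, eye-tracking experiment
_N2 = 38  # participants per cell, online experiment


def _g(mean: float, sd: float, n: int) -> GroupSummary:
    return GroupSummary(mean=mean, sd=sd, n=n)


#: Relative TVT (%) per ROI and object condition: {roi: {condition: summary}}.
EXP1_TVT_SUMMARIES: dict[str, dict[str, GroupSummary]] = {
    "perpetrator": {
        "knife": _g(49.94, 12.82, _N1),
        "water_bottle": _g(52.83, 12.88, _N1),
        "plunger": _g(48.00, 10.83, _N1),
    },
    "perpetrator_head": {
        "knife": _g(36.29, 14.06, _N1),
        "water_bottle": _g(43.12, 13.52, _N1),
        "plunger": _g(40.65, 12.57, _N1),
    },
    "perpetrator_body": {
        "knife": _g(13.65, 8.90, _N1),
        "water_bottle": _g(9.71, 6.46, _N1),
        "plunger": _g(7.35, 5.16, _N1),
    },
    "critical_object": {
        "knife": _g(10.95, 8.42, _N1),
        "water_bottle": _g(10.95, 8.47, _N1),
        "plunger": _g(11.85, 7.01, _N1),
    },
    "victim": {
        "knife": _g(18.92, 9.98, _N1),
        "water_bottle": _g(17.21, 9.23, _N1),
        "plunger": _g(20.17, 8.29, _N1),
    },
    "victim_head": {
        "knife": _g(7.57, 6.25, _N1),
        "water_bottle": _g(9.19, 7.25, _N1),
        "plunger": _g(8.44, 6.40, _N1),
    },
    "victim_body": {
        "knife": _g(11.35, 8.24, _N1),
        "water_bottle": _g(8.02, 6.11, _N1),
        "plunger": _g(11.73, 7.78, _N1),
    },
    "other": {
        "knife": _g(20.19, 8.53, _N1),
        "water_bottle": _g(19.01, 8.88, _N1),
        "plunger": _g(19.98, 7.97, _N1),
    },
}


def _plan(direction_vs_bottle: str | None) -> list[dict]:
    """The study's standard three contrasts for one ROI.

    One-tailed vs the neutral object where a direction is predicted,
    two-tailed for knife vs plunger and for ROIs without predictions.
    """
    if direction_vs_bottle is None:
        head = [
            {"a": "knife", "b": "water_bottle", "tails": 2},
            {"a": "plunger", "b": "water_bottle", "tails": 2},
        ]
    else:
        head = [
            {"a": "knife", "b": "water_bottle", "tails": 1, "direction": direction_vs_bottle},
            {"a": "plunger", "b": "water_bottle", "tails": 1, "direction": direction_vs_bottle},
        ]
    return head + [{"a": "knife", "b": "plunger", "tails": 2}]


#: Per-ROI contrast plans for the TVT tables.
EXP1_TVT_PLANS: dict[str, list[dict]] = {
    "perpetrator": _plan("A<B"),
    "perpetrator_head": _plan("A<B"),
    "perpetrator_body": _plan("A<B"),
    "critical_object": _plan("A>B"),
    "victim": _plan(None),
    "victim_head": _plan(None),
    "victim_body": _plan(None),
    "other": _plan(None),
}

#: Memory accuracy (%) in the eye-tracking experiment.
EXP1_MEMORY_SUMMARIES: dict[str, GroupSummary] = {
    "knife": _g(77.71, 8.97, _N1),
    "water_bottle": _g(76.71, 9.17, _N1),
    "plunger": _g(77.60, 8.57, _N1),
}

EXP1_MEMORY_PLAN: list[dict] = _plan("A<B")

#: Memory accuracy (%) in the online experiment, by audio condition.
EXP2_MEMORY_SUMMARIES: dict[str, dict[str, GroupSummary]] = {
    "with_audio": {
        "knife": _g(76.56, 7.87, _N2),
        "water_bottle": _g(80.38, 8.69, _N2),
        "plunger": _g(75.30, 10.17, _N2),
    },
    "without_audio": {
        "knife": _g(78.44, 10.97, _N2),
        "water_bottle": _g(77.39, 8.30, _N2),
        "plunger": _g(76.27, 11.91, _N2),
    },
}

EXP2_MEMORY_PLANS: dict[str, list[dict]] = {
    "with_audio": _plan("A<B"),
    "without_audio": _plan("A<B"),
}


def all_table_specs() -> list[tuple[str, dict[str, GroupSummary], list[dict]]]:
    """Every (block name, summaries, plan) needed to regenerate the tables."""
    specs: list[tuple[str, dict[str, GroupSummary], list[dict]]] = []
    for roi, summaries in EXP1_TVT_SUMMARIES.items():
        specs.append((f"exp1_tvt_{roi}", summaries, EXP1_TVT_PLANS[roi]))
    specs.append(("exp1_memory", EXP1_MEMORY_SUMMARIES, EXP1_MEMORY_PLAN))
    for audio, summaries in EXP2_MEMORY_SUMMARIES.items():
        specs.append((f"exp2_memory_{audio}", summaries, EXP2_MEMORY_PLANS[audio]))
    return specs
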