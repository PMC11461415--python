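"""Frozen published contrast-table values for the staged-robbery study.

One tuple per planned contrast: (block, a, b, t, p, d, bf01, symbol).
Values printed as inequalities in the source tables ("< 0.01", "< .001")
are stored as ("lt", bound) and compared as upper bounds.
"""

LT = "lt"

#: (block, group a, group b, |t|, p, d, BF01, evidence symbol)
PRINTED_CONTRASTS = [
    # relative total viewing times, whole-person ROIs
    ("exp1_tvt_perpetrator", "knife", "water_bottle", 1.17, 0.123, 0.22, 1.55, "-"),
    ("exp1_tvt_perpetrator", "plunger", "water_bottle", 2.11, 0.019, 0.41, 0.35, "+"),
    ("exp1_tvt_perpetrator", "knife", "plunger", 0.85, 0.395, 0.16, 3.54, "- -"),
    ("exp1_tvt_critical_object", "knife", "water_bottle", (LT, 0.01), 0.501, (LT, 0.01), 4.92, "- -"),
    ("exp1_tvt_critical_object", "plunger", "water_bottle", 0.60, 0.274, 0.12, 2.91, "-"),
    ("exp1_tvt_critical_object", "knife", "plunger", 0.61, 0.544, 0.12, 4.16, "- -"),
    ("exp1_tvt_victim", "knife", "water_bottle", 0.92, 0.358, 0.18, 3.35, "- -"),
    ("exp1_tvt_victim", "plunger", "water_bottle", 1.75, 0.083, 0.34, 1.25, "o"),
    ("exp1_tvt_victim", "knife", "plunger", 0.71, 0.480, 0.14, 3.92, "- -"),
    ("exp1_tvt_other", "knife", "water_bottle", 0.71, 0.482, 0.14, 3.93, "- -"),
    ("exp1_tvt_other", "plunger", "water_bottle", 0.60, 0.550, 0.12, 4.18, "- -"),
    ("exp1_tvt_other", "knife", "plunger", 0.13, 0.895, 0.03, 4.87, "- -"),
    # by body region
    ("exp1_tvt_perpetrator_head", "knife", "water_bottle", 2.57, 0.006, 0.50, 0.13, "+ +"),
    ("exp1_tvt_perpetrator_head", "plunger", "water_bottle", 0.98, 0.163, 0.19, 1.93, "-"),
    ("exp1_tvt_perpetrator_head", "knife", "plunger", 1.70, 0.093, 0.33, 1.36, "o"),
    ("exp1_tvt_perpetrator_body", "knife", "water_bottle", 2.63, 0.995, 0.51, 16.77, "- - -"),
    ("exp1_tvt_perpetrator_body", "plunger", "water_bottle", 2.10, 0.019, 0.40, 0.36, "+"),
    ("exp1_tvt_perpetrator_body", "knife", "plunger", 4.50, (LT, 0.001), 0.87, (LT, 0.01), "+ + + + +"),
    ("exp1_tvt_victim_head", "knife", "water_bottle", 1.25, 0.216, 0.24, 2.46, "-"),
    ("exp1_tvt_victim_head", "plunger", "water_bottle", 0.57, 0.569, 0.11, 4.24, "- -"),
    ("exp1_tvt_victim_head", "knife", "plunger", 0.72, 0.476, 0.14, 3.90, "- -"),
    ("exp1_tvt_victim_body", "knife", "water_bottle", 2.39, 0.019, 0.46, 0.40, "+"),
    ("exp1_tvt_victim_body", "plunger", "water_bottle", 2.76, 0.007, 0.53, 0.18, "+ +"),
    ("exp1_tvt_victim_body", "knife", "plunger", 0.25, 0.806, 0.05, 4.78, "- -"),
    # memory accuracy, eye-tracking experiment
    ("exp1_memory", "knife", "water_bottle", 0.57, 0.716, 0.11, 7.19, "- -"),
    ("exp1_memory", "plunger", "water_bottle", 0.52, 0.698, 0.10, 6.97, "- -"),
    ("exp1_memory", "knife", "plunger", 0.06, 0.949, 0.01, 4.90, "- -"),
    # memory accuracy, online experiment
    ("exp2_memory_with_audio", "knife", "water_bottle", 2.01, 0.024, 0.46, 0.39, "+"),
    ("exp2_memory_with_audio", "plunger", "water_bottle", 2.34, 0.011, 0.54, 0.21, "+ +"),
    ("exp2_memory_with_audio", "knife", "plunger", 0.60, 0.548, 0.14, 3.60, "- -"),
    ("exp2_memory_without_audio", "knife", "water_bottle", 0.47, 0.681, 0.11, 5.78, "- -"),
    ("exp2_memory_without_audio", "plunger", "water_bottle", 0.48, 0.318, 0.11, 2.85, "-"),
    ("exp2_memory_without_audio", "knife", "plunger", 0.83, 0.410, 0.19, 3.13, "- -"),
]
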