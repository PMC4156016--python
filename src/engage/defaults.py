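"""Reference parameter and count tables for the pregnancy-intervention cohort.

These constants encode the published summary of a randomized online
intervention to prevent excessive gestational weight gain (analysis
sample n=1014): the six engagement-pattern classes and four
demographic/BMI subgroups with their class prevalences and
class-conditional response probabilities, and the printed contingency
tables (baseline characteristics of the intervention vs analysis
samples; feature use by subgroup) used for association checks.

The probability tables are used as the generative truth of the
synthetic-data module and as recovery targets for the LCA engine.
Printed probabilities are rounded to two decimals, so some columns sum
to 0.99 or 1.01; they are renormalized by :func:`normalized_rho`.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Indicator vocabularies

CONSISTENCY_LEVELS = ["consistent", "almost_consistent", "inconsistent", "never"]
QUANTITY_LEVELS = ["high", "low", "never"]

CONSISTENCY_FEATURES = ["login", "weight_tracker"]
QUANTITY_FEATURES = ["health_info", "blogs", "resources", "pa_goal", "diet_goal"]
FEATURES = CONSISTENCY_FEATURES + QUANTITY_FEATURES

SUBGROUP_ITEMS = ["race", "ethnicity", "low_income", "bmi_cat", "age_cat"]
SUBGROUP_LEVELS = {
    "race": ["white", "black", "other"],
    "ethnicity": ["hispanic", "non_hispanic"],
    "low_income": ["yes", "no"],
    "bmi_cat": ["normal", "overweight", "obese"],
    "age_cat": ["18_25", "25_30", "30_plus"],
}

# ---------------------------------------------------------------------------
# Six engagement-pattern classes (columns: super-users, medium-users,
# consistent / almost-consistent / inconsistent weight-tracker users,
# non-users). rho rows are per class, in the level order declared above.

ENGAGEMENT_CLASSES = [
    "super",
    "medium",
    "wt_consistent",
    "wt_almost",
    "wt_inconsistent",
    "non_user",
]

ENGAGEMENT_GAMMA = [0.1302, 0.1400, 0.1499, 0.2199, 0.1598, 0.2002]

ENGAGEMENT_RHO = {
    # consistent, almost_consistent, inconsistent, never
    "login": [
        [0.93, 0.07, 0.00, 0.00],
        [0.12, 0.86, 0.02, 0.00],
        [0.97, 0.03, 0.00, 0.00],
        [0.14, 0.84, 0.01, 0.00],
        [0.04, 0.08, 0.89, 0.00],
        [0.00, 0.02, 0.34, 0.64],
    ],
    "weight_tracker": [
        [0.88, 0.11, 0.01, 0.00],
        [0.00, 0.85, 0.13, 0.02],
        [0.83, 0.13, 0.01, 0.03],
        [0.02, 0.63, 0.28, 0.08],
        [0.00, 0.00, 0.71, 0.29],
        [0.00, 0.00, 0.00, 1.00],
    ],
    # high, low, never
    "health_info": [
        [0.84, 0.16, 0.00],
        [0.65, 0.27, 0.09],
        [0.23, 0.42, 0.35],
        [0.08, 0.31, 0.61],
        [0.06, 0.20, 0.73],
        [0.00, 0.01, 0.99],
    ],
    "blogs": [
        [0.91, 0.07, 0.01],
        [0.59, 0.31, 0.09],
        [0.24, 0.44, 0.32],
        [0.09, 0.43, 0.48],
        [0.08, 0.33, 0.59],
        [0.00, 0.01, 1.00],
    ],
    "resources": [
        [0.89, 0.11, 0.00],
        [0.47, 0.27, 0.25],
        [0.06, 0.33, 0.61],
        [0.01, 0.20, 0.79],
        [0.05, 0.16, 0.80],
        [0.00, 0.00, 1.00],
    ],
    "pa_goal": [
        [0.53, 0.17, 0.30],
        [0.45, 0.21, 0.33],
        [0.18, 0.14, 0.67],
        [0.02, 0.14, 0.84],
        [0.04, 0.20, 0.76],
        [0.00, 0.00, 1.00],
    ],
    "diet_goal": [
        [0.50, 0.16, 0.34],
        [0.42, 0.20, 0.38],
        [0.17, 0.18, 0.65],
        [0.05, 0.15, 0.80],
        [0.10, 0.20, 0.70],
        [0.00, 0.00, 1.00],
    ],
}

# ---------------------------------------------------------------------------
# Four demographic/BMI subgroups (columns: black-young, black-heavier,
# Hispanic, white).

SUBGROUP_CLASSES = ["black_young", "black_heavier", "hispanic", "white"]

SUBGROUP_GAMMA = [0.2051, 0.1302, 0.1154, 0.5493]

SUBGROUP_RHO = {
    # white, black, other
    "race": [
        [0.29, 0.71, 0.00],
        [0.42, 0.56, 0.01],
        [0.02, 0.01, 0.96],
        [0.94, 0.00, 0.06],
    ],
    # hispanic, non_hispanic
    "ethnicity": [
        [0.06, 0.94],
        [0.04, 0.96],
        [0.84, 0.16],
        [0.02, 0.98],
    ],
    # yes, no
    "low_income": [
        [0.89, 0.11],
        [0.67, 0.33],
        [0.78, 0.22],
        [0.11, 0.89],
    ],
    # normal, overweight, obese
    "bmi_cat": [
        [0.67, 0.20, 0.13],
        [0.12, 0.45, 0.43],
        [0.41, 0.41, 0.18],
        [0.60, 0.27, 0.12],
    ],
    # 18_25, 25_30, 30_plus
    "age_cat": [
        [0.82, 0.14, 0.03],
        [0.23, 0.49, 0.28],
        [0.55, 0.31, 0.15],
        [0.07, 0.34, 0.59],
    ],
}

# ---------------------------------------------------------------------------
# Published contingency tables.

# Feature use by demographic/BMI subgroup: per feature, rows are the
# feature's category levels (consistency or quantity order as declared
# above), columns follow SUBGROUP_CLASSES. Subgroup sizes 208/132/117/557.
FEATURE_USE_BY_SUBGROUP = {
    "login": [
        [33, 28, 28, 243],
        [61, 39, 33, 209],
        [64, 35, 31, 84],
        [50, 30, 25, 21],
    ],
    "weight_tracker": [
        [17, 16, 20, 199],
        [40, 30, 27, 201],
        [58, 28, 23, 87],
        [93, 58, 47, 70],
    ],
    "health_info": [
        [22, 19, 17, 212],
        [30, 25, 25, 149],
        [156, 88, 75, 196],
    ],
    "blogs": [
        [31, 25, 22, 199],
        [44, 35, 23, 170],
        [133, 72, 72, 188],
    ],
    "resources": [
        [13, 22, 12, 160],
        [26, 22, 18, 109],
        [169, 88, 87, 288],
    ],
    "pa_goal": [
        [21, 20, 11, 124],
        [21, 19, 15, 84],
        [166, 93, 91, 349],
    ],
    "diet_goal": [
        [26, 21, 17, 118],
        [23, 13, 19, 87],
        [159, 98, 81, 352],
    ],
}

# Baseline characteristics: counts per category for the full intervention
# sample (n=1126) and the analysis sample (n=1014); the excluded column
# (n=112) is recovered by subtraction for attrition chi-square checks.
BASELINE_CATEGORIES = {
    "race": ["white", "black", "other"],
    "ethnicity": ["hispanic", "non_hispanic"],
    "low_income": ["yes", "no"],
    "bmi_cat": ["normal", "overweight", "obese"],
    "age_cat": ["18_25", "25_30", "30_plus"],
}
BASELINE_INTERVENTION_COUNTS = {
    "race": [693, 273, 160],
    "ethnicity": [145, 981],
    "low_income": [494, 632],
    "bmi_cat": [575, 346, 205],
    "age_cat": [341, 363, 422],
}
BASELINE_ANALYSIS_COUNTS = {
    "race": [630, 239, 145],
    "ethnicity": [128, 886],
    "low_income": [442, 572],
    "bmi_cat": [520, 308, 186],
    "age_cat": [305, 328, 381],
}

ANALYSIS_SAMPLE_SIZE = 1014

# Reference medians used by the synthetic event renderer (the real median
# is sample-dependent; these are fixed so rendering is invertible).
REFERENCE_MEDIANS = {
    "health_info": 4,
    "blogs": 4,
    "resources": 3,
    "pa_goal": 3,
    "diet_goal": 3,
}


def normalized_rho(rho: dict[str, list[list[float]]]) -> dict[str, np.ndarray]:
    """Return ``rho`` as float arrays with every class row renormalized to 1.

    Printed probabilities carry two-decimal rounding, so raw rows can sum
    to 0.99 or 1.01; downstream code requires exact simplex rows.
    """
    out = {}
    for item, rows in rho.items():
        arr = np.asarray(rows, dtype=float)
        if (arr < 0).any():
            raise ValueError(f"negative probability in rho table for {item!r}")
        sums = arr.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError(f"zero-sum rho row for {item!r}")
        out[item] = arr / sums
    return out


def normalized_gamma(gamma: list[float]) -> np.ndarray:
    """Return ``gamma`` renormalized to sum exactly to 1."""
    arr = np.asarray(gamma, dtype=float)
    if (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("class prevalences must be non-negative and sum > 0")
    return arr / arr.sum()
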