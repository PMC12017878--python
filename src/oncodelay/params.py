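"""Published study parameters used as package defaults.

All values here are reference constants taken from the source study's
printed tables: monthly Markov transition probabilities, stage-migration
anchor probabilities by stage transition and molecular subtype, the
per-delay-category hazard-ratio gradient and life-years-lost values, the
mediation decomposition shares, health-state utilities, phase costs, and
the symptomatic-cohort delay distribution.  Everything downstream
(synthetic cohorts, traces, thresholds, reports) is parameterised by these
defaults but accepts user-supplied overrides.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Delay categories
# ---------------------------------------------------------------------------

#: Category labels in temporal order.
DELAY_LABELS: tuple[str, ...] = (
    "<2w", "2w-1m", "1-2m", "2-6m", "6-12m", ">=1y",
)

#: Half-open day ranges [lo, hi) per category; the open-ended ">=1y"
#: category is truncated at two years for sampling purposes.
DELAY_DAY_RANGES: dict[str, tuple[int, int]] = {
    "<2w": (0, 14),
    "2w-1m": (14, 30),
    "1-2m": (30, 60),
    "2-6m": (60, 180),
    "6-12m": (180, 365),
    ">=1y": (365, 730),
}

#: Representative evaluation day per category (reference category maps to 0).
DELAY_REPRESENTATIVE_DAYS: dict[str, int] = {
    "<2w": 0,
    "2w-1m": 30,
    "1-2m": 60,
    "2-6m": 180,
    "6-12m": 270,
    ">=1y": 360,
}

#: Symptomatic-patient counts per delay category (denominator 639).
DELAY_COUNTS: dict[str, int] = {
    "<2w": 45,
    "2w-1m": 84,
    "1-2m": 40,
    "2-6m": 241,
    "6-12m": 60,
    ">=1y": 169,
}

SYMPTOMATIC_N: int = 639

#: Categories counted as high-risk delays (more than two months).
HIGH_RISK_LABELS: tuple[str, ...] = ("2-6m", "6-12m", ">=1y")

# ---------------------------------------------------------------------------
# Survival impact by delay category
# ---------------------------------------------------------------------------

#: Mortality hazard ratio per delay category (reference = 1.0).
HAZARD_RATIOS: dict[str, float] = {
    "<2w": 1.0,
    "2w-1m": 1.18,
    "1-2m": 1.27,
    "2-6m": 1.54,
    "6-12m": 1.92,
    ">=1y": 2.35,
}

#: 95% confidence intervals of the published hazard ratios.
HAZARD_RATIO_CIS: dict[str, tuple[float, float]] = {
    "2w-1m": (1.05, 1.32),
    "1-2m": (1.13, 1.42),
    "2-6m": (1.37, 1.73),
    "6-12m": (1.68, 2.19),
    ">=1y": (2.06, 2.67),
}

#: Life-years lost per delay category (years; reference = 0).
LIFE_YEARS_LOST: dict[str, float] = {
    "<2w": 0.0,
    "2w-1m": 0.7,
    "1-2m": 1.2,
    "2-6m": 2.8,
    "6-12m": 4.3,
    ">=1y": 6.7,
}

#: QALY loss per delay category (years; carried verbatim, not derived).
QALY_LOSS: dict[str, float] = {
    "<2w": 0.0,
    "2w-1m": 0.8,
    "1-2m": 1.4,
    "2-6m": 3.2,
    "6-12m": 4.9,
    ">=1y": 7.6,
}

#: Odds multipliers for requiring more intensive treatment, by category.
TREATMENT_ODDS: dict[str, float] = {
    "<2w": 1.0,
    "2w-1m": 1.3,
    "1-2m": 1.7,
    "2-6m": 2.4,
    "6-12m": 3.1,
    ">=1y": 3.8,
}

# ---------------------------------------------------------------------------
# Markov model: five health states and monthly transition probabilities
# ---------------------------------------------------------------------------

STATES: tuple[str, ...] = (
    "Symptomatic-Undiagnosed",
    "Diagnosed-Untreated",
    "Treatment-Initiated",
    "Progressive-Disease",
    "Death",
)

#: Monthly transition probabilities: (from, to) -> {stratum -> p} where a
#: stratum is a (key, value) pair; ("overall", "overall") is the fallback.
#: Only these forward transitions exist; Death is absorbing.
TRANSITIONS: dict[tuple[str, str], dict[tuple[str, str], float]] = {
    ("Symptomatic-Undiagnosed", "Diagnosed-Untreated"): {
        ("overall", "overall"): 0.302,
        ("symptom", "Breast lump"): 0.355,
        ("symptom", "Pain"): 0.217,
        ("symptom", "Nipple discharge"): 0.196,
        ("time_interval", "<2w"): 0.930,
        ("time_interval", "2w-1m"): 0.868,
        ("time_interval", "1-2m"): 0.937,
        ("time_interval", "2-6m"): 0.623,
        ("time_interval", "6-12m"): 0.906,
        ("time_interval", ">=1y"): 0.736,
    },
    ("Diagnosed-Untreated", "Treatment-Initiated"): {
        ("overall", "overall"): 0.424,
        ("stage", "IIA"): 0.476,
        ("stage", "IIB"): 0.431,
        ("stage", "III/IV"): 0.383,
    },
    ("Treatment-Initiated", "Progressive-Disease"): {
        ("overall", "overall"): 0.103,
        ("subtype", "HR+"): 0.078,
        ("subtype", "TripleNegative"): 0.138,
        ("subtype", "HER2+"): 0.115,
        ("treatment", "surgery-only"): 0.062,
        ("treatment", "surgery+chemo"): 0.126,
        ("treatment", "multimodality"): 0.143,
    },
    ("Treatment-Initiated", "Death"): {
        ("overall", "overall"): 0.021,
    },
    ("Progressive-Disease", "Death"): {
        ("overall", "overall"): 0.085,
        ("stage_at_dx", "IIA"): 0.046,
        ("stage_at_dx", "IIB"): 0.073,
        ("stage_at_dx", "III"): 0.119,
        ("stage_at_dx", "IV"): 0.215,
    },
}

#: Order in which stratification keys override the overall value when a
#: query stratum supplies several applicable keys for the same transition.
STRATUM_PRIORITY: tuple[str, ...] = (
    "time_interval", "symptom", "stage", "stage_at_dx", "subtype", "treatment",
)

# ---------------------------------------------------------------------------
# Economic parameters
# ---------------------------------------------------------------------------

CYCLE_LENGTH_MONTHS: int = 1
HORIZON_CYCLES: int = 120          # 10-year horizon, monthly cycles
ANNUAL_DISCOUNT_RATE: float = 0.035

#: Health-state utility weights (Death implicitly 0).
UTILITIES: dict[str, float] = {
    "Symptomatic-Undiagnosed": 0.78,
    "Diagnosed-Untreated": 0.70,
    "Treatment-Initiated": 0.65,
    "Progressive-Disease": 0.45,
}

#: Phase costs in Saudi riyal.  Initial treatment is a (low, high) range
#: resolved by stage at diagnosis.
COSTS_SAR: dict[str, float | tuple[float, float]] = {
    "diagnostic": 2450.0,
    "initial_treatment": (15300.0, 42800.0),
    "continuing_care": 4200.0,
    "progressive_disease": 18700.0,
    "terminal_care": 23500.0,
}

# ---------------------------------------------------------------------------
# Stage-migration anchor probabilities (months -> cumulative probability)
# ---------------------------------------------------------------------------

#: Anchors at 1, 3, 6 and 12 months for stage transitions and molecular
#: classes; curves pass through (0, 0) and are interpolated between anchors.
MIGRATION_ANCHORS: dict[str, tuple[tuple[float, float], ...]] = {
    "Stage I->II": ((1, 0.038), (3, 0.117), (6, 0.245), (12, 0.429)),
    "Stage II->III": ((1, 0.027), (3, 0.082), (6, 0.178), (12, 0.336)),
    "Stage III->IV": ((1, 0.019), (3, 0.058), (6, 0.121), (12, 0.243)),
    "HR+": ((1, 0.021), (3, 0.065), (6, 0.137), (12, 0.258)),
    "TripleNegative": ((1, 0.053), (3, 0.159), (6, 0.318), (12, 0.536)),
    "HER2+": ((1, 0.038), (3, 0.114), (6, 0.228), (12, 0.427)),
}

#: Published critical-delay thresholds in days (reference constants; the
#: published values are not derivable from the anchors above under either
#: interpolation scheme, so computed thresholds are reported alongside).
PRINTED_THRESHOLD_DAYS: dict[str, int] = {
    "Stage I->II": 56,
    "Stage II->III": 68,
    "Stage III->IV": 73,
    "HR+": 85,
    "TripleNegative": 38,
    "HER2+": 52,
    "<40y": 48,
    "40-60y": 65,
    ">60y": 92,
}

#: Published number-needed-to-treat per subgroup (reference constants).
PRINTED_NNT: dict[str, int] = {
    "Stage I->II": 9,
    "Stage II->III": 13,
    "Stage III->IV": 14,
    "HR+": 16,
    "TripleNegative": 6,
    "HER2+": 10,
    "<40y": 8,
    "40-60y": 12,
    ">60y": 17,
}

MIGRATION_THRESHOLD_LEVEL: float = 0.10

# ---------------------------------------------------------------------------
# Mediation decomposition (share of the total delay->survival effect)
# ---------------------------------------------------------------------------

MEDIATION_PROPORTIONS: dict[str, float] = {
    "stage_migration": 0.673,
    "treatment_intensity": 0.189,
    "complications": 0.074,
}

MEDIATION_DIRECT: float = 0.064
MEDIATION_CIS: dict[str, tuple[float, float]] = {
    "stage_migration": (0.584, 0.761),
    "treatment_intensity": (0.125, 0.253),
    "complications": (0.038, 0.110),
    "direct": (0.021, 0.107),
}
N_BOOTSTRAP: int = 1000

# ---------------------------------------------------------------------------
# System-level delay intervals (days)
# ---------------------------------------------------------------------------

SYSTEM_INTERVAL_MEANS: dict[str, float] = {
    "referral": 23.2,
    "pathology": 14.7,
    "planning": 18.5,
}

# ---------------------------------------------------------------------------
# Misc published quantities
# ---------------------------------------------------------------------------

BASELINE_MONTHLY_HAZARD: float = 0.021    # Treatment-Initiated -> Death
COMPLICATION_BASE_PROB: float = 0.15      # 85% had no surgical complication
COHORT_TOTAL_N: int = 802
DAYS_PER_MONTH: int = 30
DAYS_PER_YEAR: int = 365
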