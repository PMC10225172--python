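"""Study constants for the favorable intermediate-risk (FIR) prostatectomy cohort.

These are the published summary numbers the package takes as inputs: landmark
survival probabilities per endpoint, the baseline cumulative-risk values used
for the counterfactual scenario grids, the scenario grid itself, and the
demographic marginals the synthetic cohort emulates.
"""

from __future__ import annotations

# Landmark survival probabilities after radical prostatectomy, by endpoint,
# at 5/10/15 years.  These calibrate the synthetic cohort's hazards.
LANDMARK_SURVIVAL: dict[str, dict[float, float]] = {
    "PCSM": {5.0: 0.999, 10.0: 0.990, 15.0: 0.978},
    "CRPC": {5.0: 0.998, 10.0: 0.975, 15.0: 0.966},
    "metastasis": {5.0: 0.993, 10.0: 0.971, 15.0: 0.965},
}

# Baseline cumulative risk x (percent) in the surgery cohort, as printed in the
# published excess-risk table for the primary endpoint.  Note the 5-year value
# (0.14%) carries more precision than the complement of the 5-year survival
# landmark (99.9% -> 0.1%): the printed x values are authoritative for the
# scenario arithmetic.  Secondary endpoints have no printed x column, so their
# baselines are the complements of the survival landmarks.
PRINTED_BASELINE_RISK_PCT: dict[str, dict[float, str]] = {
    "PCSM": {5.0: "0.14", 10.0: "0.99", 15.0: "2.17"},
    "CRPC": {5.0: "0.20", 10.0: "2.50", 15.0: "3.40"},
    "metastasis": {5.0: "0.70", 10.0: "2.90", 15.0: "3.50"},
}

ENDPOINTS: tuple[str, ...] = ("PCSM", "CRPC", "metastasis")

# Scenario grid: risk multipliers for the hypothetical active-surveillance
# cohort, and landmark horizons in years.
DEFAULT_MULTIPLIERS: tuple[str, ...] = ("1.25", "1.5", "1.75", "2.0")
DEFAULT_HORIZONS: tuple[float, ...] = (5.0, 10.0, 15.0)

# Cohort structure: 920 men, surgery years 1988-2017 with quartiles
# (2008, 2011, 2014), follow-up administratively censored at end of 2017.
DEFAULT_N_SUBJECTS = 920
ACCRUAL_YEARS: tuple[float, ...] = (1988.0, 2008.0, 2011.0, 2014.0, 2017.0)
STUDY_END_YEAR = 2017.0
DEFAULT_DROPOUT_RATE = 0.01  # per year, non-administrative loss to follow-up

# Demographic marginals (cosmetic: estimation never reads them).
BLACK_FRACTION = 0.31
GRADE_GROUP2_FRACTION = 0.77
STAGE_PROBS: dict[str, float] = {"T1": 0.66, "T2a": 0.27, "T2b": 0.04, "T2c": 0.03}
AGE_MEDIAN, AGE_Q1, AGE_Q3 = 63.0, 59.0, 67.0
PSA_MEDIAN, PSA_Q1, PSA_Q3 = 6.0, 4.7, 8.5
# Among grade-group-1 men (who need another intermediate-risk feature), split
# between the high-PSA route and the cT2b-c route in proportion to the cohort
# counts of those features (149 PSA>=10 vs 64 cT2b-c).
GG1_HIGH_PSA_FRACTION = 149 / (149 + 64)
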