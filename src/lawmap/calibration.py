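"""Default cohort calibration tables.

The synthetic cohort is calibrated to published group summaries from a
four-group MDCT/echocardiography study of left-atrial remodeling:
controls (n=115), HFpEF alone (n=59), AF alone (n=37) and HFpEF+AF (n=38).
Wall indices are summarised as median [Q1-Q3] (right-skewed, modeled
log-normal); echocardiographic and clinical covariates as mean +/- SD
(modeled Gaussian); prevalences as fractions; hs-CRP and BNP as
median [Q1-Q3] (log-normal).

Units: LAVi ml/m2; LAWV ml; LAWT and LAWT(SD) mm; age years; BMI kg/m2;
eGFR ml/min/1.73m2; HDL-c mg/dl; hs-CRP mg/dl; BNP pg/ml; E/e' unitless;
PALS and LVGLS and LVEF %; strain rates 1/s.
"""

from __future__ import annotations

GROUPS = ("control", "hfpef", "af", "hfpef_af")

GROUP_SIZES = {"control": 115, "hfpef": 59, "af": 37, "hfpef_af": 38}

WALL_INDICES = ("lavi", "lawv", "lawt", "lawt_sd")

# median, Q1, Q3 per group
WALL_INDEX_MEDIAN_IQR = {
    "control": {
        "lavi": (33.6, 27.3, 39.5),
        "lawv": (10.7, 9.50, 12.1),
        "lawt": (1.91, 1.81, 2.02),
        "lawt_sd": (0.58, 0.55, 0.61),
    },
    "hfpef": {
        "lavi": (44.4, 37.2, 52.1),
        "lawv": (12.0, 10.2, 13.7),
        "lawt": (2.02, 1.91, 2.12),
        "lawt_sd": (0.60, 0.56, 0.65),
    },
    "af": {
        "lavi": (45.8, 34.4, 52.1),
        "lawv": (12.6, 11.6, 15.6),
        "lawt": (2.06, 1.93, 2.25),
        "lawt_sd": (0.68, 0.61, 0.71),
    },
    "hfpef_af": {
        "lavi": (62.3, 48.3, 81.3),
        "lawv": (15.4, 13.3, 18.5),
        "lawt": (2.10, 2.00, 2.28),
        "lawt_sd": (0.64, 0.57, 0.72),
    },
}

# mean, SD per group for Gaussian covariates
GAUSSIAN_COVARIATES = {
    "age": {"control": (61.4, 10.8), "hfpef": (69.1, 8.1), "af": (59.7, 10.3), "hfpef_af": (68.1, 11.9)},
    "bmi": {"control": (24.7, 3.4), "hfpef": (26.3, 3.8), "af": (25.8, 4.2), "hfpef_af": (26.4, 4.4)},
    "hdl_c": {"control": (50.2, 13.4), "hfpef": (46.7, 14.6), "af": (46.5, 10.8), "hfpef_af": (44.4, 13.6)},
    "egfr": {"control": (84.4, 21.7), "hfpef": (77.1, 29.0), "af": (83.2, 24.0), "hfpef_af": (59.7, 25.9)},
    "e_over_e_prime": {"control": (8.7, 2.9), "hfpef": (13.4, 6.4), "af": (9.8, 3.8), "hfpef_af": (16.4, 11.2)},
    "lvef": {"control": (63.5, 7.8), "hfpef": (60.6, 8.4), "af": (61.7, 7.7), "hfpef_af": (62.8, 10.5)},
    "lvgls": {"control": (-19.1, 3.2), "hfpef": (-17.0, 4.5), "af": (-18.6, 2.6), "hfpef_af": (-14.2, 3.6)},
    "pals": {"control": (35.0, 7.3), "hfpef": (27.4, 7.7), "af": (28.7, 9.5), "hfpef_af": (23.8, 7.3)},
    "srs": {"control": (1.52, 0.35), "hfpef": (1.20, 0.29), "af": (1.24, 0.34), "hfpef_af": (1.04, 0.25)},
    "sre": {"control": (-1.48, 0.44), "hfpef": (-1.07, 0.40), "af": (-1.13, 0.35), "hfpef_af": (-0.89, 0.28)},
    "sra": {"control": (-1.93, 0.48), "hfpef": (-1.13, 0.40), "af": (-1.04, 0.48), "hfpef_af": (-0.93, 0.41)},
}

# prevalence (fraction) per group for binary covariates
BINARY_COVARIATES = {
    "female": {"control": 0.34, "hfpef": 0.610, "af": 0.405, "hfpef_af": 0.474},
    "hypertension": {"control": 0.287, "hfpef": 0.695, "af": 0.730, "hfpef_af": 0.842},
    "diabetes": {"control": 0.20, "hfpef": 0.492, "af": 0.351, "hfpef_af": 0.526},
}

# median, Q1, Q3 per group for right-skewed covariates (log-normal)
LOGNORMAL_COVARIATES = {
    "hs_crp": {
        "control": (0.11, 0.045, 0.35),
        "hfpef": (0.35, 0.11, 1.71),
        "af": (0.63, 0.21, 2.09),
        "hfpef_af": (1.42, 0.34, 2.25),
    },
    "bnp": {
        "control": (19.9, 10.3, 36.0),
        "hfpef": (120.0, 46.0, 352.0),
        "af": (61.0, 35.5, 145.0),
        "hfpef_af": (482.0, 176.0, 915.0),
    },
}

# Body surface area is not reported; Normal(1.73, 0.15) truncated to
# [1.2, 2.6] m2 is a realistic adult distribution for volume indexing.
BSA_MEAN = 1.73
BSA_SD = 0.15
BSA_RANGE = (1.2, 2.6)

# Pooled standardized slope of PALS on LAVi across all groups; the
# within-group Gaussian-copula coupling is calibrated against this value.
POOLED_LAVI_PALS_SLOPE = -0.43

# Within-subject latent correlation between log wall volume and the log
# shell-volume combination (2/3)*log(LAVi*BSA) + log(LAWT).  Wall volume
# scales with chamber surface area times thickness, so the three indices
# are strongly coupled within a subject; the Gaussian copula preserves
# each index's marginal law exactly while keeping the implied mapped
# fraction inside its feasible window.  0.97 keeps log(mapped fraction)
# more than 3 SD away from both window edges in every group, so the
# bounded redraw rule almost never fires and leaves group medians intact.
WALL_VOLUME_COUPLING_RHO = 0.97
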