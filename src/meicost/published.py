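"""Printed results of the original simulation study.

Reference values used by the ``reproduce`` command to annotate its output
files with side-by-side comparisons (published vs freshly simulated).  They
are reporting targets only — nothing in the simulation or analysis code
reads them.

Each cost entry is (mean, sd) in EUR unless noted; rates are percentages.
"""

ABSTRACT_MEANS = {
    "g1": (28324.51, 6120.84),
    "g2": (32187.07, 6901.79),
    "g3": (28381.01, 10326.73),
}

MEDIANS = {"g1": 28076.08, "g2": 31849.58, "g3": 28846.55}

DURATIONS = {
    "top": (26.73, 13.94),  # years
    "thi": (4.01, 5.18),
    "tsb": (22.72, 14.60),
}

EVENT_COUNTS = {
    "noi_g1": (1.15, 0.39),
    "nor_g1": (0.45, 0.70),
    "nop_g1": (3.64, 2.19),
    "nhi_g2": (2.46, 1.70),
    "nhi_g3": (10.30, 4.26),
}

CAPABILITY_RATES_PCT = {
    "dr_lts_1": 1.12,
    "dr_lts_10": 5.65,
    "dr_lts_25": 12.62,
    "dr_ttr_1": 3.32,
    "dr_ttr_5": 8.64,
    "dr_ttr_10": 15.57,
    "ep_lts_rate": 0.12,
    "ep_ttr_rate": 0.43,
    "ep_nhi_g2_rate": 8.30,
    "ep_nhi_g3_rate": 25.84,
}

CARE_GAP_G3 = (3.32, 7.83)  # years

COST_PER_SUCCESSFUL_YEAR = {"g1": 1059.61, "g3": 1212.55, "g2": 1229.14}

# cost (mean, sd) and homogeneity by duration stratum; key None = full cohort
TABLE5 = {
    "g1": {None: (28325, 6121, 0.82), 10: (21123, 3249, 0.87), 20: (27037, 4258, 0.86), 30: (30842, 4652, 0.87)},
    "g2": {None: (32187, 6902, 0.82), 10: (25321, 4496, 0.85), 20: (31096, 5662, 0.85), 30: (34232, 5975, 0.85)},
    "g3": {None: (28381, 10327, 0.73), 10: (18471, 8018, 0.70), 20: (27409, 9690, 0.74), 30: (32552, 8037, 0.80)},
}

# lifetime cost by number of pre-implant surgeries (level 0 = direct implant)
TABLE6 = {0: (28325, 6121), 1: (30606, 6499), 2: (32347, 6493), 3: (32796, 6953), 4: (34067, 7567), 5: (35394, 7361)}

STRATEGY = {
    "mean": 29099.50,
    "sd": 8384.29,
    "cost_per_successful_year": 1088.61,
    "arm_shares_pct": {
        "g3_by_age_at_first": 16.46,
        "g3_by_age_at_second": 5.93,
        "g1_direct": 23.76,
        "surgery_then_implant": 53.85,
    },
}

CROSSINGS = {"mean_cost": (16, 17), "per_successful_year": 14}
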