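"""Reference cohort summary statistics for perivascular plaque counts.

Published group-level summaries (cell mean, SD, n) from a 28-subject
curcumin-SLO imaging cohort: plaque counts per perivascular scope
(combined, peri-venular, peri-arteriolar) and branch category, stratified
once by neuropsychometric diagnosis (normal vs impaired cognition) and once
by the MOCA screening cut-off.  These cells serve two purposes:

* defaults for the synthetic cohort generator, so simulated cohorts carry
  the same group-difference structure as the real one;
* inputs to summary-statistics-mode recomputation of the published fold
  changes and pooled-t p-values.

Cell key layout: ``{scope: {cell: {"NC"|"IC" (or "hi"|"lo" for MOCA):
(mean, sd, n)}}}`` where cells are the exclusive classes ``primary_main``,
``primary_small``, ``secondary_main``, ``secondary_small``, ``tertiary``
plus the derived ``primary_total`` / ``secondary_total`` / ``total`` rows as
printed.
"""

# Diagnosis stratification: NC = normal cognition (n=9), IC = impaired (n=19).
COGNITION_CELLS = {
    "peri": {
        "total":           {"NC": (83.89, 32.04, 9), "IC": (89.26, 27.81, 19)},
        "primary_total":   {"NC": (43.56, 35.12, 9), "IC": (24.32, 16.85, 19)},
        "primary_main":    {"NC": (12.33, 7.28, 9),  "IC": (7.32, 6.60, 19)},
        "primary_small":   {"NC": (31.22, 29.55, 9), "IC": (17.00, 11.64, 19)},
        "secondary_total": {"NC": (19.78, 10.47, 9), "IC": (35.79, 13.18, 19)},
        "secondary_main":  {"NC": (10.33, 5.89, 9),  "IC": (14.26, 6.36, 19)},
        "secondary_small": {"NC": (9.44, 8.14, 9),   "IC": (21.53, 10.15, 19)},
        "tertiary":        {"NC": (19.56, 12.63, 9), "IC": (27.89, 19.33, 19)},
    },
    "periV": {
        "total":           {"NC": (32.11, 9.40, 9),  "IC": (37.21, 13.86, 19)},
        "primary_total":   {"NC": (18.67, 13.17, 9), "IC": (11.68, 9.15, 19)},
        "primary_main":    {"NC": (7.89, 4.76, 9),   "IC": (4.63, 5.05, 19)},
        "primary_small":   {"NC": (10.78, 9.67, 9),  "IC": (7.05, 5.65, 19)},
        "secondary_total": {"NC": (6.25, 4.59, 8),   "IC": (13.39, 4.53, 18)},
        "secondary_main":  {"NC": (3.11, 1.90, 9),   "IC": (5.44, 2.99, 18)},
        "secondary_small": {"NC": (3.25, 4.03, 8),   "IC": (7.94, 3.90, 18)},
        "tertiary":        {"NC": (4.43, 2.76, 7),   "IC": (11.93, 8.23, 15)},
    },
    "periA": {
        "total":           {"NC": (51.78, 24.70, 9), "IC": (52.05, 17.55, 19)},
        "primary_total":   {"NC": (24.89, 24.43, 9), "IC": (12.63, 11.96, 19)},
        "primary_main":    {"NC": (4.44, 4.13, 9),   "IC": (2.68, 2.77, 19)},
        "primary_small":   {"NC": (23.00, 21.27, 8), "IC": (10.50, 10.14, 18)},
        "secondary_total": {"NC": (12.00, 5.70, 9),  "IC": (23.11, 12.13, 19)},
        "secondary_main":  {"NC": (7.22, 4.35, 9),   "IC": (9.11, 4.43, 19)},
        "secondary_small": {"NC": (4.78, 3.60, 9),   "IC": (14.00, 10.01, 19)},
        "tertiary":        {"NC": (14.44, 9.89, 9),  "IC": (16.56, 10.94, 18)},
    },
}

# MOCA stratification: hi = MOCA > 26 (n=15), lo = MOCA <= 26 (n=13).
MOCA_CELLS = {
    "peri": {
        "total":           {"hi": (86.40, 29.27, 15), "lo": (88.85, 29.27, 13)},
        "primary_total":   {"hi": (38.60, 28.06, 15), "lo": (21.15, 18.48, 13)},
        "primary_main":    {"hi": (11.13, 6.75, 15),  "lo": (6.38, 6.87, 13)},
        "primary_small":   {"hi": (27.47, 23.15, 15), "lo": (14.77, 13.02, 13)},
        "secondary_total": {"hi": (22.43, 11.24, 14), "lo": (37.62, 12.09, 13)},
        "secondary_main":  {"hi": (11.93, 5.96, 15),  "lo": (14.23, 6.87, 13)},
        "secondary_small": {"hi": (12.67, 10.71, 15), "lo": (23.38, 8.51, 13)},
        "tertiary":        {"hi": (21.93, 13.02, 15), "lo": (29.00, 21.80, 13)},
    },
    "periV": {
        "total":           {"hi": (32.20, 10.60, 15), "lo": (39.46, 14.09, 13)},
        "primary_total":   {"hi": (17.93, 10.73, 15), "lo": (9.31, 9.40, 13)},
        "primary_main":    {"hi": (7.13, 4.09, 15),   "lo": (4.00, 5.79, 13)},
        "primary_small":   {"hi": (10.80, 8.17, 15),  "lo": (5.31, 4.68, 13)},
        "secondary_total": {"hi": (7.64, 4.34, 14),   "lo": (15.69, 3.77, 13)},
        "secondary_main":  {"hi": (4.14, 2.80, 14),   "lo": (5.23, 2.95, 13)},
        "secondary_small": {"hi": (3.50, 3.13, 14),   "lo": (10.46, 3.26, 13)},
        "tertiary":        {"hi": (7.67, 6.50, 12),   "lo": (15.50, 14.30, 12)},
    },
    "periA": {
        "total":           {"hi": (54.20, 21.62, 15), "lo": (49.38, 17.60, 13)},
        "primary_total":   {"hi": (20.67, 20.70, 15), "lo": (11.85, 11.99, 13)},
        "primary_main":    {"hi": (4.00, 3.89, 15),   "lo": (2.38, 2.29, 13)},
        "primary_small":   {"hi": (17.86, 17.78, 14), "lo": (10.25, 10.85, 12)},
        "secondary_total": {"hi": (17.47, 11.94, 15), "lo": (21.92, 11.29, 13)},
        "secondary_main":  {"hi": (8.07, 4.13, 15),   "lo": (9.00, 4.85, 13)},
        "secondary_small": {"hi": (9.40, 10.25, 15),  "lo": (12.92, 8.50, 13)},
        "tertiary":        {"hi": (15.80, 10.97, 15), "lo": (15.92, 10.26, 12)},
    },
}

#: Cohort composition: 9 NC vs 19 IC; CDR severity levels 0.5/1/2 at 11/14/3.
N_NC, N_IC = 9, 19
CDR_COUNTS = {0.5: 11, 1.0: 14, 2.0: 3}
MOCA_SPLIT = {"hi": 15, "lo": 13}
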