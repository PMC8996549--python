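"""Published verification constants for pediatric serum creatinine and urea.

These are printed values from a published direct-vs-indirect reference
interval comparison for Chinese children (direct PRINCE-style sample on a
Roche analyzer; indirect LIS outpatient sample on a Beckman analyzer):
the between-analyzer transference chains, the per-stratum direct-sample
means before and after transference, and the direct / GMM-partitioned /
SOM-partitioned reference limits with the bias ratios derived from them.
They serve as fixed in-paper-arithmetic oracles; no microdata is involved.
"""

# Abbott-based transference chains: (slope, intercept), x_target = s*x_abbott + i
ABBOTT_TO_ROCHE_CREAT = (0.965, -0.447)
ABBOTT_TO_BECKMAN_CREAT = (0.903, -1.192)
ABBOTT_TO_ROCHE_UREA = (0.941, 0.143)
ABBOTT_TO_BECKMAN_UREA = (0.961, 0.110)

# printed composed Roche->Beckman slopes (3 dp)
COMPOSED_CREAT_SLOPE_3DP = 0.936
COMPOSED_UREA_SLOPE_3DP = 1.021

# Direct-sample creatinine means (umol/L) by age band, before and after
# transference, printed at 1 dp: (prince_boys, transferred_boys,
# prince_girls, transferred_girls); bands 1-<2 ... 16-<17 years.
CREATININE_MEANS = [
    (25.0, 22.6, 24.1, 21.8),
    (28.7, 26.1, 28.9, 26.2),
    (32.6, 29.8, 31.1, 28.4),
    (35.0, 32.0, 34.6, 31.6),
    (37.1, 33.9, 37.0, 33.9),
    (41.2, 37.8, 40.2, 36.8),
    (42.0, 38.5, 41.0, 37.6),
    (44.0, 40.4, 43.1, 39.6),
    (46.1, 42.3, 45.2, 41.5),
    (48.5, 44.6, 45.4, 41.7),
    (49.1, 45.2, 45.5, 41.8),
    (55.4, 51.1, 51.3, 47.3),
    (59.9, 55.3, 53.6, 49.4),
    (66.9, 61.9, 55.9, 51.6),
    (75.6, 70.0, 60.6, 56.0),
    (77.9, 72.2, 61.9, 57.1),
]

# Urea means (mmol/L), printed at 2 dp: (prince, transferred)
UREA_MEANS = [(4.44, 4.50), (4.10, 4.15)]

# Reference limits (LL, UL) per stratum: direct (transferred), GMM- and
# SOM-partitioned LIS, plus the radical-outlier-strategy variants.
# Strata keys: c1 = creatinine 1-<6 y, c2 = 6-<12 y, cb = 12-<17 y boys,
# cg = 12-<17 y girls, u = urea 1-<17 y.
DIRECT_RI = {"c1": (18.9, 39.5), "c2": (30.1, 52.6), "cb": (40.4, 87.2),
             "cg": (35.7, 68.6), "u": (2.62, 6.50)}
GMM_RI = {"c1": (19.2, 41.6), "c2": (28.1, 55.6), "cb": (39.6, 78.7),
          "cg": (34.0, 69.7), "u": (2.53, 6.06)}
SOM_RI = {"c1": (17.8, 39.8), "c2": (27.2, 63.8), "cb": (41.5, 87.6),
          "cg": (48.0, 77.7), "u": (2.54, 6.37)}
GMM_RADICAL_RI = {"c1": (19.4, 41.9), "c2": (28.5, 55.8), "cb": (38.0, 73.4),
                  "cg": (35.1, 69.2), "u": (2.55, 6.05)}
SOM_RADICAL_RI = {"c1": (17.5, 49.6), "c2": (26.5, 66.3), "cb": (39.6, 83.9),
                  "cg": (30.3, 83.5), "u": (2.45, 5.93)}

# Printed bias ratios (LL, UL) at 2 dp for each indirect method vs direct.
BIAS_RATIOS = {
    "gmm": {"c1": (0.06, 0.40), "c2": (-0.35, 0.52), "cb": (-0.07, -0.71),
            "cg": (-0.20, 0.13), "u": (-0.09, -0.44)},
    "som": {"c1": (-0.21, 0.06), "c2": (-0.51, 1.95), "cb": (0.09, 0.03),
            "cg": (1.47, 1.08), "u": (-0.08, -0.13)},
    "gmm_radical": {"c1": (0.10, 0.46), "c2": (-0.28, 0.56), "cb": (-0.20, -1.16),
                    "cg": (-0.07, 0.07), "u": (-0.07, -0.45)},
    "som_radical": {"c1": (-0.27, 1.92), "c2": (-0.63, 2.39), "cb": (-0.07, -0.28),
                    "cg": (-0.64, 1.78), "u": (-0.17, -0.58)},
}

INDIRECT_RI_BY_METHOD = {
    "gmm": GMM_RI, "som": SOM_RI,
    "gmm_radical": GMM_RADICAL_RI, "som_radical": SOM_RADICAL_RI,
}
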