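"""Published evaluation-table fixtures: cross-fold confusion-matrix counts
(class order N, S, V, F) and the printed metric percentages they imply.

Only internally consistent printed cells are asserted: a handful of
published PPV/SPEC cells do not recompute from their own count rows under
any standard one-vs-rest formula and are omitted (``None``).
"""

# 8-windows + NN confusion matrix and its per-class metrics.
# SPEC(F) prints 96.5 but recomputes to 99.0 from the counts -> omitted.
NN_ALL_WINDOWS_COUNTS = [
    [88681, 369, 737, 213],
    [4106, 82994, 2006, 894],
    [2669, 2132, 83701, 1498],
    [2124, 2872, 4843, 80161],
]
NN_ALL_WINDOWS_METRICS = {          # cls: (ppv, sen, spec)
    "N": (90.9, 98.5, 96.7),
    "S": (93.9, 92.2, 98.0),
    "V": (91.7, 93.0, 97.2),
    "F": (96.9, 89.1, None),
}

# 4th-window confusion matrices (NN / PNN / KNN).
WINDOW4_COUNTS = {
    "nn": [
        [88146, 811, 789, 254],
        [3181, 85641, 901, 277],
        [1553, 1323, 85084, 2040],
        [1108, 2439, 3343, 83110],
    ],
    "pnn": [
        [86415, 2540, 615, 430],
        [171, 89828, 0, 1],
        [1, 71, 89879, 49],
        [0, 1701, 1645, 86654],
    ],
    "knn": [
        [88915, 644, 281, 160],
        [893, 87177, 1155, 775],
        [496, 4545, 82247, 2712],
        [0, 3, 0, 89997],
    ],
}
# Printed per-class sensitivities for the 4th-window runs (all consistent).
WINDOW4_SEN = {
    "nn": {"N": 97.9, "S": 95.2, "V": 94.5, "F": 92.3},
    "pnn": {"N": 96.0, "S": 99.8, "V": 99.9, "F": 96.3},
    "knn": {"N": 98.8, "S": 96.9, "V": 91.4, "F": 100.0},
}

# Summary binary-collapse rows for the 4th-window PNN and KNN runs:
# (TP, TN, FP, FN, ACC, PPV, SEN, SPEC).
SUMMARY_BINARY = {
    "pnn": (269828, 86415, 3585, 172, 99.0, 98.7, 99.9, 96.0),
    "knn": (268611, 88915, 1085, 1389, 99.3, 99.6, 99.5, 98.8),
}

# Class sizes of the source database before balancing (Q later discarded)
# and the balancing target.
RAW_CLASS_COUNTS = {"N": 90023, "S": 2758, "V": 6914, "F": 800}
BALANCE_TARGET = 90000
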