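"""Published diagnostic-accuracy reference values for four indicator rows.

Each row gives Se/Sp/PPV/NPV at months 4..11 × thresholds (mean,
mean±SD, mean±2SD), i.e. 24 cells per metric, for a threshold classifier
with 14 positive and 13 negative subjects.  Values are 2-decimal
rounded; the internal consistency being tested is that inverting Se/Sp
to integer confusion counts reproduces the printed PPV/NPV exactly.
"""

N_POS = 14
N_NEG = 13

# fmt: off
REFERENCE_ROWS = {
    ("R", "GLCM", "SumEntrp"): {
        "Se":  [0.14, 0.64, 1.00, 0.14, 0.64, 1.00, 0.43, 0.71, 1.00, 0.50, 0.71, 1.00,
                0.50, 0.86, 1.00, 0.50, 0.86, 1.00, 0.79, 0.93, 1.00, 0.86, 0.93, 1.00],
        "Sp":  [1.00, 1.00, 0.54, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00,
                1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "PPV": [1.00, 1.00, 0.70, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00,
                1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "NPV": [0.52, 0.72, 1.00, 0.52, 0.72, 1.00, 0.62, 0.76, 1.00, 0.65, 0.76, 1.00,
                0.65, 0.87, 1.00, 0.65, 0.87, 1.00, 0.81, 0.93, 1.00, 0.87, 0.93, 1.00],
    },
    ("B", "GLCM", "InvDefMom"): {
        "Se":  [0.50, 0.79, 1.00, 0.50, 0.79, 1.00, 0.43, 0.71, 0.93, 0.43, 0.71, 0.93,
                0.57, 0.86, 1.00, 0.57, 0.86, 1.00, 0.50, 0.93, 1.00, 0.50, 0.93, 1.00],
        "Sp":  [0.15, 0.00, 0.00, 0.54, 0.46, 0.31, 0.85, 0.69, 0.69, 0.77, 0.69, 0.54,
                0.92, 0.92, 0.54, 1.00, 1.00, 1.00, 1.00, 0.85, 0.85, 0.85, 0.85, 0.69],
        "PPV": [0.39, 0.46, 0.52, 0.54, 0.61, 0.61, 0.75, 0.71, 0.76, 0.67, 0.71, 0.68,
                0.89, 0.92, 0.70, 1.00, 1.00, 1.00, 1.00, 0.87, 0.88, 0.78, 0.87, 0.78],
        "NPV": [0.22, 0.00, 1.00, 0.50, 0.67, 1.00, 0.58, 0.69, 0.90, 0.56, 0.69, 0.88,
                0.67, 0.86, 1.00, 0.68, 0.87, 1.00, 0.65, 0.92, 1.00, 0.61, 0.92, 1.00],
    },
    ("Q", "HS", "Mean"): {
        "Se":  [0.43, 0.93, 0.93, 0.43, 0.93, 0.93, 0.50, 0.93, 0.93, 0.50, 0.93, 0.93,
                0.50, 1.00, 1.00, 0.50, 1.00, 1.00, 0.71, 1.00, 1.00, 0.71, 1.00, 1.00],
        "Sp":  [0.85, 0.31, 0.31, 1.00, 0.23, 0.23, 1.00, 0.62, 0.62, 1.00, 0.85, 0.85,
                1.00, 0.92, 0.92, 1.00, 0.85, 0.85, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "PPV": [0.75, 0.59, 0.59, 1.00, 0.57, 0.57, 1.00, 0.72, 0.72, 1.00, 0.87, 0.87,
                1.00, 0.93, 0.93, 1.00, 0.88, 0.88, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "NPV": [0.58, 0.80, 0.80, 0.62, 0.75, 0.75, 0.65, 0.89, 0.89, 0.65, 0.92, 0.92,
                0.65, 1.00, 1.00, 0.65, 1.00, 1.00, 0.76, 1.00, 1.00, 0.76, 1.00, 1.00],
    },
    ("S", "HS", "Variance"): {
        "Se":  [0.71, 0.86, 0.93, 0.71, 0.86, 0.93, 0.57, 0.86, 0.93, 0.57, 0.86, 0.93,
                0.71, 0.93, 0.93, 0.71, 0.93, 0.93, 0.86, 1.00, 1.00, 0.86, 1.00, 1.00],
        "Sp":  [0.38, 0.38, 0.31, 0.85, 0.77, 0.62, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00,
                1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "PPV": [0.56, 0.60, 0.59, 0.83, 0.80, 0.72, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00,
                1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00],
        "NPV": [0.56, 0.71, 0.80, 0.73, 0.83, 0.89, 0.68, 0.87, 0.93, 0.68, 0.87, 0.93,
                0.76, 0.93, 0.93, 0.76, 0.93, 0.93, 0.87, 1.00, 1.00, 0.87, 1.00, 1.00],
    },
}
# fmt: on
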