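"""Frozen reference values from the published 9-item depression-network study.

Per-group centrality profiles (two demographic splits of the same sample)
and the full-sample strength columns, exactly as printed, together with the
signed-rank statistics the invariance machinery must reproduce from them.
"""

SYMPTOMS = [f"D{i}" for i in range(1, 10)]

# full-sample (outgoing, incoming) strength per symptom
FULL_STRENGTH = {
    "D4": (3.05, 2.61),
    "D8": (2.82, 2.60),
    "D6": (2.43, 2.35),
    "D7": (2.09, 1.95),
    "D2": (1.61, 1.66),
    "D5": (1.48, 1.67),
    "D1": (1.22, 1.317),
    "D3": (1.06, 1.25),
    "D9": (0.98, 1.324),
}

# full-sample relative-influence column as printed (2 dp)
FULL_RELATIVE_INFLUENCE = {
    "D4": 0.08,
    "D8": 0.04,
    "D6": 0.02,
    "D7": 0.04,  # prints 0.04; recomputation from the rounded strengths gives 0.03
    "D2": -0.02,
    "D5": -0.06,
    "D1": -0.04,
    "D3": -0.08,
    "D9": -0.15,
}

# per-group profiles: {index: (group_a values, group_b values)} in D1..D9 order
GENDER = {  # a = males, b = females
    "out_strength": (
        [1.57, 2.58, 1.17, 2.53, 1.09, 1.74, 2.93, 2.48, 1.03],
        [1.60, 1.18, 1.00, 3.12, 1.49, 2.40, 2.06, 2.79, 0.97],
    ),
    "in_strength": (
        [1.74, 2.42, 1.26, 2.35, 1.31, 1.66, 2.70, 2.33, 1.36],
        [1.68, 1.31, 1.24, 2.56, 1.63, 2.33, 1.97, 2.58, 1.30],
    ),
    "betweenness": (
        [0, 8, 0, 10, 0, 4, 8, 2, 0],
        [2, 0, 0, 13, 0, 7, 2, 6, 4],
    ),
    "closeness": (
        [3.47, 3.97, 2.93, 3.90, 3.22, 3.49, 4.27, 3.90, 3.05],
        [3.38, 3.10, 3.13, 4.01, 3.38, 3.84, 3.53, 4.09, 3.15],
    ),
}

AGE = {  # a = ages 18-28, b = ages 29-68
    "out_strength": (
        [1.10, 1.82, 0.98, 2.70, 1.43, 1.38, 2.48, 2.87, 1.02],
        [2.62, 3.12, 1.57, 2.12, 1.14, 2.56, 2.36, 1.52, 1.00],
    ),
    "in_strength": (
        [1.31, 1.93, 1.22, 2.05, 1.62, 1.56, 2.48, 2.41, 1.19],
        [2.56, 2.84, 1.72, 2.23, 1.31, 2.01, 2.11, 1.82, 1.39],
    ),
    "betweenness": (
        [0, 4, 0, 8, 2, 2, 4, 10, 0],
        [8, 12, 0, 4, 0, 8, 2, 0, 0],
    ),
    "closeness": (
        [3.03, 3.44, 2.93, 3.43, 3.26, 3.22, 3.94, 3.83, 2.92],
        [4.15, 4.46, 3.56, 3.94, 2.90, 3.58, 3.66, 3.29, 3.31],
    ),
}

# published W+ / W- per grouping and index
EXPECTED_W = {
    ("gender", "out_strength"): (22.0, 23.0),
    ("gender", "in_strength"): (23.0, 22.0),
    ("gender", "betweenness"): (13.0, 15.0),
    ("gender", "closeness"): (18.0, 27.0),
    ("age", "out_strength"): (18.0, 27.0),
    ("age", "in_strength"): (14.0, 31.0),
    ("age", "betweenness"): (13.0, 15.0),
    ("age", "closeness"): (9.5, 35.5),
}

GROUPS = {"gender": GENDER, "age": AGE}
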