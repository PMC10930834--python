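"""Published reference panels for the packaged 31-batch dataset.

These are the efficiency and indicator tables distributed with the
dataset, as printed in its original report: four DEA score columns at
2 dp, the composite panel at 6 dp, descriptive statistics, and the
zootechnical panel.  The printed raw data are rounded (feed and weight
to whole units), so recomputed scores agree with these columns only up
to the propagation of that rounding; the tolerances used in the tests
state, per check, what the printed precision supports.
"""

# DMU: (CCR-input, CCR-output, BCC-input, BCC-output) at 2 dp
SCORES_2DP = {
    1: (0.96, 0.96, 0.97, 0.97), 2: (0.97, 0.97, 0.97, 0.97),
    3: (0.94, 0.94, 0.96, 0.95), 4: (1.00, 1.00, 1.00, 1.00),
    5: (0.96, 0.96, 0.98, 0.96), 6: (0.94, 0.94, 0.97, 0.95),
    7: (0.91, 0.91, 1.00, 1.00), 8: (0.94, 0.94, 0.97, 0.96),
    9: (0.97, 0.97, 0.98, 0.97), 10: (0.97, 0.97, 0.99, 0.97),
    11: (0.96, 0.96, 0.99, 0.96), 12: (0.98, 0.98, 0.98, 0.98),
    13: (0.98, 0.98, 0.99, 0.99), 14: (0.97, 0.97, 1.00, 1.00),
    15: (0.97, 0.97, 0.98, 0.97), 16: (0.96, 0.96, 0.99, 0.96),
    17: (0.94, 0.94, 0.98, 0.95), 18: (0.96, 0.96, 0.97, 0.97),
    19: (0.92, 0.92, 0.95, 0.94), 20: (0.93, 0.93, 0.95, 0.94),
    21: (0.97, 0.97, 0.97, 0.97), 22: (0.96, 0.96, 1.00, 1.00),
    23: (1.00, 1.00, 1.00, 1.00), 24: (0.95, 0.95, 0.99, 0.96),
    25: (0.97, 0.97, 1.00, 1.00), 26: (0.95, 0.95, 0.99, 0.95),
    27: (0.96, 0.96, 0.97, 0.97), 28: (0.95, 0.95, 1.00, 1.00),
    29: (0.97, 0.97, 0.98, 0.97), 30: (0.93, 0.93, 1.00, 1.00),
    31: (0.89, 0.89, 1.00, 1.00),
}

# DMU: (standard, inverted, composed, composed*) at 6 dp
COMPOSITE_6DP = {
    1: (0.959807, 0.957755, 0.501026, 0.912693),
    2: (0.973250, 0.921659, 0.525796, 0.957815),
    3: (0.935325, 0.970419, 0.482453, 0.878860),
    4: (1.000000, 0.902093, 0.548953, 1.000000),
    5: (0.962084, 0.927591, 0.517247, 0.942242),
    6: (0.935886, 0.956157, 0.489864, 0.892360),
    7: (0.907078, 0.996113, 0.455483, 0.829729),
    8: (0.939413, 0.953986, 0.492713, 0.897550),
    9: (0.966488, 0.924736, 0.520876, 0.948853),
    10: (0.972588, 0.926735, 0.522926, 0.952588),
    11: (0.956282, 0.939747, 0.508267, 0.825884),  # composed* inconsistent with composed/max
    12: (0.976155, 0.920622, 0.527766, 0.961405),
    13: (0.979087, 0.911807, 0.533640, 0.972105),
    14: (0.966129, 0.965768, 0.500181, 0.911154),
    15: (0.969787, 0.925749, 0.522019, 0.950935),
    16: (0.960873, 0.934861, 0.513006, 0.934516),
    17: (0.944959, 0.952938, 0.496011, 0.903557),
    18: (0.959922, 0.952485, 0.503718, 0.917598),
    19: (0.924950, 0.992131, 0.466409, 0.849634),
    20: (0.928560, 0.967473, 0.480544, 0.875382),
    21: (0.974344, 0.922017, 0.526163, 0.958485),
    22: (0.963735, 0.931735, 0.516000, 0.939971),
    23: (1.000000, 0.910863, 0.544569, 0.992013),
    24: (0.948484, 0.937486, 0.505499, 0.920841),
    25: (0.973003, 0.923468, 0.524768, 0.955942),
    26: (0.946381, 0.952680, 0.496851, 0.905087),
    27: (0.964462, 0.933268, 0.515597, 0.939237),
    28: (0.949421, 0.948954, 0.500234, 0.911250),
    29: (0.968435, 0.928197, 0.520119, 0.947474),
    30: (0.930697, 0.968508, 0.481095, 0.876385),
    31: (0.885687, 1.000000, 0.442843, 0.806705),
}

# statistic: (housing, age@0dp, feed, mortality%, cost, total_weight)
DESCRIPTIVE = {
    "mean": (513_000, 42, 2341, 5.10, 4.33, 1504),
    "median": (485_820, 42, 2270, 4.56, 4.33, 1446),
    "cv_pct": (55.83, 2.53, 56.71, 30.83, 2.23, 57.74),
    "max": (1_249_391, 45, 5940, 9.15, 4.57, 3956),
    "min": (74_668, 40, 325, 3.33, 4.06, 195),
}
#: decimals each column is printed with, per statistic group
DESCRIPTIVE_DECIMALS = (0, 0, 0, 2, 2, 0)

# DMU: (viability %, DWG g/day, feed conversion, PEF) in efficiency order
ZOOTECH = {
    4: (96.51, 76.13, 1.502, 488), 23: (96.49, 74.59, 1.463, 490),
    13: (93.50, 75.11, 1.518, 463), 12: (91.08, 74.01, 1.532, 440),
    21: (96.16, 68.70, 1.535, 430), 2: (96.18, 73.25, 1.534, 459),
    25: (96.67, 75.29, 1.537, 473), 10: (92.73, 74.68, 1.543, 449),
    15: (95.75, 74.52, 1.541, 463), 9: (92.63, 73.78, 1.539, 444),
    29: (96.15, 72.90, 1.545, 454), 5: (95.28, 72.20, 1.538, 447),
    22: (95.27, 74.54, 1.551, 458), 27: (95.81, 73.86, 1.553, 456),
    16: (96.44, 72.09, 1.556, 447), 11: (90.85, 73.63, 1.561, 428),
    24: (95.56, 71.64, 1.553, 441), 18: (94.88, 73.15, 1.585, 438),
    1: (95.42, 73.67, 1.594, 441), 28: (95.70, 70.36, 1.574, 428),
    14: (94.72, 69.44, 1.548, 425), 26: (95.00, 70.23, 1.574, 424),
    17: (95.31, 72.89, 1.586, 439), 8: (94.15, 71.33, 1.588, 423),
    6: (95.27, 71.60, 1.592, 429), 3: (95.58, 70.41, 1.615, 417),
    30: (95.58, 72.31, 1.612, 429), 20: (95.49, 69.79, 1.610, 414),
    19: (96.30, 67.94, 1.651, 396), 7: (91.94, 68.62, 1.616, 390),
    31: (93.35, 64.08, 1.665, 359),
}

CRS_FRONTIER = {4, 23}
VRS_INPUT_FRONTIER_COUNT = 9  # as published at 2 dp
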