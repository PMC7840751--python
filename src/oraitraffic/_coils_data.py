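"""Residue propensity table and Gaussian score calibration for CC scoring.

The propensity table gives, for each residue and each heptad position a–g,
the ratio of its frequency at that position in two-stranded coiled coils to
its overall database frequency (the classical sliding-window CC predictor's
newer table). Leucine at core positions a/d and glutamate at e/g dominate;
proline is incompatible with a continuous α-helix and sits near zero at all
positions.

The Gaussian calibration maps a window score to a CC-formation probability by
comparing two fitted score distributions — windows drawn from coiled coils vs
windows drawn from globular (background) sequence — weighted by a 30:1
globular prior. The constants below were fitted once by Monte Carlo under the
table's own generative reading (background composition for the globular
class; background × propensity for the CC class; 2×10⁵ windows per class) and
are frozen here; see docs/methods.md for the procedure.
"""

from __future__ import annotations

HEPTAD = "abcdefg"

# residue -> (a, b, c, d, e, f, g)
MTIDK: dict[str, tuple[float, ...]] = {
    "L": (2.998, 0.269, 0.367, 3.852, 0.510, 0.514, 0.562),
    "I": (2.408, 0.261, 0.345, 0.931, 0.402, 0.440, 0.289),
    "V": (1.525, 0.479, 0.350, 0.887, 0.286, 0.350, 0.362),
    "M": (2.161, 0.605, 0.442, 1.441, 0.607, 0.457, 0.570),
    "F": (0.490, 0.075, 0.391, 0.639, 0.125, 0.081, 0.038),
    "Y": (1.319, 0.064, 0.081, 1.526, 0.204, 0.118, 0.096),
    "G": (0.084, 0.215, 0.432, 0.111, 0.153, 0.367, 0.125),
    "A": (1.283, 1.364, 1.077, 2.219, 0.490, 1.265, 0.903),
    "K": (1.233, 2.194, 1.817, 0.611, 2.095, 1.686, 2.027),
    "R": (1.014, 1.476, 1.771, 0.114, 1.667, 2.006, 1.844),
    "H": (0.590, 0.646, 0.584, 0.842, 0.307, 0.611, 0.396),
    "E": (0.281, 3.351, 2.998, 0.789, 4.868, 2.735, 3.812),
    "D": (0.068, 2.103, 1.646, 0.182, 0.664, 1.581, 1.401),
    "Q": (0.311, 2.290, 2.330, 0.811, 2.596, 2.155, 2.585),
    "N": (1.231, 1.683, 2.157, 0.197, 1.653, 2.430, 2.065),
    "S": (0.332, 0.753, 0.930, 0.424, 0.734, 0.801, 0.518),
    "T": (0.197, 0.543, 0.647, 0.680, 0.905, 0.643, 0.808),
    "C": (0.918, 0.002, 0.385, 0.440, 0.138, 0.432, 0.079),
    "W": (0.066, 0.064, 0.065, 0.747, 0.006, 0.115, 0.014),
    "P": (0.004, 0.108, 0.018, 0.006, 0.010, 0.004, 0.007),
}

# Background amino-acid composition (database frequencies, fractions).
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

# Up-weighting exponent for the core heptad positions a and d when
# ad_weighting is on (the classical predictor's "weighted" mode).
AD_WEIGHT = 2.5

# Globular windows outnumber coiled-coil windows ~30:1 in the reference
# database; the probability is p = G_cc / (G_cc + PRIOR_RATIO * G_glob).
PRIOR_RATIO = 30.0

SUPPORTED_WINDOWS = (14, 21, 28)

# (matrix, window, ad_weighting) -> (m_cc, sd_cc, m_glob, sd_glob)
# Frozen Monte-Carlo fit, 2e5 windows per class (see module docstring).
GAUSSIAN_CALIBRATION: dict[tuple[str, int, bool], tuple[float, float, float, float]] = {
    ("mtidk", 14, False): (1.6237, 0.3138, 0.7787, 0.2349),
    ("mtidk", 21, False): (1.5992, 0.2614, 0.7248, 0.1830),
    ("mtidk", 28, False): (1.5908, 0.2286, 0.6955, 0.1541),
    ("mtidk", 14, True): (1.6491, 0.3379, 0.8582, 0.2458),
    ("mtidk", 21, True): (1.6180, 0.2855, 0.7852, 0.1928),
    ("mtidk", 28, True): (1.6051, 0.2521, 0.7446, 0.1622),
}
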