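"""Independent brute-force coiled-coil scorer used as the test oracle.

Deliberately naive: enumerates every window placement × heptad frame with
plain Python loops and computes weighted geometric means via logarithms,
sharing no code with the package implementation. Probability conversion uses
the same closed-form two-Gaussian ratio evaluated with math.exp directly.
"""

import math

from oraitraffic._coils_data import (
    AD_WEIGHT,
    GAUSSIAN_CALIBRATION,
    MTIDK,
    PRIOR_RATIO,
)

FLOOR = 1e-4


def brute_force_scores(residues: str, window: int, ad_weighting: bool) -> list[float]:
    n = len(residues)
    assert n >= window
    best = [0.0] * n
    for start in range(n - window + 1):
        for frame in range(7):
            log_sum = 0.0
            weight_sum = 0.0
            for j in range(window):
                heptad_pos = (frame + j) % 7
                w = AD_WEIGHT if (ad_weighting and heptad_pos in (0, 3)) else 1.0
                prop = max(MTIDK[residues[start + j]][heptad_pos], FLOOR)
                log_sum += w * math.log(prop)
                weight_sum += w
            score = math.exp(log_sum / weight_sum)
            for j in range(window):
                if score > best[start + j]:
                    best[start + j] = score
    return best


def brute_force_probability(score: float, window: int, ad_weighting: bool,
                            matrix: str = "mtidk") -> float:
    m_cc, sd_cc, m_g, sd_g = GAUSSIAN_CALIBRATION[(matrix, window, ad_weighting)]
    g_cc = math.exp(-0.5 * ((score - m_cc) / sd_cc) ** 2) / sd_cc
    g_g = math.exp(-0.5 * ((score - m_g) / sd_g) ** 2) / sd_g
    return g_cc / (g_cc + PRIOR_RATIO * g_g)
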