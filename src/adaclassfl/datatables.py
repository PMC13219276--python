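"""Published class and client distribution tables for the CCMT crop-disease
benchmark (maize and tomato subsets, augmented release).

These printed counts serve two purposes: they parameterize the synthetic
generator's default class imbalance, and they are the arithmetic fixtures for
the class-weight and heterogeneity-summary calculations.
"""

from __future__ import annotations

import numpy as np

# class name -> (train, test) counts, augmented CCMT maize subset
CCMT_MAIZE_COUNTS: dict[str, tuple[int, int]] = {
    "fall_armyworm": (1140, 284),
    "grasshopper": (2575, 411),
    "healthy": (830, 211),
    "leaf_beetle": (3789, 950),
    "leaf_blight": (4025, 1004),
    "leaf_spot": (3024, 1261),
    "streak_virus": (4043, 1004),
}

CCMT_TOMATO_COUNTS: dict[str, tuple[int, int]] = {
    "healthy": (2000, 500),
    "leaf_blight": (5200, 1309),
    "leaf_curl": (2050, 532),
    "septoria_leaf_spot": (9373, 2340),
    "verticillium_wilt": (3100, 764),
}

# Per-client sample counts and Jensen-Shannon divergences for the published
# 10-client Dirichlet(alpha=1.0) split of the tomato subset.
CCMT_TOMATO_CLIENT_SAMPLES = np.array(
    [2383, 3054, 2046, 2033, 2956, 1971, 1930, 1352, 2546, 886])
CCMT_TOMATO_CLIENT_JS = np.array(
    [0.214, 0.213, 0.052, 0.138, 0.289, 0.047, 0.281, 0.098, 0.108, 0.025])


def class_totals(counts: dict[str, tuple[int, int]]) -> dict[str, int]:
    return {name: tr + te for name, (tr, te) in counts.items()}


def class_proportions(counts: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Each class's share of the full (train+test) dataset, in percent."""
    totals = class_totals(counts)
    grand = sum(totals.values())
    return {name: 100.0 * n / grand for name, n in totals.items()}


def train_counts(counts: dict[str, tuple[int, int]]) -> np.ndarray:
    return np.array([tr for tr, _ in counts.values()])


def maize_priors() -> np.ndarray:
    """Empirical class prior vector of the maize subset (7 classes)."""
    totals = np.array(list(class_totals(CCMT_MAIZE_COUNTS).values()), float)
    return totals / totals.sum()
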