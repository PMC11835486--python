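"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mircompete import (
    SpeciesSpec,
    SystemConfig,
    WT_RATES,
    competition_panel,
    parse_hairpin,
)
from mircompete.bpp import CANONICAL_PAIRS
from mircompete.kinetics import derivatives


@pytest.fixture
def wt_config() -> SystemConfig:
    """The single-species in-vitro condition: 1 nM pre-miRNA, 5 nM Dicer."""
    return SystemConfig(species=(SpeciesSpec("wt", 1.0, WT_RATES),), D0=5.0)


@pytest.fixture
def panel() -> SystemConfig:
    return competition_panel()


@pytest.fixture
def perfect_stem_hairpin():
    """Arm length 8, fully paired stem, loop of 4."""
    L, loop = 8, 4
    seq = "GGGGGGGG" + "AAAA" + "CCCCCCCC"
    struct = "(" * L + "." * loop + ")" * L
    return parse_hairpin("perfect", seq, struct, (0, L), (L + loop, 2 * L + loop))


@pytest.fixture
def loop_only_hairpin():
    """All pairs lie inside the loop region; no inter-arm bonds."""
    #      arms: [0,4) and [10,14); the only pair is within [4,10)
    seq = "AAAA" + "GGCC" + "UU" + "AAAA"
    struct = "...." + "((.." + "))" + "...."
    return parse_hairpin("loop-only", seq, struct, (0, 4), (10, 14))


@pytest.fixture
def bulge_hairpin():
    """One internal bulge on the 5' arm: bond count = arm length - 1.

    5' arm GGAGG (position 2 bulged, unpaired), loop AAAA, 3' arm CCCC.
    Pairs by hand: (0,13) (1,12) (3,10) (4,9) -> arm-local
    (0,4) (1,3) (3,1) (4,0); 3'-arm position 2 never pairs.
    """
    seq = "GGAGG" + "AAAA" + "CCCCC"
    struct = "((.((" + "...." + ")).))"
    return parse_hairpin("bulge", seq, struct, (0, 5), (9, 14))


def brute_force_pair_probs(seq5: str, seq3: str) -> np.ndarray:
    """Exhaustive enumeration of all non-crossing inter-strand matchings.

    Antiparallel orientation: for pairs (i1,j1), (i2,j2), i1 < i2 implies
    j1 > j2. Each matching has unit weight; returns per-pair probabilities.
    """
    n5, n3 = len(seq5), len(seq3)
    candidates = [
        (i, j)
        for i in range(n5)
        for j in range(n3)
        if (seq5[i], seq3[j]) in CANONICAL_PAIRS
    ]
    counts = np.zeros((n5, n3))
    matchings: list[list] = []

    def collect(chosen: list, start: int) -> None:
        matchings.append(list(chosen))
        for idx, (i, j) in enumerate(candidates[start:], start):
            if all(i != a and j != b and (i - a) * (j - b) < 0 for a, b in chosen):
                chosen.append((i, j))
                collect(chosen, idx + 1)
                chosen.pop()

    collect([], 0)
    for m in matchings:
        for i, j in m:
            counts[i, j] += 1
    return counts / len(matchings)


def rk4_integrate(config: SystemConfig, t_end: float, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta integration; independent of scipy."""
    y = config.initial_state()
    n_steps = int(np.ceil(t_end / dt))
    h = t_end / n_steps
    for _ in range(n_steps):
        k1 = derivatives(y, config)
        k2 = derivatives(y + 0.5 * h * k1, config)
        k3 = derivatives(y + 0.5 * h * k2, config)
        k4 = derivatives(y + h * k3, config)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
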