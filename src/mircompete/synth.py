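"""Synthetic-data generators for every input the analysis stages consume.

Three generators, all seeded and bit-reproducible:

- :func:`gen_dicing_timeseries` — noisy diced-fraction time courses from
  known rate constants, emulating the in-vitro assay the kinetic model is
  fitted to (1 nM pre-miRNA, 5 nM Dicer, 60 min);
- :func:`gen_hairpin_dataset` — random pre-miRNA hairpins whose stem
  pairing strength is controlled by a single parameter theta (the
  probability that a stem position carries a Watson-Crick/GU pair), giving
  the BPP pipeline fixtures with a tunable AUC gradient;
- :func:`gen_expression` — two-genotype expression tables in which log10
  expression depends linearly on the AUC score with genotype-specific
  slopes, the generative twin of the association regressions.

Noise on dicing fractions is additive Gaussian (default sd 0.02, roughly
gel-quantification error); values are clipped to the [-0.05, 1.05] validity
band so small negative noise is reported rather than hidden. Expression is
in arbitrary normalized units with Gaussian noise on the log10 scale; no
count-level noise model is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bpp import CANONICAL_PAIRS, HairpinRecord
from .fitting import TimeSeriesData, model_diced_fraction
from .kinetics import RateSet, WT_RATES
from .stats import ExpressionTable

__all__ = [
    "DicingSimSpec",
    "HairpinSimSpec",
    "ExpressionSimSpec",
    "gen_dicing_timeseries",
    "gen_hairpin_dataset",
    "gen_expression",
]

_WC_PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))
_GU_PAIRS = (("G", "U"), ("U", "G"))
_BASES = "ACGU"


@dataclass
class DicingSimSpec:
    """Ground truth for a simulated dicing assay.

    The default sampling grid is 20 log-spaced time points from 15 s to
    60 min: with the fitted rates the binding/stalling transient is over
    within the first minute, so a grid that only samples late times carries
    no information about the depletion rate. Gel time courses likewise
    concentrate early points.
    """

    rates: RateSet = WT_RATES
    P0: float = 1.0
    D0: float = 5.0
    times_min: np.ndarray = field(default_factory=lambda: np.geomspace(0.25, 60.0, 20))
    noise_sd: float = 0.02
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("time grid must be strictly ascending")


def gen_dicing_timeseries(spec: DicingSimSpec) -> TimeSeriesData:
    """Model diced fractions plus Gaussian noise, clipped to [-0.05, 1.05]."""
    fractions = model_diced_fraction(spec.rates, spec.P0, spec.D0, spec.times_min)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fractions = fractions + rng.normal(0.0, spec.noise_sd, size=fractions.shape)
        fractions = np.clip(fractions, -0.05, 1.05)
    return TimeSeriesData(
        times_min=spec.times_min.copy(),
        diced_fraction=fractions,
        P0=spec.P0,
        D0=spec.D0,
        label=spec.label,
    )


@dataclass
class HairpinSimSpec:
    """Random-hairpin generator settings.

    ``theta`` is the probability that each stem position carries an
    inter-arm pair (drawn from Watson-Crick pairs, a ``gu_frac`` share of
    them GU); unpaired stem positions become mismatches.
    """

    n: int = 50
    arm_len: tuple[int, int] = (18, 25)
    loop_len: tuple[int, int] = (4, 12)
    theta: float = 0.7
    gu_frac: float = 0.1
    seed: int = 0
    id_prefix: str = "syn-mir"

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if self.arm_len[0] < 1 or self.loop_len[0] < 1:
            raise ValueError("arm and loop lengths must be >= 1")
        if self.arm_len[0] > self.arm_len[1] or self.loop_len[0] > self.loop_len[1]:
            raise ValueError("length ranges must be (lo, hi) with lo <= hi")


def _random_mismatch(rng: np.random.Generator) -> tuple[str, str]:
    while True:
        a, b = rng.choice(list(_BASES), size=2)
        if (a, b) not in CANONICAL_PAIRS:
            return str(a), str(b)


def gen_hairpin_dataset(spec: HairpinSimSpec) -> list[HairpinRecord]:
    """Generate ``spec.n`` hairpins with stem positions paired w.p. theta.

    Each hairpin is 5'-arm + loop + 3'-arm; stem position p on the 5' arm
    faces position (arm_len-1-p) of the 3' arm. Paired positions get a
    canonical pair and matching brackets; unpaired positions a mismatch and
    dots. All records parse cleanly as :class:`HairpinRecord`.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for k in range(spec.n):
        L = int(rng.integers(spec.arm_len[0], spec.arm_len[1] + 1))
        loop = int(rng.integers(spec.loop_len[0], spec.loop_len[1] + 1))
        arm5 = [""] * L
        arm3 = [""] * L  # indexed by 3'-arm local position
        struct5 = ["."] * L
        struct3 = ["."] * L
        for p in range(L):
            partner = L - 1 - p
            if rng.random() < spec.theta:
                pool = _GU_PAIRS if rng.random() < spec.gu_frac else _WC_PAIRS
                a, b = pool[int(rng.integers(len(pool)))]
                arm5[p], arm3[partner] = a, b
                struct5[p], struct3[partner] = "(", ")"
            else:
                a, b = _random_mismatch(rng)
                arm5[p], arm3[partner] = a, b
        loop_seq = "".join(rng.choice(list(_BASES), size=loop))
        sequence = "".join(arm5) + loop_seq + "".join(arm3)
        structure = "".join(struct5) + "." * loop + "".join(struct3)
        records.append(
            HairpinRecord(
                id=f"{spec.id_prefix}-{k:04d}",
                sequence=sequence,
                structure=structure,
                arm5=(0, L),
                arm3=(L + loop, 2 * L + loop),
            )
        )
    return records


@dataclass
class ExpressionSimSpec:
    """Linear generative model of log10 expression per genotype.

    ``params`` maps genotype name to (intercept alpha, slope beta):
    log10 expression = alpha + beta * auc + Normal(0, noise_sd).
    """

    params: Mapping[str, tuple[float, float]]
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.params:
            raise ValueError("need at least one genotype")


def gen_expression(aucs: pd.DataFrame, spec: ExpressionSimSpec) -> ExpressionTable:
    """Expression table with log10 expression linear in AUC per genotype."""
    if "id" not in aucs.columns or "auc" not in aucs.columns:
        raise ValueError("aucs must have 'id' and 'auc' columns")
    if len(aucs) < 3:
        raise ValueError("need at least 3 miRNAs")
    rng = np.random.default_rng(spec.seed)
    x = aucs["auc"].to_numpy(dtype=float)
    data = {"id": aucs["id"].to_numpy()}
    for genotype, (alpha, beta) in spec.params.items():
        log10_expr = alpha + beta * x
        if spec.noise_sd > 0:
            log10_expr = log10_expr + rng.normal(0.0, spec.noise_sd, size=x.shape)
        data[genotype] = 10.0**log10_expr
    return ExpressionTable(pd.DataFrame(data))
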