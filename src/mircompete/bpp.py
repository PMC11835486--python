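"""Base-pair-probability scoring of mature miRNA duplexes.

TRBP, the protein that loads pre-miRNAs onto Dicer, preferentially binds
hairpins with strongly paired stems. This module turns a pre-miRNA hairpin
(sequence, dot-bracket structure, mature 5'/3' arm coordinates) into a
scalar proxy for that affinity:

1. extract the mature duplex — the two arm subsequences plus the base-pair
   bonds the hairpin structure records between them;
2. co-fold the two strands and read off the equilibrium probability of each
   recorded bond (positions without a recorded bond get the mean pairing
   probability of that nucleotide over all candidate partners);
3. lay the probabilities out on a cleavage-centred position axis (negative
   positions on the 5' strand, positive on the 3' strand) and integrate —
   the area under this curve (AUC) is the affinity proxy.

Two co-folding engines are available behind one interface. The built-in
:class:`ReferenceCofoldEngine` computes exact pairing probabilities under a
uniform-weight partition function over all non-crossing inter-strand
matchings (every Watson-Crick or GU pair weighs 1): combinatorial rather
than thermodynamic, but exactly testable against brute-force enumeration.
:class:`ViennaCofoldEngine` substitutes the full Turner-model RNAcofold
ensemble when the ViennaRNA python bindings are importable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_PAIRS",
    "HairpinRecord",
    "MatureDuplex",
    "PairProbMatrix",
    "BppCurve",
    "AucRecord",
    "HairpinParseError",
    "parse_hairpin",
    "pair_table",
    "extract_mature_duplex",
    "ReferenceCofoldEngine",
    "ViennaCofoldEngine",
    "cofold_bpp",
    "bpp_curve",
    "apply_cohort_fill",
    "auc",
    "score_hairpins",
]

#: Allowed base pairs: Watson-Crick plus GU wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

_RNA_ALPHABET = frozenset("ACGU")


class HairpinParseError(ValueError):
    """A hairpin record failed validation; the message names the record."""


@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA hairpin with annotated mature arms.

    ``arm5`` and ``arm3`` are 0-based half-open intervals on ``sequence``;
    the 5' arm must precede the 3' arm without overlap.
    """

    id: str
    sequence: str
    structure: str
    arm5: tuple[int, int]
    arm3: tuple[int, int]

    def __post_init__(self) -> None:
        rid = self.id
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise HairpinParseError(f"{rid}: non-RNA characters {sorted(bad)} in sequence")
        if len(self.structure) != len(self.sequence):
            raise HairpinParseError(
                f"{rid}: structure length {len(self.structure)} != sequence "
                f"length {len(self.sequence)}"
            )
        try:
            pair_table(self.structure)
        except ValueError as e:
            raise HairpinParseError(f"{rid}: {e}") from e
        n = len(self.sequence)
        for name, (a, b) in (("arm5", self.arm5), ("arm3", self.arm3)):
            if not (0 <= a < b <= n):
                raise HairpinParseError(f"{rid}: {name}=[{a},{b}) outside sequence of length {n}")
        if self.arm5[1] > self.arm3[0]:
            raise HairpinParseError(
                f"{rid}: arm5 {self.arm5} must precede arm3 {self.arm3} without overlap"
            )

    @property
    def seq5(self) -> str:
        return self.sequence[self.arm5[0] : self.arm5[1]]

    @property
    def seq3(self) -> str:
        return self.sequence[self.arm3[0] : self.arm3[1]]


def parse_hairpin(
    id: str,
    sequence: str,
    structure: str,
    arm5: tuple[int, int],
    arm3: tuple[int, int],
) -> HairpinRecord:
    """Validate one hairpin record (DNA-style T is accepted and converted)."""
    sequence = sequence.strip().upper().replace("T", "U")
    return HairpinRecord(
        id=str(id),
        sequence=sequence,
        structure=structure.strip(),
        arm5=(int(arm5[0]), int(arm5[1])),
        arm3=(int(arm3[0]), int(arm3[1])),
    )


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions).

    Raises ``ValueError`` on unbalanced brackets or characters other than
    ``(``, ``)``, ``.``. Nested parentheses cannot cross by construction.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class MatureDuplex:
    """The two mature arm strands plus the hairpin's recorded inter-arm bonds.

    Bonds are (i5, j3) pairs in arm-local coordinates: i5 indexes ``seq5``
    5'->3', j3 indexes ``seq3`` 5'->3'. In an antiparallel duplex, bonds
    nest: i5 increasing implies j3 decreasing.
    """

    id: str
    seq5: str
    seq3: str
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n5, n3 = len(self.seq5), len(self.seq3)
        seen5, seen3 = set(), set()
        for i, j in self.bonds:
            if not (0 <= i < n5 and 0 <= j < n3):
                raise ValueError(f"{self.id}: bond ({i},{j}) out of range")
            if i in seen5 or j in seen3:
                raise ValueError(f"{self.id}: position used by more than one bond")
            seen5.add(i)
            seen3.add(j)
        ordered = sorted(self.bonds)
        for (i1, j1), (i2, j2) in zip(ordered, ordered[1:]):
            if j1 <= j2:
                raise ValueError(
                    f"{self.id}: bonds ({i1},{j1}) and ({i2},{j2}) cross under the "
                    "antiparallel duplex orientation"
                )


def extract_mature_duplex(h: HairpinRecord) -> MatureDuplex:
    """Pull the mature duplex out of a hairpin.

    Recorded bonds are exactly the structure pairs with one end in each arm,
    re-indexed to arm-local coordinates. A hairpin whose pairs all lie
    within the loop or a single arm yields an empty bond list (allowed; the
    downstream fill rule then covers every position).
    """
    pairs = pair_table(h.structure)
    a5, a3 = h.arm5, h.arm3
    bonds = []
    for i in range(a5[0], a5[1]):
        j = pairs.get(i)
        if j is not None and a3[0] <= j < a3[1]:
            bonds.append((i - a5[0], j - a3[0]))
    return MatureDuplex(id=h.id, seq5=h.seq5, seq3=h.seq3, bonds=tuple(bonds))


@dataclass
class PairProbMatrix:
    """Inter-strand pairing probabilities: ``probs[i, j] = P(seq5[i] pairs seq3[j])``."""

    probs: np.ndarray
    engine: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ValueError("pair probabilities must lie in [0, 1]")
        tol = 1e-9
        if p.sum(axis=1).max(initial=0.0) > 1 + tol or p.sum(axis=0).max(initial=0.0) > 1 + tol:
            raise ValueError("marginal pairing probability exceeds 1")
        self.probs = np.clip(p, 0.0, 1.0)


class CofoldEngine(Protocol):
    name: str

    def pair_probabilities(self, seq5: str, seq3: str) -> np.ndarray: ...


def _allowed_matrix(seq5: str, seq3: str) -> np.ndarray:
    return np.array(
        [[(a, b) in CANONICAL_PAIRS for b in seq3] for a in seq5], dtype=bool
    )


class ReferenceCofoldEngine:
    """Uniform-weight partition function over non-crossing inter-strand matchings.

    A matching pairs distinct 5'-strand positions with distinct 3'-strand
    positions such that pairs nest antiparallel (i increasing => j
    decreasing), each allowed pair contributing weight 1. Pairing
    probabilities are exact ratios of matching counts, computed by dynamic
    programming in O(n5 * n3 * n3).
    """

    name = "reference"

    def pair_probabilities(self, seq5: str, seq3: str) -> np.ndarray:
        if not seq5 or not seq3:
            raise ValueError("both strands must be non-empty")
        bad = (set(seq5) | set(seq3)) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters {sorted(bad)}")
        n5, n3 = len(seq5), len(seq3)
        ok = _allowed_matrix(seq5, seq3)

        # Z[i][j+1] = number of matchings between seq5[i:] and seq3[0..j]
        # (pairs taken by later 5' positions use earlier 3' positions).
        Z = np.zeros((n5 + 1, n3 + 1))
        Z[n5, :] = 1.0
        for i in range(n5 - 1, -1, -1):
            Z[i, 0] = Z[i + 1, 0]
            for j in range(n3):
                Z[i, j + 1] = Z[i + 1, j + 1]  # i unpaired
                for jp in range(j + 1):
                    if ok[i, jp]:
                        Z[i, j + 1] += Z[i + 1, jp]
        # O[i][j] = number of matchings between seq5[:i] and seq3[j:] —
        # the region outside a pair (i, j-1).
        O = np.zeros((n5 + 1, n3 + 1))
        O[0, :] = 1.0
        for i in range(1, n5 + 1):
            O[i, n3] = O[i - 1, n3]
            for j in range(n3 - 1, -1, -1):
                O[i, j] = O[i - 1, j]  # position i-1 unpaired
                for jp in range(j, n3):
                    if ok[i - 1, jp]:
                        O[i, j] += O[i - 1, jp + 1]

        total = Z[0, n3]
        probs = np.zeros((n5, n3))
        for i in range(n5):
            for j in range(n3):
                if ok[i, j]:
                    probs[i, j] = O[i, j + 1] * Z[i + 1, j] / total
        return probs


class ViennaCofoldEngine:
    """Thermodynamic engine: RNAcofold ensemble via the ViennaRNA bindings.

    Returns the inter-strand block of the equilibrium base-pair probability
    matrix of the two-strand ensemble.
    """

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as e:  # pragma: no cover
            raise ImportError(
                "the ViennaRNA python bindings are required for the 'vienna' engine"
            ) from e
        self._RNA = RNA
        self.name = f"viennarna-{getattr(RNA, '__version__', 'unknown')}"

    def pair_probabilities(self, seq5: str, seq3: str) -> np.ndarray:
        RNA = self._RNA
        fc = RNA.fold_compound(f"{seq5}&{seq3}")
        fc.pf()
        bpp = np.asarray(fc.bpp())  # 1-based, upper-triangular
        n5 = len(seq5)
        inter = bpp[1 : n5 + 1, n5 + 1 :]
        return np.clip(inter, 0.0, 1.0)


def cofold_bpp(d: MatureDuplex, engine: CofoldEngine | None = None) -> PairProbMatrix:
    """Co-fold the duplex strands and return inter-strand pairing probabilities."""
    if engine is None:
        engine = ReferenceCofoldEngine()
    probs = engine.pair_probabilities(d.seq5, d.seq3)
    if probs.shape != (len(d.seq5), len(d.seq3)):
        raise ValueError(
            f"engine returned shape {probs.shape}, expected ({len(d.seq5)}, {len(d.seq3)})"
        )
    return PairProbMatrix(probs=probs, engine=engine.name)


@dataclass
class BppCurve:
    """Per-position pairing probability on the cleavage-centred axis.

    Positions are negative on the 5' strand and positive on the 3' strand;
    the loop-proximal 5' position is -1, the loop-proximal 3' position is
    +1, and 0 (the cleavage site) is an empty marker carrying no value.
    ``filled`` flags positions whose value came from the mean-fill rule
    rather than a recorded bond.
    """

    id: str
    positions: np.ndarray
    bpp: np.ndarray
    filled: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.bpp = np.asarray(self.bpp, dtype=float)
        self.filled = np.asarray(self.filled, dtype=bool)
        if not (self.positions.shape == self.bpp.shape == self.filled.shape):
            raise ValueError("positions, bpp and filled must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        finite = self.bpp[np.isfinite(self.bpp)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("bpp values must lie in [0, 1]")

    @property
    def n_filled(self) -> int:
        return int(self.filled.sum())


@dataclass(frozen=True)
class AucRecord:
    id: str
    auc: float
    n_bonds: int = 0
    n_filled: int = 0
    span: int = 0  # extent of the position axis; auc/span is the mean-BPP scale

    @property
    def auc_norm(self) -> float:
        """AUC divided by the position span: a mean pairing probability in [0, 1]."""
        if self.span <= 0:
            raise ValueError(f"{self.id}: span not set")
        return self.auc / self.span


def bpp_curve(
    m: PairProbMatrix, d: MatureDuplex, *, fill: str = "per-partner-mean"
) -> BppCurve:
    """Lay pairing probabilities along the cleavage-centred position axis.

    A 5' position with a recorded bond (i, j) takes the probability of that
    bond, and its partner position on the 3' strand takes the same value.
    Positions without a recorded bond take the mean probability over all
    candidate partners on the opposite strand (``fill='per-partner-mean'``),
    or NaN (``fill='none'``) for later cohort-level filling.
    """
    if fill not in ("per-partner-mean", "none"):
        raise ValueError(f"unknown fill mode {fill!r}")
    p = m.probs
    n5, n3 = p.shape
    if (n5, n3) != (len(d.seq5), len(d.seq3)):
        raise ValueError("matrix dimensions do not match the duplex")
    bond5 = dict(d.bonds)
    bond3 = {j: i for i, j in d.bonds}

    # 5' arm: local index i sits at axis position i - n5 (loop-proximal end
    # of the 5' arm, i = n5-1, at -1); 3' arm: local index j at j + 1.
    positions = np.concatenate([np.arange(-n5, 0), np.arange(1, n3 + 1)])
    values = np.empty(n5 + n3)
    filled = np.zeros(n5 + n3, dtype=bool)
    for i in range(n5):
        if i in bond5:
            values[i] = p[i, bond5[i]]
        else:
            values[i] = p[i, :].mean() if fill == "per-partner-mean" else np.nan
            filled[i] = True
    for j in range(n3):
        if j in bond3:
            values[n5 + j] = p[bond3[j], j]
        else:
            values[n5 + j] = p[:, j].mean() if fill == "per-partner-mean" else np.nan
            filled[n5 + j] = True
    return BppCurve(id=d.id, positions=positions, bpp=values, filled=filled)


def apply_cohort_fill(curves: Iterable[BppCurve]) -> list[BppCurve]:
    """Replace NaN curve values with the cohort mean at each axis position.

    The alternative fill rule: positions lacking a recorded bond take the
    mean of the recorded-bond probabilities observed at the same axis
    position across the whole cohort. Positions with no cohort information
    at all fall back to 0.
    """
    curves = list(curves)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for c in curves:
        for pos, val, was_filled in zip(c.positions, c.bpp, c.filled):
            if not was_filled and np.isfinite(val):
                sums[int(pos)] = sums.get(int(pos), 0.0) + float(val)
                counts[int(pos)] = counts.get(int(pos), 0) + 1
    out = []
    for c in curves:
        vals = c.bpp.copy()
        for k, (pos, val) in enumerate(zip(c.positions, vals)):
            if not np.isfinite(val):
                pos = int(pos)
                vals[k] = sums[pos] / counts[pos] if counts.get(pos) else 0.0
        out.append(BppCurve(id=c.id, positions=c.positions, bpp=vals, filled=c.filled))
    return out


def auc(c: BppCurve) -> AucRecord:
    """Trapezoidal area under the curve over its position axis."""
    if c.positions.size < 2:
        raise ValueError(f"{c.id}: AUC needs at least 2 positions")
    if not np.all(np.isfinite(c.bpp)):
        raise ValueError(f"{c.id}: curve has unfilled (NaN) values; fill before AUC")
    area = float(np.trapezoid(c.bpp, c.positions))
    n_bonds = int((~c.filled).sum()) // 2
    span = int(c.positions[-1] - c.positions[0])
    return AucRecord(id=c.id, auc=area, n_bonds=n_bonds, n_filled=c.n_filled, span=span)


def score_hairpins(
    records: Iterable[HairpinRecord],
    *,
    engine: CofoldEngine | None = None,
    fill: str = "per-partner-mean",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """End-to-end: hairpins -> duplexes -> BPP curves -> AUC table.

    Returns ``(scores, excluded)`` where scores has columns
    ``id, auc, n_bonds, n_filled`` and excluded lists ``(id, reason)`` for
    records that failed validation or duplex extraction.
    """
    if engine is None:
        engine = ReferenceCofoldEngine()
    rows, excluded = [], []
    if fill == "cohort-mean":
        pending = []
        for h in records:
            try:
                d = extract_mature_duplex(h)
                pending.append((d, bpp_curve(cofold_bpp(d, engine), d, fill="none")))
            except (HairpinParseError, ValueError) as e:
                excluded.append((h.id, str(e)))
        for (d, _), c in zip(pending, apply_cohort_fill([c for _, c in pending])):
            rec = auc(c)
            rows.append(
                {
                    "id": rec.id,
                    "auc": rec.auc,
                    "auc_norm": rec.auc_norm,
                    "n_bonds": rec.n_bonds,
                    "n_filled": rec.n_filled,
                    "span": rec.span,
                }
            )
    else:
        for h in records:
            try:
                d = extract_mature_duplex(h)
                rec = auc(bpp_curve(cofold_bpp(d, engine), d, fill=fill))
            except (HairpinParseError, ValueError) as e:
                excluded.append((h.id, str(e)))
                continue
            rows.append(
                {
                    "id": rec.id,
                    "auc": rec.auc,
                    "auc_norm": rec.auc_norm,
                    "n_bonds": rec.n_bonds,
                    "n_filled": rec.n_filled,
                    "span": rec.span,
                }
            )
    return pd.DataFrame(rows, columns=["id", "auc", "auc_norm", "n_bonds", "n_filled", "span"]), excluded
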