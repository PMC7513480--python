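"""Kimura 2-parameter (K2P) distances with pairwise deletion.

For an aligned pair, sites where either residue is a gap or any non-ACGT
ambiguity code are excluded (pairwise deletion). With P the transition
proportion (A<->G, C<->T) and Q the transversion proportion over the
compared sites,

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

A pair with zero comparable sites is *undefined*; a pair where the log
argument is non-positive is *saturated*. Both are flagged (NaN in the
matrix), never coerced to a number, and excluded from downstream means.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import AlignedSet, LabeledSequence

log = logging.getLogger(__name__)

__all__ = [
    "PairStatus",
    "PairwiseComparison",
    "K2PResult",
    "DistanceMatrix",
    "compare_pair",
    "k2p_from_pq",
    "k2p",
    "build_matrix",
]

# Encoding: A=0, C=1, G=2, T=3 -- chosen so x ^ y == 2 exactly for the two
# transition pairs (A,G) and (C,T). Anything else is 255 (excluded site).
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8; non-ACGT (gaps, ambiguities) become 255."""
    return _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


class PairStatus(enum.Enum):
    OK = "ok"
    NO_SITES = "no_sites"          # zero comparable sites
    SATURATED = "saturated"        # K2P log argument <= 0


@dataclass(frozen=True)
class PairwiseComparison:
    """Counts underlying one K2P evaluation."""

    sites_compared: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.sites_compared if self.sites_compared else math.nan

    @property
    def Q(self) -> float:
        return self.transversions / self.sites_compared if self.sites_compared else math.nan


@dataclass(frozen=True)
class K2PResult:
    distance: float                # NaN unless status is OK
    status: PairStatus
    comparison: PairwiseComparison


def compare_pair(a: np.ndarray | str, b: np.ndarray | str) -> PairwiseComparison:
    """Count compared sites, transitions and transversions under pairwise deletion."""
    x = encode(a) if isinstance(a, str) else a
    y = encode(b) if isinstance(b, str) else b
    if x.shape != y.shape:
        raise ValueError("sequences must be aligned to equal length")
    valid = (x != 255) & (y != 255)
    diff = valid & (x != y)
    ts = diff & ((x ^ y) == 2)
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return PairwiseComparison(
        sites_compared=int(valid.sum()),
        transitions=n_ts,
        transversions=n_diff - n_ts,
    )


def k2p_from_pq(P: float, Q: float) -> tuple[float, PairStatus]:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, PairStatus.SATURATED
    return -0.5 * math.log(w1 * math.sqrt(w2)), PairStatus.OK


def k2p(a: LabeledSequence | str, b: LabeledSequence | str) -> float:
    """K2P distance between two aligned sequences; NaN when undefined.

    Use :func:`k2p_detail` when the undefined/saturated distinction matters.
    """
    return k2p_detail(a, b).distance


def k2p_detail(a: LabeledSequence | str, b: LabeledSequence | str) -> K2PResult:
    sa = a.residues if isinstance(a, LabeledSequence) else a
    sb = b.residues if isinstance(b, LabeledSequence) else b
    cmp = compare_pair(sa, sb)
    if cmp.sites_compared == 0:
        return K2PResult(math.nan, PairStatus.NO_SITES, cmp)
    d, status = k2p_from_pq(cmp.P, cmp.Q)
    if status is PairStatus.OK and cmp.transitions == 0 and cmp.transversions == 0:
        d = 0.0
    return K2PResult(d, status, cmp)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with flagged undefined entries.

    ``values`` holds NaN for undefined pairs; ``flags`` records why
    (keyed by the index pair (i, j), i < j).
    """

    labels: list[str]
    values: np.ndarray
    flags: dict[tuple[int, int], PairStatus]

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        return len(self.flags)

    def defined_pairs(self):
        """Yield (label_i, label_j, distance) for every defined pair i < j."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                d = self.values[i, j]
                if not math.isnan(d):
                    yield self.labels[i], self.labels[j], float(d)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with row and column labels; undefined entries are 'NA'."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.6f}" for v in self.values[i]
                ]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format (undefined entries written as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                cells = [
                    "-1.000000" if math.isnan(v) else f"{v:.6f}"
                    for v in self.values[i]
                ]
                fh.write(f"{lab:<10s} " + " ".join(cells) + "\n")


def build_matrix(aln: AlignedSet) -> DistanceMatrix:
    """All-pairs K2P matrix over an alignment; undefined pairs flagged and logged."""
    n = len(aln)
    enc = np.stack([encode(r.residues) for r in aln.records])
    values = np.zeros((n, n))
    flags: dict[tuple[int, int], PairStatus] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = _k2p_encoded(enc[i], enc[j])
            values[i, j] = values[j, i] = res.distance
            if res.status is not PairStatus.OK:
                flags[(i, j)] = res.status
    if flags:
        log.warning(
            "%d of %d pairs undefined (%s)",
            len(flags),
            n * (n - 1) // 2,
            ", ".join(f"{s.value}: {sum(1 for v in flags.values() if v is s)}"
                      for s in set(flags.values())),
        )
    return DistanceMatrix(labels=aln.labels, values=values, flags=flags)


def _k2p_encoded(x: np.ndarray, y: np.ndarray) -> K2PResult:
    cmp = compare_pair(x, y)
    if cmp.sites_compared == 0:
        return K2PResult(math.nan, PairStatus.NO_SITES, cmp)
    if cmp.transitions == 0 and cmp.transversions == 0:
        return K2PResult(0.0, PairStatus.OK, cmp)
    d, status = k2p_from_pq(cmp.P, cmp.Q)
    return K2PResult(d, status, cmp)
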