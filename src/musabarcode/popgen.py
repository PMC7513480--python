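"""Nucleotide polymorphism and neutrality statistics per sample group.

Segregating sites S, haplotype count H, nucleotide diversity pi, Watterson's
theta and Tajima's D. Alignment columns containing any gap or ambiguity code
in any analyzed sequence are excluded throughout (indels and missing data do
not contribute), and the exclusion is recomputed per group so each group
uses its own maximal indel-free site set.

All diversity values are per analyzed site. Tajima's D is defined only for
n >= 4 sequences with S >= 1; undefined cases are NaN-flagged, never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AlignedSet, validate_alignment

__all__ = [
    "PolymorphismSummary",
    "included_columns",
    "segregating_sites",
    "haplotypes",
    "diversity",
    "tajima_d",
    "group_summaries",
]

_ACGT = frozenset(b"ACGT")


def _column_matrix(aln: AlignedSet) -> np.ndarray:
    return np.frombuffer(
        "".join(r.residues for r in aln.records).encode("ascii"), dtype="S1"
    ).reshape(len(aln), aln.length)


def included_columns(aln: AlignedSet) -> np.ndarray:
    """0-based indices of columns free of gaps and ambiguity codes in all rows."""
    mat = _column_matrix(aln)
    ok = np.isin(mat, [b"A", b"C", b"G", b"T"]).all(axis=0)
    return np.flatnonzero(ok)


def segregating_sites(aln: AlignedSet) -> tuple[int, list[int]]:
    """Count polymorphic columns; returns (S, 1-based positions).

    Positions refer to the original alignment coordinates; excluded
    (gapped/ambiguous) columns can never be segregating.
    """
    mat = _column_matrix(aln)
    cols = included_columns(aln)
    positions = [
        int(c) + 1 for c in cols if len(np.unique(mat[:, c])) >= 2
    ]
    return len(positions), positions


def haplotypes(aln: AlignedSet) -> tuple[int, dict[str, int]]:
    """Distinct sequence variants over the indel-free columns.

    Haplotype ids are assigned by first occurrence (0, 1, 2, ...), so the
    numbering is deterministic given record order.
    """
    cols = included_columns(aln)
    seen: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for r in aln.records:
        key = "".join(r.residues[c] for c in cols)
        if key not in seen:
            seen[key] = len(seen)
        assignment[r.sample_id] = seen[key]
    return len(seen), assignment


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


@dataclass(frozen=True)
class DiversityResult:
    pi: float                 # mean pairwise differences per site
    theta_w: float            # Watterson's estimator per site
    mean_pairwise_k: float    # mean pairwise difference count
    sites: int                # analyzed (indel-free) columns

    @property
    def defined(self) -> bool:
        return self.sites > 0


def diversity(aln: AlignedSet) -> DiversityResult:
    """Nucleotide diversity pi and Watterson's theta, both per analyzed site.

    pi = mean pairwise difference count / L;  theta_w = S / (a1 * L) with
    a1 the (n-1)-th harmonic number. When every column is excluded the
    result is NaN-flagged.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("diversity requires >=2 sequences")
    mat = _column_matrix(aln)
    cols = included_columns(aln)
    L = len(cols)
    if L == 0:
        return DiversityResult(math.nan, math.nan, math.nan, 0)
    sub = mat[:, cols]
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((sub[i] != sub[j]).sum())
    k_bar = total / (n * (n - 1) / 2)
    S, _ = segregating_sites(aln)
    return DiversityResult(
        pi=k_bar / L,
        theta_w=S / (_harmonic(n) * L),
        mean_pairwise_k=k_bar,
        sites=L,
    )


def tajima_d(aln: AlignedSet) -> float:
    """Tajima's D from k_bar and S using the standard variance constants.

    Returns NaN (undefined) when n < 4 or S = 0.
    """
    n = len(aln)
    if n < 4:
        return math.nan
    S, _ = segregating_sites(aln)
    if S == 0:
        return math.nan
    div = diversity(aln)
    a1 = _harmonic(n)
    a2 = _harmonic(n, power=2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a2 + a1**2)
    var = e1 * S + e2 * S * (S - 1)
    return (div.mean_pairwise_k - S / a1) / math.sqrt(var)


@dataclass(frozen=True)
class PolymorphismSummary:
    """One row of the per-group polymorphism table."""

    group: str
    n: int
    sites: int
    S: int
    H: int
    pi: float
    theta_w: float
    tajima_d: float

    def to_dict(self) -> dict:
        return {
            "group": self.group, "n": self.n, "sites": self.sites,
            "S": self.S, "H": self.H, "theta_w": self.theta_w,
            "pi": self.pi, "tajima_d": self.tajima_d,
        }


def _summarize(aln: AlignedSet, name: str) -> PolymorphismSummary:
    S, _ = segregating_sites(aln)
    H, _ = haplotypes(aln)
    div = diversity(aln)
    return PolymorphismSummary(
        group=name, n=len(aln), sites=div.sites, S=S, H=H,
        pi=div.pi, theta_w=div.theta_w, tajima_d=tajima_d(aln),
    )


def group_summaries(
    aln: AlignedSet,
    grouping: dict[str, str],
    overall_label: str = "Over All",
) -> list[PolymorphismSummary]:
    """Polymorphism statistics for each group plus an overall row.

    ``grouping`` maps sample_id to a group name (genome code such as AAA,
    or a category such as wild/subspecies/cultivar). Groups with fewer
    than two members are reported with NaN diversity. Indel exclusion is
    recomputed within each group, so a gap confined to one group does not
    shrink another group's site set.
    """
    groups = sorted(set(grouping.values()))
    out = []
    for g in groups:
        ids = [r.sample_id for r in aln.records if grouping.get(r.sample_id) == g]
        if len(ids) < 2:
            out.append(
                PolymorphismSummary(
                    group=g, n=len(ids), sites=0, S=0, H=1 if ids else 0,
                    pi=math.nan, theta_w=math.nan, tajima_d=math.nan,
                )
            )
            continue
        sub = validate_alignment([r for r in aln.records if r.sample_id in set(ids)])
        out.append(_summarize(sub, g))
    out.append(_summarize(aln, overall_label))
    return out


def summaries_to_frame(summaries: list[PolymorphismSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
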