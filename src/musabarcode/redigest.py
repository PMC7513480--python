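"""In-silico restriction digestion (PCR-RFLP) with IUPAC-degenerate sites.

Recognition patterns may contain degenerate IUPAC letters (W = A/T, etc.).
Scanning is exhaustive over the forward strand including overlapping
matches; the built-in enzymes (MseI, PstI, AvaII) are all palindromic, so
forward-strand scanning already covers both strands. Digestion is of a
linear molecule: n de-duplicated cuts give n+1 fragments whose lengths sum
to the ungapped sequence length.

In strict mode (default) an ambiguity code in the *sequence* never matches
any pattern letter; permissive mode lets it match when its expansion
intersects the pattern letter's.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .seqio import LabeledSequence

__all__ = [
    "Enzyme",
    "DigestProfile",
    "BUILTIN_ENZYMES",
    "find_sites",
    "digest",
    "discriminate_haplotypes",
    "load_enzyme_table",
    "write_enzyme_table",
]

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition pattern and top-strand cut offset.

    ``cut_offset`` counts bases from the pattern start to the cut, so
    MseI (T^TAA) cuts after the first base of its site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        pat = self.recognition.upper()
        if any(ch not in IUPAC_EXPAND for ch in pat):
            raise ValueError(f"{self.name}: invalid pattern letter in {pat!r}")
        object.__setattr__(self, "recognition", pat)
        if not 0 <= self.cut_offset <= len(pat):
            raise ValueError(f"{self.name}: cut offset outside pattern")

    def __len__(self) -> int:
        return len(self.recognition)


BUILTIN_ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("MseI", "TTAA", 1),     # T^TAA
        Enzyme("PstI", "CTGCAG", 5),   # CTGCA^G
        Enzyme("AvaII", "GGWCC", 1),   # G^GWCC
    )
}


def _matches(seq_char: str, pat_char: str, permissive: bool) -> bool:
    pat_set = IUPAC_EXPAND[pat_char]
    if seq_char in "ACGT":
        return seq_char in pat_set
    if not permissive:
        return False
    return bool(set(IUPAC_EXPAND.get(seq_char, "")) & set(pat_set))


def find_sites(
    seq: LabeledSequence | str, enzyme: Enzyme, permissive: bool = False
) -> list[int]:
    """1-based start positions of every (possibly overlapping) recognition site.

    Gaps are stripped from the sequence before scanning.
    """
    s = seq.ungapped if isinstance(seq, LabeledSequence) else seq.upper().replace("-", "")
    pat = enzyme.recognition
    m = len(pat)
    hits = []
    for start in range(len(s) - m + 1):
        if all(_matches(s[start + k], pat[k], permissive) for k in range(m)):
            hits.append(start + 1)
    return hits


@dataclass(frozen=True)
class DigestProfile:
    """Cut positions (1-based, after the given base) and fragment lengths."""

    sample_id: str
    enzyme: str
    sequence_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]   # sorted ascending

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def digest(seq: LabeledSequence | str, enzyme: Enzyme,
           permissive: bool = False) -> DigestProfile:
    """Digest a linear molecule; fragments always sum to the ungapped length."""
    if isinstance(seq, LabeledSequence):
        s = seq.ungapped
        sid = seq.sample_id
    else:
        s = seq.upper().replace("-", "")
        sid = "<anonymous>"
    sites = find_sites(s, enzyme, permissive)
    # cut position = base after which the strand is cleaved; de-duplicate
    cuts = sorted({p - 1 + enzyme.cut_offset for p in sites})
    cuts = [c for c in cuts if 0 < c < len(s)]
    bounds = [0] + cuts + [len(s)]
    fragments = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return DigestProfile(
        sample_id=sid,
        enzyme=enzyme.name,
        sequence_length=len(s),
        cut_positions=tuple(cuts),
        fragment_lengths=fragments,
    )


def discriminate_haplotypes(
    profiles: dict[str, dict[str, DigestProfile]],
    haplotype_of: dict[str, int | str],
) -> list[tuple[str, int]]:
    """Rank enzymes by how many haplotype pairs their fragment patterns separate.

    ``profiles`` maps sample_id -> enzyme name -> DigestProfile. Each
    haplotype is represented by its first sample (samples of one haplotype
    share a sequence over the compared sites, so their digests agree).
    A pair is separated when the fragment-length multisets differ.
    Ranking is by descending power, then fewer total cuts, then name.
    Returns [] when fewer than two haplotypes are present.
    """
    rep: dict[int | str, str] = {}
    for sample in profiles:
        hap = haplotype_of[sample]
        rep.setdefault(hap, sample)
    haps = sorted(rep, key=lambda h: str(h))
    if len(haps) < 2:
        return []
    enzymes = sorted({e for per in profiles.values() for e in per})
    ranking = []
    for enz in enzymes:
        power = 0
        total_cuts = 0
        for h in haps:
            total_cuts += len(profiles[rep[h]][enz].cut_positions)
        for ha, hb in itertools.combinations(haps, 2):
            fa = Counter(profiles[rep[ha]][enz].fragment_lengths)
            fb = Counter(profiles[rep[hb]][enz].fragment_lengths)
            if fa != fb:
                power += 1
        ranking.append((enz, power, total_cuts))
    ranking.sort(key=lambda t: (-t[1], t[2], t[0]))
    return [(name, power) for name, power, _ in ranking]


def load_enzyme_table(path: str | Path) -> dict[str, Enzyme]:
    """Read enzymes from a TSV (name, pattern, cut_offset); header optional."""
    enzymes: dict[str, Enzyme] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 1 and parts[0].lower() == "name":
                continue
            if len(parts) != 3:
                raise ValueError(f"enzyme table line {i}: expected 3 columns")
            enzymes[parts[0]] = Enzyme(parts[0], parts[1], int(parts[2]))
    return enzymes


def write_enzyme_table(enzymes: dict[str, Enzyme], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpattern\tcut_offset\n")
        for e in enzymes.values():
            fh.write(f"{e.name}\t{e.recognition}\t{e.cut_offset}\n")
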