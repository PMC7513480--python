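"""Synthetic barcode alignments and coalescent samples for pipeline testing.

Three generators:

* :func:`simulate_barcode_set` — species-structured, ITS2-like alignments
  under the Kimura two-parameter substitution model on a star phylogeny
  (optionally a random bifurcating species tree). ``inter_divergence`` is
  the expected K2P distance between samples of *different* species and
  ``intra_divergence`` between conspecific samples, so the matching
  estimator recovers both directly. Defaults emulate the marker this
  toolkit targets: 325-375 bp, 60% GC, intra ~0.035 and inter ~0.19
  substitutions/site.

* :func:`simulate_coalescent` — the standard neutral coalescent
  (exponential coalescence times at rate k(k-1)/2 with time in units of
  2N generations; mutations Poisson with mean theta/2 per unit branch
  length, placed infinite-sites style on L sites). E[S] = theta * a1 and
  E[pi_total] = theta, which the unit tests exploit as oracles.

* :func:`plant_restriction_haplotypes` — engineered haplotypes whose
  restriction-site presence/absence pattern is known by construction,
  giving an end-to-end truth table for enzyme discrimination.

All randomness flows from one seeded generator; a fixed seed reproduces
output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .redigest import Enzyme, find_sites
from .seqio import AlignedSet, LabeledSequence, validate_alignment

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_barcode_set",
    "simulate_coalescent",
    "simulate_k2p_pair",
    "plant_restriction_haplotypes",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Conditions for a species-structured barcode simulation.

    ``kappa`` is the transition/transversion *rate* ratio (alpha/beta);
    2.0 is a typical nuclear-ribosomal value. Divergences are expected
    substitutions per site between sample pairs of the given relation.
    """

    n_species: int = 46
    samples_per_species: int = 6
    inter_divergence: float = 0.19
    intra_divergence: float = 0.035
    kappa: float = 2.0
    length_range: tuple[int, int] = (325, 375)
    gc_target: float = 0.60
    seed: int = 0
    species_tree: str = "star"          # "star" or "bifurcating"
    gap_fraction: float = 0.0           # optional indel mode: per-site gap prob

    def __post_init__(self):
        if self.n_species < 1 or self.samples_per_species < 1:
            raise ValueError("need >=1 species and >=1 sample per species")
        if not 0 <= self.intra_divergence <= self.inter_divergence:
            raise ValueError("require 0 <= intra_divergence <= inter_divergence")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must lie in (0, 1)")
        if self.species_tree not in ("star", "bifurcating"):
            raise ValueError("species_tree must be 'star' or 'bifurcating'")


@dataclass
class TruthTable:
    """What the simulator actually did, for downstream verification."""

    config: SimConfig
    root_sequence: str
    species_ancestors: dict[str, str]
    species_of: dict[str, str] = field(default_factory=dict)


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """Per-site (transition, each-transversion) probability after branch d.

    Rates are normalized so alpha + 2 beta = 1: time equals expected
    substitutions per site.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta * d) - 0.5 * math.exp(-2 * (alpha + beta) * d)
    p_tv_each = 0.25 - 0.25 * math.exp(-4 * beta * d)
    return p_ts, p_tv_each


# index arithmetic over A=0,C=1,G=2,T=3: transition partner = i ^ 2,
# transversion partners = the other two bases
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _evolve(seq: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded (0..3) sequence along a branch of length d."""
    if d == 0:
        return seq.copy()
    p_ts, p_tv = _k2p_probs(d, kappa)
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts = u < p_ts
    out[ts] = _TS_PARTNER[seq[ts]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    out[tv1] = _TV_PARTNERS[seq[tv1], 0]
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv2] = _TV_PARTNERS[seq[tv2], 1]
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in seq)


def _random_root(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def simulate_k2p_pair(
    t: float, length: int, kappa: float, rng: np.random.Generator,
    gc: float = 0.5,
) -> tuple[str, str]:
    """One pair of sequences at expected K2P divergence t (common-ancestor style)."""
    root = _random_root(length, gc, rng)
    return (
        _decode(_evolve(root, t / 2, kappa, rng)),
        _decode(_evolve(root, t / 2, kappa, rng)),
    )


def _species_branches(cfg: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    """Depth of each species ancestor below the root."""
    depth = (cfg.inter_divergence - cfg.intra_divergence) / 2.0
    return {f"sp{i + 1:02d}": depth for i in range(cfg.n_species)}


def simulate_barcode_set(cfg: SimConfig) -> tuple[AlignedSet, TruthTable]:
    """Simulate a species-structured aligned barcode set under the K2P model.

    On the default star phylogeny every species ancestor sits at depth
    (inter - intra)/2 below the root and every sample at depth intra/2
    below its ancestor, so heterospecific sample pairs are separated by
    an expected ``inter_divergence`` and conspecific pairs by
    ``intra_divergence``. No indels are introduced unless
    ``gap_fraction`` > 0, so the set is an alignment by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    root = _random_root(length, cfg.gc_target, rng)

    ancestors: dict[str, np.ndarray] = {}
    if cfg.species_tree == "star":
        for name, depth in _species_branches(cfg, rng).items():
            ancestors[name] = _evolve(root, depth, cfg.kappa, rng)
    else:
        ancestors = _bifurcating_ancestors(cfg, root, rng)

    records = []
    species_of = {}
    for name in ancestors:
        for s in range(cfg.samples_per_species):
            sid = f"{name}_s{s + 1}"
            tip = _evolve(ancestors[name], cfg.intra_divergence / 2.0, cfg.kappa, rng)
            residues = _decode(tip)
            if cfg.gap_fraction > 0:
                mask = rng.random(length) < cfg.gap_fraction
                residues = "".join(
                    "-" if m else ch for ch, m in zip(residues, mask)
                )
            records.append(
                LabeledSequence(sample_id=sid, species=name, residues=residues)
            )
            species_of[sid] = name

    truth = TruthTable(
        config=cfg,
        root_sequence=_decode(root),
        species_ancestors={k: _decode(v) for k, v in ancestors.items()},
        species_of=species_of,
    )
    if len(records) == 1:
        # single-record "alignment": bypass the >=2 validation path
        return AlignedSet(records=tuple(records), length=length), truth
    return validate_alignment(records), truth


def _bifurcating_ancestors(
    cfg: SimConfig, root: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Random bifurcating species history: recursive splits of the divergence budget."""
    total_depth = (cfg.inter_divergence - cfg.intra_divergence) / 2.0
    names = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
    out: dict[str, np.ndarray] = {}

    def grow(seq: np.ndarray, members: list[str], remaining: float):
        if len(members) == 1:
            out[members[0]] = _evolve(seq, remaining, cfg.kappa, rng)
            return
        split = 1 + int(rng.integers(0, len(members) - 1))
        step = remaining * float(rng.uniform(0.2, 0.8))
        left = _evolve(seq, step, cfg.kappa, rng)
        right = _evolve(seq, step, cfg.kappa, rng)
        grow(left, members[:split], remaining - step)
        grow(right, members[split:], remaining - step)

    grow(root, names, total_depth)
    return out


def simulate_coalescent(
    n: int, theta: float, sites: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AlignedSet:
    """Sample n haplotypes of length ``sites`` under the neutral coalescent.

    Mutations are Poisson with mean theta/2 times total branch length and
    are placed on distinct sites (infinite-sites approximated on L sites;
    a collision redraws the site). Variants appear as G against an A
    background. Raises when the mutation count exceeds the site count.
    """
    if n < 2:
        raise ValueError("coalescent requires n >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)

    # lineages as sets of leaf indices; record (leaf_set, branch_length)
    lineages: list[set[int]] = [{i} for i in range(n)]
    birth = {i: 0.0 for i in range(n)}        # time each lineage appeared
    branches: list[tuple[frozenset[int], float]] = []
    t = 0.0
    next_id = n
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(sorted(active), size=2, replace=False)
        for lid in (a, b):
            branches.append((frozenset(active[lid]), t - birth[lid]))
        active[next_id] = active.pop(a) | active.pop(b)
        birth[next_id] = t
        next_id += 1

    total_len = sum(bl for _, bl in branches)
    n_mut = rng.poisson(theta / 2.0 * total_len)
    if n_mut > sites:
        raise ValueError(
            f"{n_mut} mutations exceed {sites} sites; increase the site count"
        )
    seqs = np.zeros((n, sites), dtype=np.uint8)   # 0 = A, 1 = G
    weights = np.array([bl for _, bl in branches])
    weights = weights / weights.sum() if weights.sum() > 0 else weights
    used: set[int] = set()
    for _ in range(n_mut):
        bidx = int(rng.choice(len(branches), p=weights))
        site = int(rng.integers(sites))
        while site in used:
            site = int(rng.integers(sites))
        used.add(site)
        for leaf in branches[bidx][0]:
            seqs[leaf, site] = 1
    records = [
        LabeledSequence(
            sample_id=f"h{i + 1}",
            species="sim",
            residues="".join("AG"[v] for v in seqs[i]),
        )
        for i in range(n)
    ]
    return validate_alignment(records)


def plant_restriction_haplotypes(
    base: LabeledSequence | str,
    n_haplotypes: int,
    enzymes: list[Enzyme],
    seed: int = 0,
) -> tuple[list[LabeledSequence], dict[tuple[int, int], set[str]]]:
    """Engineer haplotypes with known restriction-site presence/absence.

    Haplotype h carries enzyme k's recognition site iff bit k of h is set,
    each at an enzyme-specific fixed position, so enzyme k separates the
    haplotype pair (i, j) exactly when bit k differs — the returned truth
    table records this and end-to-end tests compare it against
    :func:`musabarcode.redigest.discriminate_haplotypes`.
    """
    s = base.ungapped if isinstance(base, LabeledSequence) else base.upper().replace("-", "")
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if n_haplotypes > 2 ** len(enzymes):
        raise ValueError(
            f"{len(enzymes)} enzymes can distinguish at most {2 ** len(enzymes)} haplotypes"
        )
    rng = np.random.default_rng(seed)
    # reserve a non-overlapping interior window for each enzyme's site
    max_pat = max(len(e) for e in enzymes)
    slot = max_pat + 4
    needed = slot * (len(enzymes) + 1)
    if len(s) < needed:
        raise ValueError(f"sequence of {len(s)} bp too short; need >= {needed}")
    windows = {
        e.name: 2 + k * slot for k, e in enumerate(enzymes)
    }

    scrubbed = _scrub_sites(s, enzymes, rng)
    haplos = []
    for h in range(n_haplotypes):
        seq = list(scrubbed)
        for k, e in enumerate(enzymes):
            if h >> k & 1:
                start = windows[e.name]
                concrete = "".join(
                    ch if ch in "ACGT" else rng.choice(list({
                        "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
                        "K": "GT", "M": "AC", "N": "ACGT",
                    }[ch]))
                    for ch in e.recognition
                )
                seq[start : start + len(e)] = concrete
        final = _scrub_sites(
            "".join(seq), enzymes, rng,
            keep={(e.name, windows[e.name] + 1) for e in enzymes},
        )
        haplos.append(
            LabeledSequence(sample_id=f"hap{h + 1}", species=f"hap{h + 1}",
                            residues=final)
        )

    truth: dict[tuple[int, int], set[str]] = {}
    for i in range(n_haplotypes):
        for j in range(i + 1, n_haplotypes):
            truth[(i, j)] = {
                e.name for k, e in enumerate(enzymes) if (i >> k & 1) != (j >> k & 1)
            }
    return haplos, truth


def _scrub_sites(
    s: str, enzymes: list[Enzyme], rng: np.random.Generator,
    keep: set[tuple[str, int]] = frozenset(),
) -> str:
    """Mutate away every recognition site not in ``keep`` ((enzyme, 1-based pos))."""
    seq = list(s)
    for _ in range(50):  # fixed-point iteration; planting order can recreate sites
        dirty = False
        for e in enzymes:
            for pos in find_sites("".join(seq), e):
                if (e.name, pos) in keep:
                    continue
                # break the site by substituting a base the pattern excludes
                idx = pos - 1
                pat_sets = {
                    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG",
                    "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
                    "N": "ACGT",
                }
                for off, pch in enumerate(e.recognition):
                    allowed = pat_sets.get(pch, "ACGT")
                    options = [b for b in "ACGT" if b not in allowed]
                    if options:
                        seq[idx + off] = options[int(rng.integers(len(options)))]
                        dirty = True
                        break
        if not dirty:
            break
    return "".join(seq)
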