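"""Neighbor-joining trees from distance matrices, with column bootstrap.

Standard Saitou-Nei neighbor joining with the Q-criterion. Tie-breaking is
deterministic (first pair in label-index order attaining the minimum), and
negative branch lengths are clamped to zero with a logged count, so a fixed
input always yields a byte-identical Newick string.

Bootstrap support resamples alignment columns with replacement, recomputes
the K2P matrix and NJ tree per replicate, and reports for each internal
edge of the original tree the percentage of replicates containing the same
bipartition of the leaf set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .distmat import DistanceMatrix, build_matrix
from .seqio import AlignedSet, LabeledSequence, validate_alignment

log = logging.getLogger(__name__)

__all__ = ["TreeNode", "Phylogeny", "nj", "bootstrap_support"]


@dataclass
class TreeNode:
    """A node of an (arbitrarily rooted) phylogeny; leaves carry labels."""

    label: str | None = None
    length: float = 0.0                     # branch to parent
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None            # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Phylogeny:
    """Unrooted tree over sample labels, stored with a trifurcating root."""

    root: TreeNode
    n_clamped: int = 0                      # negative branches clamped to 0

    @property
    def labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial splits of the leaf set induced by internal edges."""
        all_leaves = frozenset(self.root.leaves())
        splits = set()

        def walk(node: TreeNode):
            for child in node.children:
                below = frozenset(child.leaves())
                if 1 < len(below) < len(all_leaves) - 1:
                    splits.add(frozenset({below, all_leaves - below}))
                walk(child)

        walk(self.root)
        return splits

    def annotate_supports(self, support_of: dict[frozenset, float]) -> None:
        all_leaves = frozenset(self.root.leaves())

        def walk(node: TreeNode):
            for child in node.children:
                below = frozenset(child.leaves())
                if 1 < len(below) < len(all_leaves) - 1:
                    key = frozenset({below, all_leaves - below})
                    child.support = support_of.get(key, 0.0)
                walk(child)

        walk(self.root)

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path, include_support: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_support) + "\n")


def nj(dm: DistanceMatrix) -> Phylogeny:
    """Neighbor joining over a fully defined distance matrix (>=3 labels)."""
    if len(dm.labels) < 3:
        raise ValueError("NJ requires at least 3 labels")
    if np.isnan(dm.values).any():
        bad = sorted(
            {dm.labels[i] for i, j in dm.flags} | {dm.labels[j] for i, j in dm.flags}
        )
        raise ValueError(
            "distance matrix has undefined entries; exclude samples involved: "
            + ", ".join(bad)
        )
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    active = list(range(len(nodes)))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # Q(i, j) = (m - 2) d_ij - r_i - r_j; first minimum in index order wins
        best = (math.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three nodes: solve the three-point equations
    i, j, k = active
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    if clamped:
        log.warning("clamped %d negative NJ branch lengths to 0", clamped)
    return Phylogeny(root=root, n_clamped=clamped)


def bootstrap_support(
    aln: AlignedSet,
    replicates: int = 1000,
    seed: int = 0,
    tree: Phylogeny | None = None,
) -> Phylogeny:
    """Attach column-bootstrap support percentages to the NJ tree of ``aln``.

    Replicates whose resampled matrix contains undefined distances are
    dropped (and logged); supports are percentages of the retained
    replicates. A fixed seed gives identical supports across runs.
    """
    if tree is None:
        tree = nj(build_matrix(aln))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    used = 0
    dropped = 0
    records = list(aln.records)
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        resampled = validate_alignment(
            [
                LabeledSequence(
                    sample_id=r.sample_id,
                    species=r.species,
                    genome_code=r.genome_code,
                    residues="".join(r.residues[c] for c in cols),
                )
                for r in records
            ]
        )
        dmat = build_matrix(resampled)
        if np.isnan(dmat.values).any():
            dropped += 1
            continue
        rep_splits = nj(dmat).bipartitions()
        used += 1
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    if dropped:
        log.warning("dropped %d bootstrap replicates with undefined distances",
                    dropped)
    if used == 0:
        raise RuntimeError("no bootstrap replicate produced a defined matrix")
    tree.annotate_supports({s: 100.0 * c / used for s, c in counts.items()})
    return tree
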