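import itertools
import logging

import numpy as np
import pytest

from musabarcode.distmat import DistanceMatrix
from musabarcode.seqio import LabeledSequence, validate_alignment

logging.getLogger("musabarcode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tajima_toy():
    """4x16 alignment with S=3 and pairwise difference counts {1,2,3,1,2,1}.

    Thirteen constant columns, a singleton variant in each of columns 14
    and 15, and a 2/2 split in column 16.
    """
    base = "ACGTACGTACGTA"
    return validate_alignment(
        [
            LabeledSequence("s1", "sp", base + "GCG"),
            LabeledSequence("s2", "sp", base + "ATA"),
            LabeledSequence("s3", "sp", base + "ACG"),
            LabeledSequence("s4", "sp", base + "ACA"),
        ]
    )


def build_random_additive(n_taxa: int, rng):
    """Random binary tree via random joins; returns (DistanceMatrix, splits).

    The matrix holds exact path lengths, so it is additive by construction
    and any consistent distance method must recover the topology.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes: list[dict] = [{"leaves": {lab}, "dist": {lab: 0.0}} for lab in labels]
    splits = set()
    full = frozenset(labels)
    matrix_entries = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.05, 0.4, size=2)
        for x, dx in a["dist"].items():
            for y, dy in b["dist"].items():
                matrix_entries[frozenset({x, y})] = dx + la + dy + lb
        merged = {
            "leaves": a["leaves"] | b["leaves"],
            "dist": {k: v + la for k, v in a["dist"].items()}
            | {k: v + lb for k, v in b["dist"].items()},
        }
        for side in (a["leaves"], b["leaves"]):
            s = frozenset(side)
            if 1 < len(s) < len(full) - 1:
                splits.add(frozenset({s, full - s}))
        nodes.append(merged)
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        v[i, j] = v[j, i] = matrix_entries[frozenset({labels[i], labels[j]})]
    return DistanceMatrix(labels=labels, values=v, flags={}), splits


@pytest.fixture(scope="session")
def clear_gap_set():
    """10 species x 5 samples with a clean barcoding gap (inter/intra = 10)."""
    from musabarcode.simseq import SimConfig, simulate_barcode_set

    cfg = SimConfig(
        n_species=10,
        samples_per_species=5,
        inter_divergence=0.20,
        intra_divergence=0.02,
        seed=42,
    )
    aln, truth = simulate_barcode_set(cfg)
    return aln, truth


@pytest.fixture(scope="session")
def clear_gap_matrix(clear_gap_set):
    from musabarcode.distmat import build_matrix

    aln, _ = clear_gap_set
    return build_matrix(aln)
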