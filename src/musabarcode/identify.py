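"""Leave-one-out species identification with correct/ambiguous/incorrect outcomes.

Two methods, each querying every sample against all remaining samples:

* DISTANCE — the nearest-distance method: the hit set is every reference at
  the smallest pairwise distance to the query (ties within 1e-12).
* BLAST1 — a best-hit search by local alignment score against the internal
  reference set (megablast-style scoring by default); the hit set is every
  reference at the maximal score (integer scores, exact ties).

Outcome rules (applied identically to both hit sets):

* correct    — every top hit is conspecific with the query;
* ambiguous  — top hits span two or more species;
* incorrect  — the top hits are a single species that is not the query's.

A query whose distances are all undefined is reported separately as
*unassignable*, never folded into the three rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .distmat import DistanceMatrix, build_matrix
from .seqio import AlignedSet, LabeledSequence

log = logging.getLogger(__name__)

DISTANCE_TIE_TOL = 1e-12

__all__ = [
    "AlignmentScoring",
    "IdentificationOutcome",
    "IdentificationReport",
    "nearest_distance_identify",
    "blast1_identify",
    "evaluate_identification",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Local-alignment scoring; a gap of length k scores gap_open + k * gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # Biopython charges open_gap_score for the first gap position and
        # extend_gap_score for each subsequent one.
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a


@dataclass(frozen=True)
class IdentificationOutcome:
    query_id: str
    method: str                     # "DISTANCE" or "BLAST1"
    outcome: str                    # correct | ambiguous | incorrect | unassignable
    hit_species: frozenset[str]
    hit_ids: tuple[str, ...]
    score_or_distance: float

    def __post_init__(self):
        if self.outcome == "correct" and len(self.hit_species) != 1:
            raise ValueError("correct outcome requires a single hit species")


def _classify(query_species: str, hit_species: frozenset[str]) -> str:
    if len(hit_species) >= 2:
        return "ambiguous"
    if hit_species == {query_species}:
        return "correct"
    return "incorrect"


def nearest_distance_identify(
    query: LabeledSequence | str,
    refs: AlignedSet,
    dm: DistanceMatrix,
) -> IdentificationOutcome:
    """Identify one query by the smallest K2P distance to any other sample.

    ``dm`` is the full matrix over ``refs`` (query included); the query's own
    row entry is excluded, so this is leave-one-out at the sample level.
    """
    qid = query.sample_id if isinstance(query, LabeledSequence) else query
    species_of = refs.species_of
    qi = dm.labels.index(qid)
    row = dm.values[qi].copy()
    row[qi] = math.nan
    if np.all(np.isnan(row)):
        return IdentificationOutcome(
            qid, "DISTANCE", "unassignable", frozenset(), (), math.nan
        )
    dmin = float(np.nanmin(row))
    hit_idx = [
        j for j in range(len(row))
        if not math.isnan(row[j]) and row[j] <= dmin + DISTANCE_TIE_TOL
    ]
    hit_ids = tuple(dm.labels[j] for j in hit_idx)
    hit_species = frozenset(species_of[h] for h in hit_ids)
    return IdentificationOutcome(
        qid, "DISTANCE", _classify(species_of[qid], hit_species),
        hit_species, hit_ids, dmin,
    )


def blast1_identify(
    query: LabeledSequence,
    refs: list[LabeledSequence],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> IdentificationOutcome:
    """Identify one query by best local-alignment score against the references.

    Gaps are stripped before alignment (the references act as an ungapped
    sequence database). The query itself must not be in ``refs``.
    """
    if not refs:
        raise ValueError("reference set is empty")
    aligner = scoring.aligner()
    q = query.ungapped
    scores = [float(aligner.score(q, r.ungapped)) for r in refs]
    best = max(scores)
    hits = [r for r, s in zip(refs, scores) if s == best]
    hit_species = frozenset(r.species for r in hits)
    return IdentificationOutcome(
        query.sample_id, "BLAST1", _classify(query.species, hit_species),
        hit_species, tuple(r.sample_id for r in hits), best,
    )


@dataclass
class IdentificationReport:
    """Per-method and per-species identification tallies from leave-one-out runs."""

    outcomes: list[IdentificationOutcome]
    singletons: list[str] = field(default_factory=list)  # single-sample species

    OUTCOME_ORDER = ("correct", "ambiguous", "incorrect", "unassignable")

    def methods(self) -> list[str]:
        return sorted({o.method for o in self.outcomes})

    def rates(self, method: str) -> dict[str, float]:
        """Outcome percentages for one method; they sum to 100 exactly."""
        outs = [o for o in self.outcomes if o.method == method]
        if not outs:
            raise ValueError(f"no outcomes for method {method!r}")
        n = len(outs)
        return {
            k: 100.0 * sum(1 for o in outs if o.outcome == k) / n
            for k in self.OUTCOME_ORDER
        }

    def success_rate(self, method: str) -> float:
        """Species-level identification success rate: % of queries correct."""
        return self.rates(method)["correct"]

    def per_species(self, species_of: dict[str, str]) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            rows.append(
                {
                    "species": species_of[o.query_id],
                    "method": o.method,
                    "outcome": o.outcome,
                }
            )
        df = pd.DataFrame(rows)
        tab = (
            df.groupby(["species", "method", "outcome"]).size().unstack(fill_value=0)
        )
        for k in self.OUTCOME_ORDER:
            if k not in tab.columns:
                tab[k] = 0
        tab = tab[list(self.OUTCOME_ORDER)]
        total = tab.sum(axis=1)
        pct = tab.div(total, axis=0) * 100.0
        pct.columns = [f"{c}_pct" for c in pct.columns]
        out = pd.concat([tab, pct], axis=1)
        out["n_queries"] = total
        return out.reset_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": [o.query_id for o in self.outcomes],
                "method": [o.method for o in self.outcomes],
                "outcome": [o.outcome for o in self.outcomes],
                "hit_species": ["; ".join(sorted(o.hit_species)) for o in self.outcomes],
                "score_or_distance": [o.score_or_distance for o in self.outcomes],
            }
        )


def evaluate_identification(
    aln: AlignedSet,
    dm: DistanceMatrix | None = None,
    methods: tuple[str, ...] = ("DISTANCE", "BLAST1"),
    scoring: AlignmentScoring = AlignmentScoring(),
) -> IdentificationReport:
    """Run leave-one-out identification for every sample under both methods.

    Species represented by a single sample can never be identified
    correctly under leave-one-out; they are listed in ``report.singletons``.
    """
    if dm is None and "DISTANCE" in methods:
        dm = build_matrix(aln)
    counts = aln.species_counts()
    singletons = sorted(s for s, c in counts.items() if c == 1)
    if singletons:
        log.info("%d single-sample species cannot be identified correctly: %s",
                 len(singletons), ", ".join(singletons))

    outcomes: list[IdentificationOutcome] = []
    records = list(aln.records)
    for idx, query in enumerate(records):
        if "DISTANCE" in methods:
            outcomes.append(nearest_distance_identify(query, aln, dm))
        if "BLAST1" in methods:
            refs = records[:idx] + records[idx + 1:]
            outcomes.append(blast1_identify(query, refs, scoring))
    return IdentificationReport(outcomes=outcomes, singletons=singletons)
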