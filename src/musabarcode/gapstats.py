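"""Barcoding-gap statistics over a pairwise distance matrix.

Six divergence metrics summarize inter- vs intra-specific variation. The
literature names them but rarely writes them down, so the unit each mean
averages over is made explicit here:

========================  =======================================================
all_inter                 mean over all between-species *sample pairs*
theta_prime               mean over *species pairs* of their average distance
min_inter                 per *species*: min distance from any of its samples to
                          any heterospecific sample; averaged over species
all_intra                 mean over all within-species *sample pairs*
theta                     per *species* (>=2 samples): mean intra distance;
                          averaged over those species
coalescent_depth          per *species* (>=2 samples): max intra distance;
                          averaged over those species
========================  =======================================================

The "+/-" dispersion reported with each mean is the standard deviation over
the per-unit values that the mean averages. Undefined (flagged) distances
are excluded everywhere, with a logged count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from statistics import NormalDist

import numpy as np

from .distmat import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "MetricValue",
    "DivergenceSummary",
    "GapHistogram",
    "split_distances",
    "divergence_summary",
    "gap_histogram",
    "proportion_below",
    "wilcoxon_ranksum",
]


@dataclass(frozen=True)
class MetricValue:
    """A mean +/- sd over n averaged units; NaN mean means 'undefined'."""

    mean: float
    sd: float
    n: int

    @staticmethod
    def of(values) -> "MetricValue":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            return MetricValue(math.nan, math.nan, 0)
        return MetricValue(
            float(arr.mean()),
            float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            int(arr.size),
        )

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mean)


@dataclass(frozen=True)
class DivergenceSummary:
    all_inter: MetricValue
    theta_prime: MetricValue
    min_inter: MetricValue
    all_intra: MetricValue
    theta: MetricValue
    coalescent_depth: MetricValue
    n_species: int
    n_species_multi: int  # species with >=2 samples (eligible for intra metrics)

    def to_rows(self):
        for name in (
            "all_inter", "theta_prime", "min_inter",
            "all_intra", "theta", "coalescent_depth",
        ):
            m: MetricValue = getattr(self, name)
            yield name, m.mean, m.sd, m.n


def split_distances(
    dm: DistanceMatrix, species_of: dict[str, str]
) -> tuple[list[float], list[float]]:
    """Defined pairwise distances split into (intra-specific, inter-specific)."""
    intra, inter = [], []
    for a, b, d in dm.defined_pairs():
        (intra if species_of[a] == species_of[b] else inter).append(d)
    return intra, inter


def divergence_summary(
    dm: DistanceMatrix, species_of: dict[str, str]
) -> DivergenceSummary:
    """Compute the six divergence metrics from a distance matrix.

    Requires >=2 species. Species with a single sample contribute to the
    inter-specific metrics only; if no species has >=2 samples the intra
    metrics come back undefined (NaN) rather than zero.
    """
    species = sorted(set(species_of[l] for l in dm.labels))
    if len(species) < 2:
        raise ValueError("inter-specific metrics require >=2 species")
    members: dict[str, list[str]] = {s: [] for s in species}
    for lab in dm.labels:
        members[species_of[lab]].append(lab)

    intra, inter = split_distances(dm, species_of)
    if dm.n_undefined:
        log.warning("excluding %d undefined pairs from divergence metrics",
                    dm.n_undefined)

    # species-pair averages (theta prime) and per-species nearest neighbor
    pair_means = []
    for sa, sb in itertools.combinations(species, 2):
        ds = [
            dm[a, b]
            for a in members[sa]
            for b in members[sb]
            if not math.isnan(dm[a, b])
        ]
        if ds:
            pair_means.append(float(np.mean(ds)))

    nearest = []
    for s in species:
        ds = [
            dm[a, b]
            for a in members[s]
            for other in species
            if other != s
            for b in members[other]
            if not math.isnan(dm[a, b])
        ]
        if ds:
            nearest.append(min(ds))

    theta_vals, depth_vals = [], []
    multi = [s for s in species if len(members[s]) >= 2]
    for s in multi:
        ds = [
            dm[a, b]
            for a, b in itertools.combinations(members[s], 2)
            if not math.isnan(dm[a, b])
        ]
        if ds:
            theta_vals.append(float(np.mean(ds)))
            depth_vals.append(max(ds))

    return DivergenceSummary(
        all_inter=MetricValue.of(inter),
        theta_prime=MetricValue.of(pair_means),
        min_inter=MetricValue.of(nearest),
        all_intra=MetricValue.of(intra),
        theta=MetricValue.of(theta_vals),
        coalescent_depth=MetricValue.of(depth_vals),
        n_species=len(species),
        n_species_multi=len(multi),
    )


@dataclass(frozen=True)
class GapHistogram:
    """Binned intra vs inter distance distributions with half-open bins [lo, hi)."""

    bin_width: float
    bin_edges: np.ndarray          # len = n_bins + 1, anchored at 0
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    intra_range: tuple[float, float] | None
    inter_range: tuple[float, float] | None
    overlap_fraction: float        # fraction of inter distances <= max intra

    def to_rows(self):
        for k in range(len(self.intra_counts)):
            yield (
                float(self.bin_edges[k]),
                float(self.bin_edges[k + 1]),
                int(self.intra_counts[k]),
                int(self.inter_counts[k]),
            )


def gap_histogram(
    dm: DistanceMatrix,
    species_of: dict[str, str],
    bin_width: float = 0.008,
) -> GapHistogram:
    """Histogram the intra/inter distance distributions at a fixed bin width.

    Bins are half-open [lo, hi) and anchored at zero so binning is
    bit-reproducible. ``overlap_fraction`` is the proportion of
    inter-specific distances that fall at or below the largest
    intra-specific distance (0 means a clean barcoding gap).
    """
    intra, inter = split_distances(dm, species_of)
    return histogram_from_values(intra, inter, bin_width)


def histogram_from_values(
    intra: list[float], inter: list[float], bin_width: float = 0.008
) -> GapHistogram:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not intra:
        log.warning("no intra-specific distances: intra histogram is empty")
    if not inter:
        log.warning("no inter-specific distances: inter histogram is empty")
    top = max(intra + inter, default=0.0)
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width

    def counts(values):
        c = np.zeros(n_bins, dtype=int)
        for v in values:
            c[min(int(v // bin_width), n_bins - 1)] += 1
        return c

    max_intra = max(intra) if intra else None
    if inter and max_intra is not None:
        overlap = sum(1 for d in inter if d <= max_intra) / len(inter)
    else:
        overlap = math.nan
    return GapHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        intra_counts=counts(intra),
        inter_counts=counts(inter),
        intra_range=(min(intra), max(intra)) if intra else None,
        inter_range=(min(inter), max(inter)) if inter else None,
        overlap_fraction=overlap,
    )


def proportion_below(values, threshold: float, strict: bool = True) -> float:
    """Fraction of values below (strict) or at-or-below a distance threshold."""
    values = list(values)
    if not values:
        raise ValueError("proportion_below requires non-empty values")
    if strict:
        k = sum(1 for v in values if v < threshold)
    else:
        k = sum(1 for v in values if v <= threshold)
    return k / len(values)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # midrank, 1-based
        i = j + 1
    return ranks


def wilcoxon_ranksum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p-value).

    Midranks resolve ties. Under ``method="auto"``, for n_x and n_y both
    <= 10 the p-value is an exact permutation enumeration over all
    C(n_x+n_y, n_x) group assignments of the pooled midranks; otherwise a
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used. ``"exact"`` / ``"normal"`` force either route.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())
    n = nx + ny
    mean_w = nx * (n + 1) / 2.0

    if method == "exact" or (method == "auto" and nx <= 10 and ny <= 10):
        obs_dev = abs(w - mean_w)
        total = 0
        hits = 0
        for combo in itertools.combinations(range(n), nx):
            total += 1
            if abs(ranks[list(combo)].sum() - mean_w) >= obs_dev - 1e-9:
                hits += 1
        return w, hits / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all observations identical
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - NormalDist().cdf(z))
    return w, min(max(p, np.nextafter(0, 1)), 1.0)
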