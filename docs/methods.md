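# Methods

This note documents the models and procedures behind `musabarcode`, the
choices made where conventions diverge, and the limits of what the
synthetic benchmarks demonstrate.

## Distances

Pairwise distances use the Kimura 2-parameter model. For an aligned pair,
a site contributes only when both residues are unambiguous bases
(pairwise deletion); gaps and every IUPAC ambiguity code exclude the
site, and ambiguity codes are never partially matched — determinism is
worth more here than the occasional extra site. With transition
proportion P (A↔G, C↔T) and transversion proportion Q over the n
compared sites,

    d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)].

Two degenerate outcomes are flagged rather than numerically coerced:
n = 0 ("no sites") and a non-positive logarithm argument ("saturated").
Flagged pairs propagate as NaN in the matrix and are excluded, with a
logged count, from every downstream mean; clamping them to a number
would bias the divergence summaries. Complete deletion (dropping any
column gapped anywhere) was rejected because barcoding datasets mix
sequences of uneven trimming, and pairwise deletion preserves far more
signal per pair.

## Barcoding-gap metrics

The six divergence metrics differ only in the unit each mean averages
over, so the units are fixed explicitly:

| metric | averaged unit | eligibility |
|---|---|---|
| all inter-specific distance | heterospecific sample pairs | ≥2 species |
| theta prime | species-pair mean distances | ≥2 species |
| minimum inter-specific distance | per-species nearest-neighbor distance | every species |
| all intra-specific distance | conspecific sample pairs | species with ≥2 samples |
| theta | per-species mean intra distance | species with ≥2 samples |
| coalescent depth | per-species maximum intra distance | species with ≥2 samples |

The "±" reported with each metric is the standard deviation over the
averaged units (an interpretation — the convention is rarely stated in
published tables — flagged here so users comparing to other software
know what the dispersion is). Eligible-species counts are reported with
the summary.

Gap histograms use half-open bins [lo, hi) anchored at 0 (default width
0.008 distance units) so binning is bit-reproducible; the overlap
fraction is the proportion of inter-specific distances at or below the
largest intra-specific distance.

The intra-vs-inter location test is a two-sided Wilcoxon rank-sum with
midranks for ties. Both samples ≤ 10: exact enumeration of all
C(n₁+n₂, n₁) assignments of the pooled midranks. Larger samples:
normal approximation with tie-corrected variance and a 0.5 continuity
correction. Exhaustive comparison of the two routes over every
achievable rank-sum shows the approximation is within 0.02 of the exact
p whenever both samples have ≥ 5 observations; at sizes 2–4 the extreme
lattice tails widen the gap (up to 0.088 at n₁=n₂=2), which is intrinsic
to the approximation, not repairable by implementation. Null rejection
at α = 0.05 is calibrated (≈ 0.048 over 1000 replicates).

## Species identification

Every sample is queried once against all remaining samples (sample-level
leave-one-out: conspecific references stay in the database). Two
methods:

* **DISTANCE** — hit set = references at the minimal K2P distance, ties
  within 1e−12 (distances are floats; exact equality would split
  numerically identical hits).
* **BLAST1** — hit set = references at the maximal local-alignment
  score against the gap-stripped sequences. Default scoring mimics
  megablast: match +1, mismatch −2, and a gap of length k costs
  5 + 2k. Scores are integers, so ties are exact. The search is an
  exhaustive Smith–Waterman-style alignment per reference — at barcode
  scale (hundreds of ~350 bp sequences) heuristic seeding buys nothing.

Outcomes: *correct* if every top hit is conspecific; *ambiguous* if top
hits span ≥ 2 species; *incorrect* if the top hits are a single wrong
species. Queries with no defined distance are *unassignable* and
reported separately rather than diluting the three rates. The
species-level success rate is correct queries / total queries. Species
represented by a single sample can never be correct under leave-one-out
and are flagged.

## Polymorphism and neutrality

Alignment columns containing any gap or ambiguity in the analyzed group
are excluded; the exclusion is recomputed per group, so each group keeps
its own maximal indel-free site set. Over the L included columns:
S = polymorphic columns; H = distinct residue strings (numbered by first
occurrence); π = mean pairwise difference count / L; θ_W = S/(a₁L) with
a₁ = Σ_{i<n} 1/i; Tajima's D uses the standard a₁, a₂, b, c, e constants
with variance e₁S + e₂S(S−1). D is undefined (NaN, never 0) when n < 4
or S = 0.

ITS2 is non-coding, so the default pipeline computes total-site
statistics only; silent/non-synonymous splits would require a reading
frame the data does not carry, and the pipeline never invents one.

A practical caution encoded in the tests: D's normalization does not
make it mean-zero in finite samples. At n = 20, θ = 5 its expectation is
≈ −0.06, confirmed both by this package's simulator (−0.060 ± 0.014,
4000 replicates) and by independent msprime genealogies (−0.062 ± 0.030).
Tests therefore check D against that expectation, not against 0.

## Restriction digestion

Recognition patterns expand IUPAC letters (W = A/T, …); scanning is
exhaustive including overlapping matches, forward strand only — the
built-ins MseI (T^TAA), PstI (CTGCA^G) and AvaII (G^GWCC) are
palindromic, so the reverse strand adds nothing (property-tested).
Sequences are digested as linear molecules after gap stripping: cuts
de-duplicated by position, n cuts → n+1 fragments, fragment lengths
always summing to the ungapped length. In strict mode (default) an
ambiguity code in the *sequence* never matches; permissive mode accepts
compatible expansions. Enzyme discrimination power = number of haplotype
pairs whose fragment-length multisets differ; ranking breaks ties by
fewer total cuts, then name. Because published RFLP tables are often
ambiguous between cut positions and fragment lengths, reports always
contain both.

## Neighbor joining and bootstrap

Standard Saitou–Nei NJ with the Q-criterion. Determinism is a contract:
the first minimal pair in label-index order wins ties, and negative
branch lengths are clamped to 0 with a logged count, so a fixed input
yields a byte-identical Newick string. NJ requires a fully defined
matrix; undefined pairs raise an error naming the samples to exclude.
Bootstrap resamples alignment columns with replacement (default 1000
replicates), recomputes K2P + NJ per replicate, and reports for each
internal edge the percentage of retained replicates containing the same
leaf bipartition; replicates with undefined distances are dropped and
logged. Maximum-likelihood tree inference is deliberately out of scope —
NJ over the same matrix supports the clade-level sanity checks this
toolkit needs (e.g. conspecific monophyly on clean simulated data).

## Synthetic data

`simulate_barcode_set` emulates an ITS2-like study: root drawn i.i.d.
with a GC target (default 0.60, echoing the ~60% GC of real ITS2),
length uniform in 325–375 bp, substitutions under the K2P rate matrix
with κ = 2.0 (a typical nuclear ribosomal transition/transversion rate
ratio). Species sit on a star phylogeny by default: species ancestors at
depth (inter − intra)/2 below the root, samples at depth intra/2 below
their ancestor. `inter_divergence` and `intra_divergence` are therefore
the *expected pairwise K2P distances* between heterospecific and
conspecific samples respectively — the property the estimator-recovery
tests exploit — which requires inter ≥ intra. Defaults (intra 0.035,
inter 0.19) mirror the divergence levels reported for ITS2 in *Musa*.
The star design makes expected inter-divergence uniform and analytically
checkable; a random-bifurcating mode exists for tree tests, and an
optional per-site gap mode exercises the pairwise-deletion and
indel-exclusion paths. No indels, rate heterogeneity, base-composition
drift or sequencing error are modeled: passing tests show the estimators
and decision rules behave correctly under their matched model, not that
real ITS2 data are this clean.

`simulate_coalescent` implements the standard neutral coalescent
(exponential waiting times at rate k(k−1)/2, time in units of 2N
generations), with mutation count Poisson(θ/2 × total branch length)
placed branch-weighted on distinct sites — infinite sites approximated
on L sites with collision redraw, erroring when mutations exceed L.
Variants are written as G on an A background. E[S] = θa₁ and
E[π·L] = θ serve as closed-form oracles.

`plant_restriction_haplotypes` engineers haplotypes whose
restriction-site presence/absence is known bit-by-bit (haplotype h
carries enzyme k's site iff bit k of h is set, each at a fixed
non-overlapping window, pre-existing sites scrubbed), yielding an exact
truth table for the discrimination ranking; capacity is 2^(number of
enzymes) haplotypes.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so
each stochastic check retains clear statistical power: 1000 random pairs
for the K2P oracle, 50 replicate 10 × 5 sets for gap/identification
recovery, 1000 (tests) or 300 (script) coalescent replicates at n = 20,
θ = 5, 1000 random 400-mers per enzyme, 100 random additive 6-taxon
matrices for NJ consistency. Distance tie tolerance 1e−12; histogram
bins anchored at 0; haplotype and NJ tie-breaks by first occurrence /
label order; all simulation randomness flows from a single seeded
generator per run.

## Known limitations

* K2P only — no other substitution models or gamma rate correction.
* The BLAST1 method searches the study's own reference set, not an
  external database; no E-values.
* No smoothed density estimation for the gap, no multi-marker framework,
  no recombination-aware or sliding-window diversity statistics.
* Digestion ignores methylation sensitivity and star activity; molecules
  are linear.
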