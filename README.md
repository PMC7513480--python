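# musabarcode

Evaluation toolkit for short DNA barcode markers, built around the analyses
used to judge whether a locus such as the nuclear ribosomal ITS2 spacer can
authenticate closely related plant species and cultivars (the motivating
case is *Musa* — banana — cultivar identification).

Given an aligned FASTA of barcode sequences with species labels, the
package computes:

* **Pairwise distances** under the Kimura 2-parameter (K2P) model with
  pairwise deletion: with transition proportion *P* and transversion
  proportion *Q* over the compared sites,
  *d* = −½ ln[(1 − 2P − Q)·√(1 − 2Q)].
  Undefined and saturated pairs are flagged, never coerced.
* **Barcoding-gap statistics**: six divergence metrics (all inter-specific
  distance, theta prime, minimum inter-specific distance, all
  intra-specific distance, theta, coalescent depth), binned intra/inter
  distance distributions at a configurable width (default 0.008), overlap
  fractions, threshold proportions, and a Wilcoxon rank-sum test
  (exact permutation enumeration for small samples, tie-corrected normal
  approximation otherwise).
* **Species identification** by leave-one-out queries under two methods:
  nearest K2P distance ("DISTANCE") and best local-alignment hit
  ("BLAST1"), with correct / ambiguous / incorrect outcome rules and
  per-species success rates.
* **Polymorphism and neutrality statistics** per group (e.g. genome
  constitution AA, AAB, BB): segregating sites *S*, haplotypes *H*,
  nucleotide diversity π, Watterson's θ<sub>W</sub> = S/(a₁L), and
  Tajima's *D*, with indel-containing columns excluded.
* **In-silico PCR-RFLP**: restriction digestion with IUPAC-degenerate
  recognition sites (built-ins MseI, PstI, AvaII; extendable via a TSV
  table), fragment-length profiles, and ranking of enzymes by how many
  haplotype pairs their fragment patterns separate.
* **Neighbor-joining trees** from the K2P matrix with column-bootstrap
  support, exported as Newick.
* **Synthetic data**: a species-structured K2P barcode simulator (default
  conditions: 325–375 bp, 60% GC, within-species divergence 0.035,
  between-species divergence 0.19 substitutions/site) and a neutral
  coalescent simulator, so every stage can be benchmarked against known
  truth.

## Worked example

Simulate a 10-species set with a clear barcoding gap and evaluate it:

```python
from musabarcode import (
    SimConfig, simulate_barcode_set, build_matrix,
    divergence_summary, gap_histogram, evaluate_identification,
)

cfg = SimConfig(n_species=10, samples_per_species=5,
                inter_divergence=0.20, intra_divergence=0.02, seed=42)
aln, truth = simulate_barcode_set(cfg)
dm = build_matrix(aln)
summ = divergence_summary(dm, aln.species_of)
hist = gap_histogram(dm, aln.species_of, bin_width=0.008)
report = evaluate_identification(aln, dm=dm)

print(f"all inter:  {summ.all_inter.mean:.4f} +/- {summ.all_inter.sd:.4f}")
print(f"all intra:  {summ.all_intra.mean:.4f} +/- {summ.all_intra.sd:.4f}")
print(f"overlap fraction: {hist.overlap_fraction:.3f}")
print(f"DISTANCE correct: {report.success_rate('DISTANCE'):.1f}%")
print(f"BLAST1 correct:   {report.success_rate('BLAST1'):.1f}%")
```

Output:

```
all inter:  0.2009 +/- 0.0190
all intra:  0.0221 +/- 0.0077
overlap fraction: 0.000
DISTANCE correct: 100.0%
BLAST1 correct:   100.0%
```

The inter- and intra-specific means recover the simulated divergences
(0.20 and 0.02); an overlap fraction of 0 means no between-species pair is
as close as the widest within-species pair — a clean barcoding gap — and
under that gap both identification methods assign every leave-one-out
query to its true species.

The same pipeline runs from the shell:

```bash
musabarcode simulate --n-species 10 --samples-per-species 5 \
    --inter 0.20 --intra 0.02 --seed 42 demo.fasta
musabarcode run-all demo.fasta results/ --bootstrap 100 --threshold 0.135
```

which writes the distance matrix, divergence summary, gap histogram,
identification reports, polymorphism table, digest report, Newick tree and
a JSON manifest into `results/`.

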