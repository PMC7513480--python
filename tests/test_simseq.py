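import math

import numpy as np
import pytest

from musabarcode.distmat import build_matrix, k2p
from musabarcode.gapstats import divergence_summary
from musabarcode.popgen import segregating_sites, tajima_d
from musabarcode.redigest import BUILTIN_ENZYMES, digest, discriminate_haplotypes
from musabarcode.seqio import write_fasta
from musabarcode.simseq import (
    SimConfig,
    plant_restriction_haplotypes,
    simulate_barcode_set,
    simulate_coalescent,
    simulate_k2p_pair,
)


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_species=0)
        with pytest.raises(ValueError):
            SimConfig(intra_divergence=0.3, inter_divergence=0.2)
        with pytest.raises(ValueError):
            SimConfig(kappa=0)
        with pytest.raises(ValueError):
            SimConfig(gc_target=1.2)


class TestBarcodeSet:
    def test_shape_and_labels(self):
        cfg = SimConfig(n_species=4, samples_per_species=3, seed=1)
        aln, truth = simulate_barcode_set(cfg)
        assert len(aln) == 12
        assert aln.n_species() == 4
        assert 325 <= aln.length <= 375
        assert truth.species_of == aln.species_of

    def test_zero_intra_divergence_makes_conspecifics_identical(self):
        cfg = SimConfig(
            n_species=3, samples_per_species=4, inter_divergence=0.2,
            intra_divergence=0.0, seed=2,
        )
        aln, _ = simulate_barcode_set(cfg)
        dm = build_matrix(aln)
        summ = divergence_summary(dm, aln.species_of)
        assert summ.all_intra.mean == 0.0
        by_species = {}
        for r in aln.records:
            by_species.setdefault(r.species, set()).add(r.residues)
        assert all(len(v) == 1 for v in by_species.values())

    def test_fixed_seed_reproduces_bytes(self, tmp_path):
        cfg = SimConfig(n_species=3, samples_per_species=2, seed=9)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(simulate_barcode_set(cfg)[0].records, p1)
        write_fasta(simulate_barcode_set(cfg)[0].records, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_root_gc_near_target(self):
        gcs = []
        for seed in range(30):
            cfg = SimConfig(
                n_species=1, samples_per_species=1, length_range=(350, 350),
                inter_divergence=0.0, intra_divergence=0.0, seed=seed,
            )
            _, truth = simulate_barcode_set(cfg)
            s = truth.root_sequence
            gcs.append((s.count("G") + s.count("C")) / len(s))
        assert abs(np.mean(gcs) - 0.60) < 0.03

    def test_divergence_recovery_under_matched_model(self):
        """all_inter and all_intra recover the configured divergences (3 SE)."""
        inters, intras = [], []
        for i in range(20):
            cfg = SimConfig(
                n_species=10, samples_per_species=5, inter_divergence=0.2,
                intra_divergence=0.02, length_range=(350, 350), seed=900 + i,
            )
            aln, _ = simulate_barcode_set(cfg)
            s = divergence_summary(build_matrix(aln), aln.species_of)
            inters.append(s.all_inter.mean)
            intras.append(s.all_intra.mean)
        for est, truth in ((np.array(inters), 0.2), (np.array(intras), 0.02)):
            se = est.std(ddof=1) / math.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * se

    def test_pair_simulator_recovery(self):
        rng = np.random.default_rng(12)
        ds = [k2p(*simulate_k2p_pair(0.1, 350, 2.0, rng)) for _ in range(200)]
        ds = np.asarray(ds)
        se = ds.std(ddof=1) / math.sqrt(len(ds))
        assert abs(ds.mean() - 0.1) < 3 * se

    def test_indel_mode_introduces_gaps(self):
        cfg = SimConfig(n_species=2, samples_per_species=2, gap_fraction=0.05, seed=3)
        aln, _ = simulate_barcode_set(cfg)
        assert any("-" in r.residues for r in aln.records)
        # pipeline still runs with pairwise deletion
        dm = build_matrix(aln)
        assert np.isfinite(np.nanmax(dm.values))

    def test_bifurcating_mode_runs(self):
        cfg = SimConfig(n_species=6, samples_per_species=2, seed=4,
                        species_tree="bifurcating")
        aln, truth = simulate_barcode_set(cfg)
        assert aln.n_species() == 6
        assert len(truth.species_ancestors) == 6


class TestCoalescent:
    def test_theta_zero_monomorphic(self):
        aln = simulate_coalescent(10, 0.0, 100, seed=1)
        assert segregating_sites(aln)[0] == 0

    def test_watterson_expectation(self):
        a1 = sum(1 / i for i in range(1, 20))
        S = [
            segregating_sites(simulate_coalescent(20, 5.0, 500, seed=60_000 + i))[0]
            for i in range(300)
        ]
        S = np.asarray(S, dtype=float)
        se = S.std(ddof=1) / math.sqrt(len(S))
        assert abs(S.mean() - 5.0 * a1) < 3 * se

    def test_mutation_overflow_raises(self):
        with pytest.raises(ValueError, match="sites"):
            simulate_coalescent(20, 50.0, 3, seed=0)

    def test_determinism(self):
        a = simulate_coalescent(8, 2.0, 200, seed=5)
        b = simulate_coalescent(8, 2.0, 200, seed=5)
        assert [r.residues for r in a] == [r.residues for r in b]


class TestPlantedHaplotypes:
    BASE = "ACGTAC" * 70

    def test_single_haplotype_empty_truth(self):
        haps, truth = plant_restriction_haplotypes(
            self.BASE, 1, list(BUILTIN_ENZYMES.values()), seed=1
        )
        assert len(haps) == 1
        assert truth == {}

    def test_two_haplotypes_one_planted_site(self):
        msei = BUILTIN_ENZYMES["MseI"]
        psti = BUILTIN_ENZYMES["PstI"]
        haps, truth = plant_restriction_haplotypes(self.BASE, 2, [msei, psti], seed=2)
        assert truth[(0, 1)] == {"MseI"}
        d0 = digest(haps[0], msei)
        d1 = digest(haps[1], msei)
        assert d0.fragment_lengths != d1.fragment_lengths
        assert digest(haps[0], psti).fragment_lengths == digest(haps[1], psti).fragment_lengths

    @pytest.mark.parametrize("n_haps", [2, 3, 4])
    def test_truth_table_matches_discrimination(self, n_haps):
        enzymes = list(BUILTIN_ENZYMES.values())
        haps, truth = plant_restriction_haplotypes(self.BASE, n_haps, enzymes, seed=7)
        profiles = {
            h.sample_id: {e.name: digest(h, e) for e in enzymes} for h in haps
        }
        hap_of = {h.sample_id: i for i, h in enumerate(haps)}
        ranking = dict(discriminate_haplotypes(profiles, hap_of))
        expected = {
            e.name: sum(1 for pair in truth.values() if e.name in pair)
            for e in enzymes
        }
        assert ranking == expected

    def test_capacity_and_length_limits(self):
        enzymes = list(BUILTIN_ENZYMES.values())
        with pytest.raises(ValueError, match="at most"):
            plant_restriction_haplotypes(self.BASE, 9, enzymes, seed=0)
        with pytest.raises(ValueError, match="too short"):
            plant_restriction_haplotypes("ACGTACGT", 2, enzymes, seed=0)


def test_clear_gap_pipeline_end_to_end(clear_gap_set, clear_gap_matrix):
    """A clear-gap synthetic set flows through every stage with the expected signal."""
    from musabarcode.gapstats import gap_histogram
    from musabarcode.identify import evaluate_identification
    from musabarcode.njtree import nj

    aln, _ = clear_gap_set
    hist = gap_histogram(clear_gap_matrix, aln.species_of)
    assert hist.overlap_fraction == 0.0
    report = evaluate_identification(aln, dm=clear_gap_matrix, methods=("DISTANCE",))
    assert report.success_rate("DISTANCE") == 100.0
    tree = nj(clear_gap_matrix)
    # conspecific samples cluster: the full species clade is a bipartition
    full = frozenset(aln.labels)
    splits = tree.bipartitions()
    for species in sorted(set(aln.species_of.values())):
        members = frozenset(l for l, s in aln.species_of.items() if s == species)
        assert frozenset({members, full - members}) in splits
    d = tajima_d(aln)
    assert math.isfinite(d)
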