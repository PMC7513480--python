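import math

import numpy as np
import pytest

from musabarcode.popgen import (
    diversity,
    group_summaries,
    haplotypes,
    segregating_sites,
    tajima_d,
)
from musabarcode.seqio import LabeledSequence, validate_alignment
from musabarcode.simseq import simulate_coalescent

# hand-verified values for the 4x16 toy (S=3, pairwise diffs {1,2,3,1,2,1})
TOY_KBAR = 10 / 6
TOY_PI = TOY_KBAR / 16
TOY_THETA_W = 3 / ((1 + 1 / 2 + 1 / 3) * 16)
TOY_D = 0.16765579503394926


def aln_of(*seqs, species="sp"):
    return validate_alignment(
        [LabeledSequence(f"s{i + 1}", species, s) for i, s in enumerate(seqs)]
    )


class TestSegregatingSites:
    def test_identical_sequences(self):
        aln = aln_of("ACGTACGT", "ACGTACGT")
        assert segregating_sites(aln) == (0, [])

    def test_toy_positions_one_based(self, tajima_toy):
        S, pos = segregating_sites(tajima_toy)
        assert S == 3
        assert pos == [14, 15, 16]

    def test_gapped_column_excluded_even_if_variable(self):
        aln = aln_of("ACGT", "A-TT", "ACTT")
        # column 2 has a gap -> excluded; column 3 varies (G/T/T)
        S, pos = segregating_sites(aln)
        assert S == 1
        assert pos == [3]

    def test_ambiguity_column_excluded(self):
        aln = aln_of("ACGT", "ANTT")
        S, pos = segregating_sites(aln)
        assert pos == [3]


class TestHaplotypes:
    def test_all_identical(self):
        H, _ = haplotypes(aln_of("ACGT", "ACGT", "ACGT"))
        assert H == 1

    def test_all_distinct(self, tajima_toy):
        H, assignment = haplotypes(tajima_toy)
        assert H == 4
        assert sorted(assignment.values()) == [0, 1, 2, 3]

    def test_difference_inside_excluded_column_ignored(self):
        # sequences differ only at column 2, which is gapped in a third row
        aln = aln_of("AAGT", "ACGT", "A-GT")
        H, assignment = haplotypes(aln)
        assert H == 1
        assert len(set(assignment.values())) == 1

    def test_numbering_by_first_occurrence(self):
        aln = aln_of("ACGT", "TCGT", "ACGT")
        _, assignment = haplotypes(aln)
        assert assignment == {"s1": 0, "s2": 1, "s3": 0}


class TestDiversity:
    def test_toy_hand_enumeration(self, tajima_toy):
        div = diversity(tajima_toy)
        assert div.mean_pairwise_k == pytest.approx(TOY_KBAR, abs=1e-12)
        assert div.pi == pytest.approx(TOY_PI, abs=1e-12)
        assert div.theta_w == pytest.approx(TOY_THETA_W, abs=1e-12)

    def test_monomorphic_gives_zero(self):
        div = diversity(aln_of("ACGT", "ACGT"))
        assert div.pi == 0.0 and div.theta_w == 0.0

    def test_n2_pi_equals_k_over_l_and_theta_equals_s_over_l(self):
        div = diversity(aln_of("ACGTACGTAC", "ACGTACGTAG"))
        assert div.pi == pytest.approx(1 / 10)
        assert div.theta_w == pytest.approx(1 / 10)

    def test_all_columns_excluded_flagged(self):
        div = diversity(aln_of("----", "ACGT"))
        assert not div.defined
        assert math.isnan(div.pi)

    def test_invariant_under_reordering(self, tajima_toy):
        shuffled = validate_alignment(list(tajima_toy.records)[::-1])
        assert diversity(shuffled).pi == diversity(tajima_toy).pi
        assert diversity(shuffled).theta_w == diversity(tajima_toy).theta_w


class TestTajimaD:
    def test_toy_matches_hand_derivation(self, tajima_toy):
        assert tajima_d(tajima_toy) == pytest.approx(TOY_D, abs=1e-9)

    def test_undefined_when_no_segregating_sites(self):
        assert math.isnan(tajima_d(aln_of("ACGT", "ACGT", "ACGT", "ACGT")))

    def test_undefined_below_four_sequences(self):
        assert math.isnan(tajima_d(aln_of("ACGT", "ACGA", "ACGG")))

    def test_singleton_heavy_below_balanced(self):
        # same S; singletons depress pi relative to S/a1
        balanced = aln_of(
            "AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA",
            "GGGAAAAAAA", "GGGAAAAAAA", "GGGAAAAAAA",
        )
        singleton = aln_of(
            "AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA",
            "GAAAAAAAAA", "AGAAAAAAAA", "AAGAAAAAAA",
        )
        assert tajima_d(singleton) < tajima_d(balanced)

    def test_neutral_coalescent_mean_slightly_negative(self):
        """Mean D under neutrality sits at its small negative expectation.

        D is a ratio statistic whose normalization does not make it
        mean-zero: at n=20, theta=5 its finite-sample expectation is about
        -0.06 (frozen here from a 4000-replicate run cross-checked against
        an independent coalescent simulator; see the msprime test below).
        """
        ds = []
        for i in range(300):
            aln = simulate_coalescent(20, 5.0, 400, seed=20_000 + i)
            d = tajima_d(aln)
            if not math.isnan(d):
                ds.append(d)
        ds = np.asarray(ds)
        se = ds.std(ddof=1) / math.sqrt(len(ds))
        assert abs(ds.mean() - (-0.06)) < 3 * se

    def test_mean_d_agrees_with_msprime_coalescent(self):
        """Our coalescent + D pipeline matches msprime-simulated genealogies.

        Haploid samples with population size 1 give coalescence rate
        k(k-1)/2 in units matching simulate_coalescent; mutation rate
        theta/2 on an infinite-sites genome reproduces E[S] = theta * a1.
        """
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 20, 5.0, 300
        ours_d, ours_s = [], []
        for i in range(reps):
            aln = simulate_coalescent(n, theta, 500, seed=80_000 + i)
            ours_s.append(segregating_sites(aln)[0])
            d = tajima_d(aln)
            if not math.isnan(d):
                ours_d.append(d)
        theirs_d, theirs_s = [], []
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a2 + a1**2)
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1, random_seed=1 + i
            )
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=10_000 + i, discrete_genome=False
            )
            S = mts.num_sites
            theirs_s.append(S)
            if S == 0:
                continue
            counts = (mts.genotype_matrix() > 0).sum(axis=1)
            kbar = (counts * (n - counts)).sum() / (n * (n - 1) / 2)
            theirs_d.append(
                (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
            )
        for ours, theirs in ((ours_s, theirs_s), (ours_d, theirs_d)):
            a, b = np.asarray(ours, dtype=float), np.asarray(theirs, dtype=float)
            se = math.hypot(a.std(ddof=1) / math.sqrt(len(a)),
                            b.std(ddof=1) / math.sqrt(len(b)))
            assert abs(a.mean() - b.mean()) < 3 * se


class TestGroupSummaries:
    def test_single_group_equals_global(self, tajima_toy):
        rows = group_summaries(tajima_toy, {r.sample_id: "g" for r in tajima_toy})
        group_row = next(r for r in rows if r.group == "g")
        overall = next(r for r in rows if r.group == "Over All")
        assert group_row.S == overall.S == 3
        assert group_row.pi == overall.pi

    def test_group_s_bounded_by_global(self, clear_gap_set):
        aln, _ = clear_gap_set
        rows = group_summaries(aln, aln.species_of)
        overall = next(r for r in rows if r.group == "Over All")
        for r in rows:
            assert r.S <= overall.S

    def test_small_group_flagged_undefined(self, tajima_toy):
        grouping = {"s1": "solo", "s2": "rest", "s3": "rest", "s4": "rest"}
        rows = group_summaries(tajima_toy, grouping)
        solo = next(r for r in rows if r.group == "solo")
        assert solo.n == 1
        assert math.isnan(solo.pi)

    def test_theta_ratio_recovery_between_groups(self):
        """Groups simulated at theta 5 vs 1.25 recover both levels, hence ratio 4.

        Watterson's estimator is unbiased for theta (E[S/a1] = theta), so
        each group's mean estimate is compared to its truth; the ratio of
        the recovered means then sits at the simulated fourfold contrast.
        """
        hi = np.asarray([
            diversity(simulate_coalescent(15, 5.0, 600, seed=40_000 + i)).theta_w * 600
            for i in range(150)
        ])
        lo = np.asarray([
            diversity(simulate_coalescent(15, 1.25, 600, seed=50_000 + i)).theta_w * 600
            for i in range(150)
        ])
        for est, truth in ((hi, 5.0), (lo, 1.25)):
            se = est.std(ddof=1) / math.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * se
        assert hi.mean() / lo.mean() == pytest.approx(4.0, rel=0.25)
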