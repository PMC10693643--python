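"""Summary statistics against brute-force oracles and constructed fixtures."""

import numpy as np
import pytest

from _oracles import (
    brute_folded_sfs,
    brute_hudson_fst,
    brute_pi,
    brute_segregating,
    brute_site_partition,
)
from splitabc.sumstats import (
    IBDSegment,
    StatsInputError,
    compute_summary_vector,
    detect_ibd,
    detect_roh,
    diversity_stats,
    divergence_stats,
    filter_low_density,
    ibd_bin_stats,
    merge_ibd_gaps,
    registry_names,
    site_frequency_spectrum,
)


def haps_to_genotypes(haps):
    h = np.asarray(haps, dtype=np.int8)
    return h[0::2] + h[1::2]


# ---------------------------------------------------------------------------
# diversity / divergence vs brute force
# ---------------------------------------------------------------------------


class TestDiversityOracle:
    def test_worked_example(self):
        # 4 haplotypes, columns 1000 / 1100 / 1110 -> S=3, pi=10/6
        haps = np.array([[1, 1, 1], [0, 1, 1], [0, 0, 1], [0, 0, 0]])
        d = diversity_stats(haps_to_genotypes(haps))
        assert d["S"] == 3
        assert d["pi"] == pytest.approx(10 / 6)
        assert d["pi"] == pytest.approx(brute_pi(haps) * 3 / 3)

    def test_monomorphic_panel(self):
        g = np.zeros((5, 10), dtype=np.int8)
        d = diversity_stats(g)
        assert d["S"] == 0 and d["pi"] == 0 and d["het_mean"] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_panels_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_hap, n_sites = 10, rng.integers(20, 200)
        haps = (rng.random((n_hap, n_sites)) < rng.uniform(0.05, 0.6, n_sites)).astype(np.int8)
        g = haps_to_genotypes(haps)
        d = diversity_stats(g)
        assert d["S"] == brute_segregating(haps)
        n_pairs = n_hap * (n_hap - 1) / 2
        assert d["pi"] == pytest.approx(brute_pi(haps) * n_pairs / n_pairs * 1.0)
        # pi: mean pairwise Hamming distance summed over the panel
        assert d["pi"] == pytest.approx(brute_pi(haps))
        sfs = site_frequency_spectrum(g)
        assert np.array_equal(sfs, brute_folded_sfs(haps))
        assert d["singletons"] == sfs[0]
        assert d["doubletons"] == sfs[1]

    def test_tajimas_d_zero_when_pi_equals_watterson(self):
        # 4 haplotypes, a1 = 11/6; 8 singleton + 3 doubleton columns give
        # pi = 8*(1/2) + 3*(2/3) = 6 = S/a1
        cols = [[1, 0, 0, 0]] * 8 + [[1, 1, 0, 0]] * 3
        haps = np.array(cols).T
        d = diversity_stats(haps_to_genotypes(haps))
        assert d["S"] == 11
        assert d["pi"] == pytest.approx(6.0)
        assert d["tajimas_d"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(StatsInputError):
            diversity_stats(np.zeros((0, 5), dtype=np.int8))


class TestDivergenceOracle:
    def test_identical_frequencies_give_zero_fst(self, rng):
        # two independent samples from one set of allele frequencies: the
        # Hudson estimator is unbiased around zero divergence
        freqs = rng.uniform(0.2, 0.8, 3000)
        draw = lambda n: (
            (rng.random((n, freqs.size)) < freqs).astype(np.int8)
            + (rng.random((n, freqs.size)) < freqs).astype(np.int8)
        )
        d = divergence_stats(draw(60), draw(60))
        assert d["fst"] == pytest.approx(0.0, abs=0.01)

    def test_fixed_difference(self):
        ga = np.zeros((3, 1), dtype=np.int8)
        gb = np.full((3, 1), 2, dtype=np.int8)
        d = divergence_stats(ga, gb)
        assert d["fixed_diff"] == 1
        assert d["fst"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_random_panels_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = 150
        hap_a = (rng.random((8, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.int8)
        hap_b = (rng.random((6, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.int8)
        d = divergence_stats(haps_to_genotypes(hap_a), haps_to_genotypes(hap_b))
        assert d["fst"] == pytest.approx(brute_hudson_fst(hap_a, hap_b), rel=1e-12)
        partition = brute_site_partition(hap_a, hap_b)
        for key, value in partition.items():
            assert d[key] == value, key
        # conservation: the partition covers every overall-segregating site
        total = haps_to_genotypes(np.vstack([hap_a, hap_b]))
        assert sum(partition.values()) == diversity_stats(total)["S"]


# ---------------------------------------------------------------------------
# IBD detection
# ---------------------------------------------------------------------------


def _uniform_cm(n_sites, total_cm):
    return np.linspace(0.0, total_cm, n_sites)


def _hwe_cohort(rng, n_ind, freqs):
    return (
        (rng.random((n_ind, freqs.size)) < freqs).astype(np.int8)
        + (rng.random((n_ind, freqs.size)) < freqs).astype(np.int8)
    )


class TestDetectIBD:
    def test_duplicated_individual_shares_whole_chromosome(self, rng):
        n_sites = 2000
        freqs = rng.uniform(0.1, 0.9, n_sites)
        g = _hwe_cohort(rng, 10, freqs)
        g[9] = g[0]  # individual 9 is a copy of individual 0
        cm = _uniform_cm(n_sites, 20.0)
        segs = [s for s in detect_ibd(g, np.arange(n_sites) * 1000.0, cm)
                if {s.id1, s.id2} == {0, 9}]
        assert segs
        assert max(s.length_cm for s in segs) > 0.8 * 20.0

    def test_opposite_homozygotes_kill_segments(self, rng):
        n_sites = 1000
        g = np.ones((6, n_sites), dtype=np.int8)
        g[0, ::5] = 0
        g[1, ::5] = 2
        for i in range(2, 6):  # background cohort establishing frequencies
            g[i, ::5] = rng.integers(0, 3, n_sites // 5 + (n_sites % 5 > 0))
        cm = _uniform_cm(n_sites, 20.0)  # opposite homozygote every ~0.1 cM
        segs = [s for s in detect_ibd(g, np.arange(n_sites) * 1000.0, cm)
                if {s.id1, s.id2} == {0, 1}]
        assert all(s.length_cm < 2.0 for s in segs) and not segs

    def test_sibling_pairs_share_more_than_random_pairs(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            n_sites = 2500
            freqs = rng.uniform(0.1, 0.9, n_sites)
            cohort = _hwe_cohort(rng, 12, freqs)
            # two parents, two children: each child inherits one recombined
            # haplotype per parent (two crossovers per meiosis)
            parents = [(rng.random((2, n_sites)) < freqs).astype(np.int8) for _ in range(4)]

            def gamete(parent):
                cuts = np.sort(rng.integers(1, n_sites, 2))
                which = np.zeros(n_sites, dtype=int)
                which[cuts[0]:cuts[1]] = 1
                return parent[which, np.arange(n_sites)]

            sib1 = gamete(parents[0]) + gamete(parents[1])
            sib2 = gamete(parents[0]) + gamete(parents[1])
            g = np.vstack([cohort, sib1, sib2]).astype(np.int8)
            cm = _uniform_cm(n_sites, 25.0)
            segs = detect_ibd(g, np.arange(n_sites) * 1000.0, cm,
                              pairs=[(0, 1), (12, 13)])
            random_total = sum(s.length_cm for s in segs if {s.id1, s.id2} == {0, 1})
            sib_total = sum(s.length_cm for s in segs if {s.id1, s.id2} == {12, 13})
            wins += sib_total > random_total
        assert wins >= 19

    def test_total_ibd_monotone_in_lod_threshold(self, rng):
        n_sites = 1500
        freqs = rng.uniform(0.1, 0.9, n_sites)
        g = _hwe_cohort(rng, 8, freqs)
        g[7, : n_sites // 2] = g[0, : n_sites // 2]  # half-shared pair
        cm = _uniform_cm(n_sites, 15.0)
        pos = np.arange(n_sites) * 1000.0
        totals = [
            sum(s.length_cm for s in detect_ibd(g, pos, cm, lod_threshold=t))
            for t in (1.0, 3.0, 6.0)
        ]
        assert totals[0] >= totals[1] >= totals[2]


class TestMergeAndFilter:
    def _fixture(self):
        """Two segments for pair (0,1) with a 5-site gap; cM = 0.1/site."""
        n_sites = 100
        cm = np.arange(n_sites) * 0.1
        g = np.ones((2, n_sites), dtype=np.int8)
        segs = [
            IBDSegment(0, 1, 0.0, 29e3, cm[0], cm[29], 10.0, 0, 30),
            IBDSegment(0, 1, 35e3, 59e3, cm[35], cm[59], 8.0, 35, 60),
        ]
        return g, cm, segs

    def test_small_concordant_gap_merged(self):
        g, cm, segs = self._fixture()
        # gap cM = cm[35] - cm[29] = 0.6 exactly -> widen by shifting: use
        # segments 0.5 cM apart instead
        segs[1] = IBDSegment(0, 1, 34e3, 59e3, cm[34], cm[59], 8.0, 34, 60)
        merged = merge_ibd_gaps(segs, g, cm)
        assert len(merged) == 1
        assert merged[0].start_idx == 0 and merged[0].end_idx == 60
        assert merged[0].score == pytest.approx(18.0)

    def test_two_discordant_homozygotes_block_merge(self):
        g, cm, segs = self._fixture()
        segs[1] = IBDSegment(0, 1, 34e3, 59e3, cm[34], cm[59], 8.0, 34, 60)
        g[0, 31] = 0
        g[1, 31] = 2
        g[0, 33] = 2
        g[1, 33] = 0
        assert len(merge_ibd_gaps(segs, g, cm)) == 2

    def test_one_discordant_homozygote_allows_merge(self):
        g, cm, segs = self._fixture()
        segs[1] = IBDSegment(0, 1, 34e3, 59e3, cm[34], cm[59], 8.0, 34, 60)
        g[0, 31] = 0
        g[1, 31] = 2
        assert len(merge_ibd_gaps(segs, g, cm)) == 1

    def test_wide_gap_not_merged(self):
        g, cm, segs = self._fixture()
        # gap cm[36] - cm[29] = 0.7
        segs[1] = IBDSegment(0, 1, 36e3, 59e3, cm[36], cm[59], 8.0, 36, 60)
        assert len(merge_ibd_gaps(segs, g, cm)) == 2

    def test_iterative_chain_merge(self):
        n_sites = 100
        cm = np.arange(n_sites) * 0.1
        g = np.ones((2, n_sites), dtype=np.int8)
        segs = [
            IBDSegment(0, 1, 0, 0, cm[0], cm[20], 5.0, 0, 21),
            IBDSegment(0, 1, 0, 0, cm[25], cm[45], 5.0, 25, 46),
            IBDSegment(0, 1, 0, 0, cm[50], cm[70], 5.0, 50, 71),
        ]
        merged = merge_ibd_gaps(segs, g, cm)
        assert len(merged) == 1 and merged[0].end_idx == 71

    def test_density_filter(self):
        seg_dense = IBDSegment(0, 1, 0, 0, 0.0, 2.0, 5.0, 0, 100)  # 50 snps/cM
        seg_sparse = IBDSegment(0, 1, 0, 0, 0.0, 2.0, 5.0, 0, 99)
        seg_empty = IBDSegment(0, 1, 0, 0, 0.0, 2.0, 5.0, 10, 10)
        kept = filter_low_density([seg_dense, seg_sparse, seg_empty], 50.0)
        assert kept == [seg_dense]  # boundary retained, sparse and empty dropped


# ---------------------------------------------------------------------------
# ROH detection (hand-enumerated fixtures)
# ---------------------------------------------------------------------------


def _with_het_cohort(target_row):
    """Stack the scanned individual over 9 all-heterozygous individuals so
    every site passes the MAF filter while contributing no ROH of its own."""
    S = target_row.size
    cohort = np.ones((9, S), dtype=np.int8)
    return np.vstack([target_row[None, :], cohort])


class TestDetectROH:
    def test_fully_heterozygous_individual(self):
        g = np.ones((10, 80), dtype=np.int8)
        pos = np.arange(80) * 5000.0
        assert detect_roh(g, pos) == []

    def test_whole_chromosome_homozygous_run(self):
        # 60 homozygous SNPs spanning ~401 kb: all windows homozygous, every
        # SNP's window fraction is 1 -> exactly one ROH with all 60 SNPs
        row = np.zeros(60, dtype=np.int8)
        g = _with_het_cohort(row)
        pos = np.arange(60) * 6800.0
        segs = detect_roh(g, pos)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.individual == 0
        assert seg.n_snps == 60
        assert seg.length_kb == int(59 * 6800) // 1000 == 401

    def test_short_run_fails_min_snps(self):
        row = np.zeros(40, dtype=np.int8)  # spans 400 kb but only 40 SNPs
        g = _with_het_cohort(row)
        pos = np.arange(40) * 10_300.0
        assert detect_roh(g, pos) == []

    def test_embedded_run_hand_enumeration(self):
        """60 homozygous SNPs (indices 70..129) inside a heterozygous
        background of 200 SNPs, 7 kb apart.

        Homozygous 50-SNP windows (het tolerance 1) start at 69..81; a SNP
        needs >= 3 of its 50 overlapping windows homozygous to reach the
        0.05 fraction, which holds exactly for SNPs 71..128.
        """
        row = np.ones(200, dtype=np.int8)
        row[70:130] = 0
        g = _with_het_cohort(row)
        pos = np.arange(200) * 7000.0
        segs = detect_roh(g, pos)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_bp, seg.end_bp) == (71 * 7000.0, 128 * 7000.0)
        assert seg.n_snps == 58
        assert seg.length_kb == 399

    def test_gap_splits_runs(self):
        # homozygous throughout, but a 1.2 Mb gap in the middle splits the
        # run into two halves that each satisfy every threshold
        row = np.zeros(120, dtype=np.int8)
        g = _with_het_cohort(row)
        pos = np.concatenate([np.arange(60) * 7000.0, 1_800_000 + np.arange(60) * 7000.0])
        segs = detect_roh(g, pos)
        assert len(segs) == 2
        assert all(s.n_snps == 60 for s in segs)

    def test_unsorted_positions_rejected(self):
        g = np.zeros((2, 3), dtype=np.int8)
        with pytest.raises(StatsInputError):
            detect_roh(g, np.array([3.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# binned IBD and the 46-statistic registry
# ---------------------------------------------------------------------------


def _seg(id1, id2, length_cm):
    return IBDSegment(id1, id2, 0.0, 0.0, 0.0, length_cm, 5.0, 0, 10)


class TestIbdBins:
    def test_single_segment(self):
        out = ibd_bin_stats([_seg(0, 1, 3.0)], {0: "A", 1: "A"})
        cell = out[("A", "A")][(2.0, 4.0)]
        assert cell == {"count": 1.0, "total_cm": 3.0}

    def test_left_closed_boundaries(self):
        out = ibd_bin_stats([_seg(0, 1, 2.0), _seg(0, 1, 4.0)], {0: "A", 1: "B"})
        cell = out[("A", "B")]
        assert cell[(2.0, 4.0)]["count"] == 1 and cell[(4.0, 8.0)]["count"] == 1

    def test_totals_conserved(self, rng):
        lengths = rng.uniform(2.0, 20.0, 50)
        segs = [_seg(0, 1, l) for l in lengths]
        out = ibd_bin_stats(segs, {0: "A", 1: "B"})
        total = sum(c["total_cm"] for c in out[("A", "B")].values())
        assert total == pytest.approx(lengths.sum())


class TestSummaryVector:
    def test_length_names_and_determinism(self, small_panel, small_genotypes):
        labels = small_panel.individual_labels
        sv = compute_summary_vector(
            small_genotypes, small_panel.positions, small_panel.genetic_pos_cm, labels
        )
        assert len(sv) == 46
        assert sv.names == registry_names()
        assert len(set(sv.names)) == 46
        sv2 = compute_summary_vector(
            small_genotypes, small_panel.positions, small_panel.genetic_pos_cm, labels
        )
        assert np.array_equal(sv.values, sv2.values)

    def test_individual_order_within_population_irrelevant(self, small_panel, small_genotypes):
        labels = small_panel.individual_labels
        sv = compute_summary_vector(
            small_genotypes, small_panel.positions, small_panel.genetic_pos_cm, labels
        )
        rng = np.random.default_rng(3)
        order = np.concatenate(
            [rng.permutation(np.where(labels == "CAB")[0]),
             rng.permutation(np.where(labels == "MOZ")[0])]
        )
        sv_perm = compute_summary_vector(
            small_genotypes[order], small_panel.positions, small_panel.genetic_pos_cm,
            labels[order],
        )
        assert np.allclose(sv.values, sv_perm.values)

    def test_degenerate_panel_nan_policy(self, caplog):
        g = np.zeros((8, 5), dtype=np.int8)  # monomorphic in both pops
        labels = np.array(["CAB"] * 4 + ["MOZ"] * 4)
        pos = np.arange(5) * 1000.0
        cm = pos / 1e6
        import logging

        with caplog.at_level(logging.WARNING):
            sv = compute_summary_vector(g, pos, cm, labels)
        assert np.all(np.isfinite(sv.values))
        assert sv.as_dict()["fst"] == 0.0
        assert "non-finite" in caplog.text

    def test_requires_two_populations(self, small_genotypes, small_panel):
        with pytest.raises(StatsInputError):
            compute_summary_vector(
                small_genotypes, small_panel.positions, small_panel.genetic_pos_cm,
                np.array(["CAB"] * small_genotypes.shape[0]),
            )


def test_segments_to_dataframe_bed_convention():
    from splitabc.sumstats import ROHSegment, segments_to_dataframe

    ibd = _seg(0, 1, 3.0)
    roh = ROHSegment(2, 1000.0, 5000.0, 60)
    df = segments_to_dataframe([ibd, roh])
    assert list(df.columns[:4]) == ["id1", "id2", "start_bp", "end_bp"]
    # half-open: end is one past the last covered base
    assert df.loc[1, "end_bp"] == 5001
    assert df.loc[1, "id1"] == df.loc[1, "id2"] == 2
    assert df.loc[0, "length_cm"] == 3.0
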