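import numpy as np
import pytest

from selscreen.branchsite import (
    BranchSiteModel,
    BranchSiteParams,
    EmptyAlignmentError,
    ScreenThresholds,
    bh_fdr,
    fit_gene,
    gene_passes,
    lrt_pvalue,
    strip_gap_columns,
)
from selscreen.codon import equal_frequencies
from selscreen.io import CodonAlignment, LabeledTree

from _oracles import brute_force_loglik


class TestStripGapColumns:
    def test_gap_free_alignment_unchanged_with_identity_map(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGAAACCC"] * 3)
        clean, cmap = strip_gap_columns(aln)
        assert clean.sequences == aln.sequences
        assert cmap == [1, 2, 3]

    def test_one_gapped_codon_removes_that_column_for_all(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAACCC", "ATG---CCC"])
        clean, cmap = strip_gap_columns(aln)
        assert clean.sequences == ["ATGCCC", "ATGCCC"]
        assert cmap == [1, 3]

    def test_ambiguous_and_stop_codons_removed(self):
        aln = CodonAlignment(["a", "b"], ["ATGAANTGACCC", "ATGAAATGACCC"])
        clean, cmap = strip_gap_columns(aln)
        assert cmap == [1, 4]  # 'AAN' column and 'TGA' column dropped

    def test_empty_after_cleaning_raises(self):
        aln = CodonAlignment(["a", "b"], ["---", "ATG"])
        with pytest.raises(EmptyAlignmentError):
            strip_gap_columns(aln)


class TestLikelihoodOracle:
    """Pruning likelihood vs explicit ancestral-state enumeration."""

    @pytest.mark.parametrize(
        "newick,taxa,seqs",
        [
            ("(A#1:0.2,B:0.4,C:0.15);", ["A", "B", "C"], ["ATGAAACCC", "ATGAAGCCA", "TTGAAACCC"]),
            ("((A#1:0.1,B:0.3):0.2,C:0.25,D:0.15);", ["A", "B", "C", "D"],
             ["ATGTTTACGCCCAAA", "ATGTTCACGCCAAAA", "ATGTTTACGCCCAAG", "CTGTTTAGGCCCAAA"]),
        ],
    )
    @pytest.mark.parametrize("params", [
        BranchSiteParams(1.7, 0.3, 3.5, 0.55, 0.3),
        BranchSiteParams(3.0, 0.05, 1.0, 0.8, 0.1),
        BranchSiteParams(2.0, 0.5, 8.0, 0.4, 0.4, tree_scale=1.5),
    ])
    def test_matches_brute_force(self, newick, taxa, seqs, params):
        aln = CodonAlignment(taxa, seqs)
        tree = LabeledTree.from_newick(newick)
        pi = equal_frequencies()
        mine = BranchSiteModel(aln, tree, codon_freq="equal").log_likelihood(params)
        brute = brute_force_loglik(aln, tree, params, pi)
        assert mine == pytest.approx(brute, abs=1e-8)

    def test_zero_length_tree_reduces_to_log_frequencies(self):
        aln = CodonAlignment(["A", "B", "C"], ["ATGAAA"] * 3)
        tree = LabeledTree.from_newick("(A#1:0.0,B:0.0,C:0.0);")
        params = BranchSiteParams(2.0, 0.2, 3.0, 0.6, 0.3)
        lnl = BranchSiteModel(aln, tree, codon_freq="equal").log_likelihood(params)
        assert lnl == pytest.approx(2 * np.log(1 / 61), abs=1e-10)

    def test_nesting_alt_with_omega2_one_equals_null(self, null_alignment, primate_tree):
        aln, _ = null_alignment
        model = BranchSiteModel(aln, primate_tree)
        p_alt = BranchSiteParams(2.0, 0.2, 1.0, 0.6, 0.3)
        p_null = BranchSiteParams(2.0, 0.2, 1.0, 0.6, 0.3)
        assert model.log_likelihood(p_alt) == pytest.approx(model.log_likelihood(p_null), abs=1e-12)

    def test_likelihood_invariant_to_gapped_column_insertion(self, primate_tree):
        from selscreen.simulate import SimulationConfig, simulate_alignment

        cfg = SimulationConfig(
            tree_spec="(((hum#1:0.06,chi:0.06):0.04,rhe:0.1):0.08,(dog:0.15,hor:0.15):0.05,rab:0.2);",
            foreground_branch="hum", n_codons=40, seed=77,
        )
        aln, _ = simulate_alignment(cfg)
        withgap = CodonAlignment(
            aln.taxa,
            [s[:30] + ("---" if i == 0 else "AAA") + s[30:] for i, s in enumerate(aln.sequences)],
        )
        clean, cmap = strip_gap_columns(withgap)
        assert clean.sequences == aln.sequences  # the inserted column is stripped
        assert cmap == [c + 1 if c >= 11 else c for c in range(1, 41)]
        params = BranchSiteParams(2.0, 0.2, 2.5, 0.6, 0.3)
        lnl_a = BranchSiteModel(aln, primate_tree, codon_freq="equal").log_likelihood(params)
        lnl_b = BranchSiteModel(clean, primate_tree, codon_freq="equal").log_likelihood(params)
        assert lnl_a == pytest.approx(lnl_b, abs=1e-9)


class TestLrtAndFdr:
    def test_zero_difference_gives_p_one(self):
        assert lrt_pvalue(-100.0, -100.0) == (0.0, 1.0)

    def test_chi2_reference_points(self):
        """Known chi-square(1) tail values at the 1% and 5% criticals."""
        _, p1 = lrt_pvalue(0.0, -6.635 / 2)
        _, p5 = lrt_pvalue(0.0, -3.841 / 2)
        assert p1 == pytest.approx(0.0100, abs=5e-4)
        assert p5 == pytest.approx(0.0500, abs=5e-4)

    def test_small_negative_clamped_large_negative_raises(self):
        stat, p = lrt_pvalue(-10.0 - 1e-9, -10.0)
        assert stat == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            lrt_pvalue(-11.0, -10.0)

    def test_bh_fdr_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.04])
        assert q == pytest.approx([0.004, 0.02, 0.0267, 0.04], abs=1e-4)

    def test_bh_fdr_edge_cases(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert list(bh_fdr([])) == []
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    def test_bh_fdr_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestGenePassRule:
    def test_conjunction_rule(self):
        th = ScreenThresholds()
        assert not gene_passes(0.009, 0.06, th)  # q fails
        assert gene_passes(0.009, 0.04, th)
        assert not gene_passes(0.02, 0.04, th)  # p fails
        assert not gene_passes(0.009, None, th)

    def test_boundaries(self):
        th = ScreenThresholds()
        assert gene_passes(0.01, 0.049, th)  # p <= is inclusive
        assert not gene_passes(0.01, 0.05, th)  # q < is strict


class TestFitGene:
    def test_null_data_yield_small_statistic(self, null_alignment, primate_tree):
        aln, _ = null_alignment
        f = fit_gene(aln, primate_tree, seed=0)
        assert f.converged
        assert f.lrt_stat >= -1e-6
        assert f.p_value > 0.01

    def test_strong_selection_detected_and_omega2_recovered(self, selected_alignment, long_fg_tree):
        aln, _ = selected_alignment
        f = fit_gene(aln, long_fg_tree, seed=2)
        assert f.p_value < 1e-4
        assert f.params_alt.omega2 > 2.0
        assert f.lnl_alt >= f.lnl_null - 1e-6

    def test_refit_with_different_seed_agrees(self, null_alignment, primate_tree):
        aln, _ = null_alignment
        f1 = fit_gene(aln, primate_tree, seed=0)
        f2 = fit_gene(aln, primate_tree, seed=5)
        assert f1.lnl_null == pytest.approx(f2.lnl_null, abs=1e-4)
        assert f1.lnl_alt == pytest.approx(f2.lnl_alt, abs=1e-4)
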