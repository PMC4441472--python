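import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selscreen.branchsite import PositiveSiteRecord
from selscreen.io import CodonAlignment, ProteinAlignment
from selscreen.simulate import CorruptionSpec, SimulationConfig, corrupt_alignment, simulate_alignment
from selscreen.sp_filter import SPConfig, SpeciesRetention, extract_window, filter_sites, pairwise_penalty, score_site

from _oracles import naive_sp_score
from conftest import PRIMATE_TREE


def _site(taxon="h", column=16, gene="g"):
    return PositiveSiteRecord(gene=gene, foreground=taxon, column=column, residue="K", posterior=0.99)


def _uniform(seq_count=3, length=40, char="K", taxa=None):
    taxa = taxa or [f"s{i}" for i in range(seq_count)]
    return ProteinAlignment(taxa, [char * length] * seq_count)


class TestExtractWindow:
    def test_interior_site_full_windows(self):
        aln = _uniform(length=40)
        up, down, n_up, n_down = extract_window(aln, "s0", 20)
        assert (n_up, n_down) == (15, 15)
        assert up == list(range(5, 20)) and down == list(range(21, 36))

    def test_near_start_gives_partial_upstream(self):
        """Site at the focal sequence's 5th residue: n = 4, S = 15/4."""
        aln = _uniform(length=40)
        up, down, n_up, n_down = extract_window(aln, "s0", 5)
        assert n_up == 4
        assert 15 / n_up == pytest.approx(3.75)

    def test_first_residue_has_empty_upstream(self):
        aln = _uniform(length=40)
        up, down, n_up, _ = extract_window(aln, "s0", 1)
        assert up == [] and n_up == 0

    def test_focal_gap_columns_are_included_in_window(self):
        aln = ProteinAlignment(["f", "o"], ["KK--KKKKKKKKKKKKKKKK", "KKKKKKKKKKKKKKKKKKKK"])
        up, _, n_up, _ = extract_window(aln, "f", 6, window=3)
        assert up == [1, 2, 3, 4, 5]  # three residues + the two focal-gap columns between them
        assert n_up == 3

    def test_gapped_focal_site_is_a_contract_violation(self):
        aln = ProteinAlignment(["f", "o"], ["K-K", "KKK"])
        with pytest.raises(ValueError):
            extract_window(aln, "f", 2)


class TestPairwisePenalty:
    def test_identical_windows_score_zero(self):
        assert pairwise_penalty("KLMNP", "KLMNP", 1.0) == 0.0

    def test_hand_oracle_mismatches_and_gaps(self):
        """3 mismatches and 2 one-sided gaps at S=1: -3 - 4 = -7."""
        a = "KKKKKKKKKKKKKKK"
        b = "KKKKKKKKKKCCC--"
        assert pairwise_penalty(a, b, 1.0) == -7.0

    def test_all_one_sided_gaps_full_window(self):
        assert pairwise_penalty("K" * 15, "-" * 15, 1.0) == -30.0

    def test_gap_gap_columns_score_zero(self):
        assert pairwise_penalty("K--K", "K--K", 2.0) == 0.0

    def test_scales_with_s(self):
        assert pairwise_penalty("KL", "KM", 3.75) == -3.75
        assert pairwise_penalty("K-", "KM", 3.75) == -7.5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pairwise_penalty("KK", "K", 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 14), st.sampled_from("ACDEF-"))
    def test_perturbing_a_column_never_raises_the_score(self, pos, char):
        """Score monotonicity: a mismatch or gap never helps."""
        base = "K" * 15
        perturbed = base[:pos] + char + base[pos + 1 :]
        assert pairwise_penalty(base, perturbed, 1.3) <= pairwise_penalty(base, base, 1.3)


class TestScoreSite:
    def test_perfectly_conserved_windows_pass_with_zero_scores(self):
        aln = _uniform(seq_count=4, taxa=["h", "a", "b", "c"])
        res = score_site(aln, _site(column=20))
        assert res.general_score == 0.0 and res.individual_score == 0.0
        assert res.passed and res.s_up == 1.0 and res.s_down == 1.0

    def test_scores_are_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            taxa = ["h", "a", "b"]
            seqs = ["".join(rng.choice(list("KLM-"), 31)) for _ in taxa]
            seqs = [s[:15] + "K" + s[16:] for s in seqs]
            res = score_site(ProteinAlignment(taxa, seqs), _site(column=16))
            assert res.general_score <= 1e-12 and res.individual_score <= 1e-12

    def test_threshold_is_strict(self):
        aln = ProteinAlignment(["h", "o"], ["K" * 31, "L" * 31])
        res = score_site(aln, _site(column=16))
        # every non-focal column mismatches: pair total -30, general -15, individual -30
        assert res.general_score == pytest.approx(-15.0)
        assert res.individual_score == pytest.approx(-30.0)
        exact = SPConfig(general_threshold=-15.0, individual_threshold=-30.0)
        assert not score_site(aln, _site(column=16), exact).passed  # equality fails
        looser = SPConfig(general_threshold=-15.0 - 1e-9, individual_threshold=-30.0 - 1e-9)
        assert score_site(aln, _site(column=16), looser).passed

    def test_codon_alignment_is_auto_translated(self):
        aln = CodonAlignment(["h", "a", "b"], ["AAA" * 31] * 3)
        res = score_site(aln, _site(column=16))
        assert res.passed and res.general_score == 0.0

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(30):
            n_seq = int(rng.integers(2, 6))
            length = int(rng.integers(10, 60))
            taxa = [f"s{i}" for i in range(n_seq)]
            seqs = ["".join(rng.choice(alphabet, length)) for _ in range(n_seq)]
            focal_positions = [i for i, ch in enumerate(seqs[0]) if ch != "-"]
            if not focal_positions:
                continue
            col = int(rng.choice(focal_positions)) + 1
            aln = ProteinAlignment(taxa, seqs)
            res = score_site(aln, _site(taxon="s0", column=col))
            general, individual = naive_sp_score(aln, "s0", col)
            assert res.general_score == pytest.approx(general, abs=1e-9)
            assert res.individual_score == pytest.approx(individual, abs=1e-9)

    def test_fewer_than_two_sequences_raises(self):
        with pytest.raises(ValueError):
            score_site(ProteinAlignment(["h"], ["K" * 31]), _site(column=16))


class TestShuffleDiscrimination:
    def test_corrupted_window_scores_below_clean(self, primate_tree):
        cfg = SimulationConfig(tree_spec=PRIMATE_TREE, foreground_branch="hum", n_codons=120, seed=9)
        aln, _ = simulate_alignment(cfg)
        spec = CorruptionSpec(misalignment_windows=[("hum", 40, 31, "shuffle")], seed=3)
        bad, _ = corrupt_alignment(aln, spec)
        site = _site(taxon="hum", column=55)
        clean_score = score_site(aln.to_protein(), site)
        bad_score = score_site(bad.to_protein(), site)
        assert bad_score.general_score < clean_score.general_score


class TestFilterSites:
    def test_fpr_arithmetic_from_counts(self):
        assert SpeciesRetention(total=26, retained=16).fpr == pytest.approx(38.46, abs=0.005)
        assert SpeciesRetention(total=92, retained=54).fpr == pytest.approx(41.30, abs=0.005)
        assert SpeciesRetention(total=7, retained=7).fpr == 0.0

    def test_summary_counts_and_orphans(self):
        aln = _uniform(seq_count=3, taxa=["h", "a", "b"])
        sites = [_site(column=16), _site(column=20), _site(column=5, gene="missing")]
        results, summary, orphans = filter_sites(sites, {"g": aln})
        assert len(results) == 2
        assert summary["h"].total == 2 and summary["h"].retained == 2
        assert [o.gene for o in orphans] == ["missing"]
        assert all(s.sp_pass for s in sites if s.gene == "g")
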