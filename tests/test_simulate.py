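import numpy as np
import pytest
from scipy.stats import chisquare

from selscreen.codon import CODON_INDEX, N_CODONS, equal_frequencies
from selscreen.simulate import (
    CorruptionSpec,
    SimulationConfig,
    corrupt_alignment,
    emit_cdnas,
    emit_proteomes,
    simulate_alignment,
)

STAR3 = "(A#1:0.1,B:0.1,C:0.1);"


def _config(**kw):
    defaults = dict(
        tree_spec=STAR3, foreground_branch="A", n_codons=50, seed=0
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateAlignment:
    def test_zero_branch_lengths_give_identical_sequences(self):
        aln, _ = simulate_alignment(_config(tree_spec="(A#1:0.0,B:0.0,C:0.0);"))
        assert len(set(aln.sequences)) == 1

    def test_same_seed_is_byte_identical(self):
        a1, _ = simulate_alignment(_config(seed=9))
        a2, _ = simulate_alignment(_config(seed=9))
        assert a1.to_fasta() == a2.to_fasta()
        a3, _ = simulate_alignment(_config(seed=10))
        assert a1.to_fasta() != a3.to_fasta()

    def test_output_is_gap_free_in_frame_and_stop_free(self):
        aln, truth = simulate_alignment(_config(n_codons=200, omega2=6.0, seed=3))
        assert aln.n_codons == 200
        for seq in aln.sequences:
            assert "-" not in seq
            for i in range(0, len(seq), 3):
                assert seq[i : i + 3] in CODON_INDEX
        assert len(truth.site_classes) == 200

    def test_class_frequencies_match_proportions_within_3_se(self):
        """With p0 + p1 = 1 the site classes are a plain binomial draw."""
        p0, p1 = 0.6, 0.4
        cfg = _config(n_codons=5000, site_class_proportions=(p0, p1), omega2=1.0, seed=11)
        _, truth = simulate_alignment(cfg)
        counts = {c: truth.site_classes.count(c) for c in ("0", "1", "2a", "2b")}
        assert counts["2a"] == counts["2b"] == 0
        se = np.sqrt(p0 * (1 - p0) * 5000)
        assert abs(counts["0"] - p0 * 5000) < 3 * se

    def test_model_a_split_of_class2_mass(self):
        props = _config(site_class_proportions=(0.5, 0.3)).class_proportions()
        assert props == pytest.approx([0.5, 0.3, 0.2 * 0.5 / 0.8, 0.2 * 0.3 / 0.8])
        assert props.sum() == pytest.approx(1.0)

    def test_codon_frequencies_converge_to_stationary(self):
        """Long total tree length: observed codons ~ equilibrium (chi-square GOF)."""
        tree = "(A#1:2.0,B:2.0,C:2.0,D:2.0);"
        cfg = _config(tree_spec=tree, n_codons=10000, omega2=1.0, seed=5)
        aln, _ = simulate_alignment(cfg)
        counts = np.zeros(N_CODONS)
        for seq in aln.sequences:
            for i in range(0, len(seq), 3):
                counts[CODON_INDEX[seq[i : i + 3]]] += 1
        _, p = chisquare(counts, counts.sum() * equal_frequencies())
        assert p > 0.01

    def test_foreground_label_absent_raises(self):
        with pytest.raises(ValueError):
            simulate_alignment(_config(foreground_branch="ZZZ"))

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_alignment(_config(omega0=1.5))
        with pytest.raises(ValueError):
            simulate_alignment(_config(site_class_proportions=(0.8, 0.4)))
        with pytest.raises(ValueError):
            simulate_alignment(_config(n_codons=0))


@pytest.fixture(scope="module")
def base():
    aln, _ = simulate_alignment(_config(n_codons=60, seed=21))
    return aln


class TestCorruptAlignment:
    def test_empty_spec_is_identity(self, base):
        out, truth = corrupt_alignment(base, CorruptionSpec())
        assert out.sequences == base.sequences
        assert truth.corrupted_columns == {}

    def test_gap_burst_inserts_exactly_w_gap_codons(self, base):
        spec = CorruptionSpec(misalignment_windows=[("B", 10, 5, "gap_burst")])
        out, truth = corrupt_alignment(base, spec)
        b = out.sequence_of("B")
        assert b[27:42] == "-" * 15  # codons 10..14
        assert truth.corrupted_columns["B"] == set(range(10, 15))

    def test_corruption_is_local(self, base):
        spec = CorruptionSpec(misalignment_windows=[("B", 10, 5, "shuffle")], seed=2)
        out, _ = corrupt_alignment(base, spec)
        for taxon in base.taxa:
            before, after = base.sequence_of(taxon), out.sequence_of(taxon)
            assert before[: 9 * 3] == after[: 9 * 3]
            assert before[14 * 3 :] == after[14 * 3 :]
            if taxon != "B":
                assert before == after

    def test_shuffle_permutes_codons_within_window(self, base):
        spec = CorruptionSpec(misalignment_windows=[("B", 10, 5, "shuffle")], seed=2)
        out, _ = corrupt_alignment(base, spec)
        win_before = [base.sequence_of("B")[i * 3 : i * 3 + 3] for i in range(9, 14)]
        win_after = [out.sequence_of("B")[i * 3 : i * 3 + 3] for i in range(9, 14)]
        assert sorted(win_before) == sorted(win_after)
        assert win_before != win_after

    def test_substitution_errors_recorded_and_stop_free(self, base):
        spec = CorruptionSpec(substitution_error_rate=0.2, error_taxon="C", seed=8)
        out, truth = corrupt_alignment(base, spec)
        assert truth.error_positions["C"]
        for i in range(0, len(out.sequence_of("C")), 3):
            assert out.sequence_of("C")[i : i + 3] in CODON_INDEX

    def test_frameshift_marks_downstream_and_preserves_length(self, base):
        spec = CorruptionSpec(frameshift=("A", 20, -1), seed=1)
        out, truth = corrupt_alignment(base, spec)
        assert len(out.sequence_of("A")) == len(base.sequence_of("A"))
        assert truth.corrupted_columns["A"] == set(range(20, 61))

    def test_window_outside_bounds_raises(self, base):
        with pytest.raises(ValueError):
            corrupt_alignment(base, CorruptionSpec(misalignment_windows=[("B", 58, 10, "gap_burst")]))


class TestEmitCdnas:
    def test_error_free_fragments_are_exact_substrings(self):
        aln, truth = simulate_alignment(_config(n_codons=80, seed=30))
        frags = emit_cdnas(aln, truth, n_fragments=4, fragment_span=(5, 20), seed=1)
        for f in frags:
            cds = aln.sequence_of(f.taxon)
            assert f.sequence == cds[(f.start_codon - 1) * 3 : f.end_codon * 3]
            assert f.sequence in cds

    def test_seeded_run_reproducible(self):
        aln, truth = simulate_alignment(_config(n_codons=80, seed=30))
        f1 = emit_cdnas(aln, truth, 3, (5, 20), seed=4)
        f2 = emit_cdnas(aln, truth, 3, (5, 20), seed=4)
        assert [(f.start_codon, f.end_codon, f.sequence) for f in f1] == [
            (f.start_codon, f.end_codon, f.sequence) for f in f2
        ]

    def test_span_exceeding_cds_raises(self):
        aln, truth = simulate_alignment(_config(n_codons=10, seed=30))
        with pytest.raises(ValueError):
            emit_cdnas(aln, truth, 1, (5, 100), seed=0)


class TestEmitProteomes:
    def test_truth_records_pairings_and_identities(self):
        proteomes, truth = emit_proteomes(3, 5, identity_decay=0.05, seed=2)
        assert set(proteomes) == {"sp1", "sp2", "sp3"}
        assert len(truth.pairs) == 10  # 5 genes x 2 non-reference species
        assert all(60 <= v <= 100 for v in truth.identities.values())

    def test_heavy_decay_flags_sub_threshold_pairs(self):
        _, truth = emit_proteomes(2, 6, identity_decay=0.6, seed=3)
        # measured identity drives the flag
        for key, ident in truth.identities.items():
            assert (key in truth.sub_threshold) == (ident < 60.0)
        assert truth.sub_threshold  # at 60% decay some pairs must fall below

    def test_seeded_run_reproducible(self):
        p1, _ = emit_proteomes(2, 4, seed=9)
        p2, _ = emit_proteomes(2, 4, seed=9)
        assert [(r.gene_id, r.sequence) for r in p1["sp2"]] == [(r.gene_id, r.sequence) for r in p2["sp2"]]
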