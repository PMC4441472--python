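"""Validate candidate site codons against independent cDNA fragments.

Sequencing errors are injected into the 'genomic' human sequence; cDNA
fragments are cut from the error-free original.  A site is valid when at
least one covering cDNA matches its codon exactly, invalid when covered
only by disagreeing cDNAs, and unmapped when no cDNA covers it.
"""

from selscreen import (
    CorruptionSpec,
    SimulationConfig,
    corrupt_alignment,
    emit_cdnas,
    simulate_alignment,
    validate_site,
)

TREE = "(((hum#1:0.06,chi:0.06):0.04,rhe:0.1):0.08,(dog:0.15,hor:0.15):0.05,rab:0.2);"

alignment, _ = simulate_alignment(
    SimulationConfig(tree_spec=TREE, foreground_branch="hum", n_codons=80, seed=11)
)
corrupted, truth = corrupt_alignment(
    alignment, CorruptionSpec(substitution_error_rate=0.05, error_taxon="hum", seed=4)
)
fragments = emit_cdnas(
    corrupted, truth, n_fragments=8, fragment_span=(20, 60), with_errors=False, seed=2, taxa=["hum"]
)
cdnas = {f.fragment_id: f.sequence for f in fragments}
cds = corrupted.sequence_of("hum")
error_codons = sorted(truth.corrupted_columns["hum"])
print(f"injected errors in codons: {error_codons}")

verdicts = {"valid": 0, "invalid": 0, "unmapped": 0}
wrong_calls = 0
for codon in range(1, 81):
    v = validate_site(None, cds, cdnas, codon_index=codon)
    verdicts[v.verdict] += 1
    if v.verdict == "invalid" and codon not in error_codons:
        wrong_calls += 1
print(f"verdicts over all 80 codons: {verdicts}")
print(f"error-free codons wrongly invalidated: {wrong_calls}")
# Every 'invalid' verdict points at an injected error that at least one
# cDNA covers; unmapped codons simply lack transcript evidence.
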