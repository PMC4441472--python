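"""SP penalty scoring of the +/-15-residue windows around candidate sites.

A clean simulated alignment is compared with a copy whose human row was
shuffled over a 31-codon window (a misalignment artifact).  The filter
keeps the clean-context site and rejects the corrupted-context one.
"""

from selscreen import CorruptionSpec, PositiveSiteRecord, SimulationConfig, corrupt_alignment, score_site, simulate_alignment

TREE = "(((hum#1:0.012,chi:0.012):0.006,(rhe:0.025,mac:0.025):0.012):0.01,mar:0.05,gor:0.02);"

config = SimulationConfig(tree_spec=TREE, foreground_branch="hum", n_codons=200, seed=7003)
alignment, _ = simulate_alignment(config)
corrupted, _ = corrupt_alignment(
    alignment, CorruptionSpec(misalignment_windows=[("hum", 80, 31, "shuffle")], seed=3)
)

inside = PositiveSiteRecord(gene="demo", foreground="hum", column=95, residue="?", posterior=0.99)
clean = PositiveSiteRecord(gene="demo", foreground="hum", column=40, residue="?", posterior=0.99)

for label, aln, site in [("clean context", alignment, clean), ("shuffled window", corrupted, inside)]:
    r = score_site(aln.to_protein(), site)
    print(f"{label:16s} column {site.column:3d}: general {r.general_score:8.2f}  "
          f"individual {r.individual_score:8.2f}  pass={r.passed}")
# Per column: match 0, mismatch -S, gap -2S with S = 15/n (n = focal
# residues in the stream).  A site passes only if the pair-averaged
# general score stays above -50 AND the focal-vs-others individual score
# stays above -15, both strictly.
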