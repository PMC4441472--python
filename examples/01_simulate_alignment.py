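"""Simulate a codon alignment under the branch-site Model A mixture.

Sites fall into four classes: purifying (omega0 < 1) or neutral
(omega = 1) everywhere, plus two classes that switch to omega2 > 1 on
the designated foreground branch (here: the human tip).
"""

from collections import Counter

from selscreen import SimulationConfig, simulate_alignment

TREE = "(((hum#1:0.06,chi:0.06):0.04,rhe:0.1):0.08,(dog:0.15,hor:0.15):0.05,rab:0.2);"

config = SimulationConfig(
    tree_spec=TREE,
    foreground_branch="hum",
    n_codons=400,
    site_class_proportions=(0.7, 0.2),  # p0, p1; the rest is split into 2a/2b
    omega0=0.1,
    omega2=4.0,
    kappa=2.0,
    seed=1,
)

alignment, truth = simulate_alignment(config)
counts = Counter(truth.site_classes)

print(f"alignment: {alignment.n_taxa} taxa x {alignment.n_codons} codons (gap-free, in-frame)")
print(f"site classes drawn: {dict(sorted(counts.items()))}")
print(f"true foreground-selected columns (classes 2a/2b): {len(truth.positive_site_columns())}")
print()
print("First 10 codons per taxon:")
for taxon in alignment.taxa:
    print(f"  {taxon:4s} {alignment.sequence_of(taxon)[:30]}")
# The class counts follow the Model A proportions: with p0=0.7, p1=0.2 the
# remaining 10% of sites is split 2a:2b in ratio p0:p1.
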