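# selscreen

A genome-scale screen for **episodic positive selection** on designated
lineages, with the two false-positive filters such screens need in
practice: an alignment-quality filter around each candidate site and
validation of candidate codons against independent cDNA evidence.

It is written for molecular evolution researchers who want a tested,
scriptable pipeline: orthologs → branch-site test → site filtering →
cDNA validation → summary statistics, plus a simulator that generates
every input the pipeline consumes (so the whole chain is testable
without any genome download).

## The model and the statistics

**Branch-site test (Model A).** Codon sites of an in-frame alignment are
a mixture of four classes: class 0 evolves at 0 < ω₀ < 1 on every
branch, class 1 at ω = 1, and classes 2a/2b switch to ω₂ ≥ 1 on a single
designated *foreground* branch while keeping ω₀ / 1 on the background.
Class weights are (p₀, p₁, p₂a, p₂b) with the class-2 mass split in
ratio p₀ : p₁.  The substitution process is the standard 61-state codon
model (single-nucleotide changes only, transition/transversion ratio κ,
target-codon frequencies π from F3x4 by default).  The null model fixes
ω₂ = 1; twice the log-likelihood difference, 2Δℓ, is referred to χ²₁.
Genes pass at p ≤ 0.01 **and** Benjamini–Hochberg FDR < 0.05 (FDR
computed per foreground species across its gene set).  Candidate sites
are called by Bayes Empirical Bayes: the posterior of classes 2a+2b is
averaged over a parameter grid weighted by the full-data likelihood;
sites with posterior > 0.95 are reported.

**SP penalty filter.** Around each candidate site, the 15 focal residues
upstream and downstream are extracted (with any intervening gap
columns).  Each column scores 0 for a match, −S for a mismatch, −2S for
a residue opposite a gap, where S = 15/n and n is the number of focal
residues actually available in that stream (edge sites get larger
penalties per column).  A site is kept only if the *general* score (sum
over all unordered sequence pairs, divided by the number of sequences N)
exceeds −50 **and** the *individual* score (focal sequence against every
other, unaveraged) exceeds −15, both strictly.

**cDNA validation.** Each cDNA is locally aligned to the gene's CDS
(both orientations).  A site is *valid* if at least one covering cDNA
matches its codon base-for-base with no gaps, *invalid* if covered only
by disagreeing cDNAs, and *unmapped* otherwise (excluded from error-rate
statistics).

**Orthologs.** 1:1 orthologs are reciprocal best hits between proteomes
(affine-gap local alignment, BLOSUM62, gap open 11 / extend 1), keeping
one record per gene (longest transcript) and discarding hits under 60%
identity before ranking.

## Worked example

`examples/` contains one short script per capability.  The end-to-end
demo (`python examples/06_full_screen.py`) simulates three genes — two
neutral, one with ω₂ = 8 on a long human foreground branch — and screens
four species:

```
species   p<=0.01  FDR<0.05  SP genes  BEB sites  SP sites   FPR%
hum             1         1         1         10         6  40.00
chi             0         0         0          0         0   0.00
rhe             0         0         0          0         0   0.00
mac             0         0         0          0         0   0.00

mean FDR-passing genes per group: {'group_a': 0.5, 'group_b': 0.0}
overall SP site retention: 60.00%
```

Only the species actually carrying the selected gene detects it; of its
10 BEB sites, the SP filter discards 4 whose windows contain too many
foreground-specific changes (a 40% per-species misalignment FPR — the
same order as published screens report).  The single-gene demo
(`python examples/02_branch_site_test.py`) prints the fitted
log-likelihoods, the LRT and the ω₂ estimate next to the simulation
truth:

```
lnL alternative = -4795.537, lnL null = -4821.130
LRT statistic 2*dlnL = 51.19, chi-square(1) p = 8.4e-13
omega2 MLE = 8.18 (simulated at 8.0)

BEB sites with posterior > 0.95: 9 (9 are truly class 2a/2b; 63 truth sites in total)
```

## Command line

A thin CLI wraps the library for shell use:

```bash
selscreen simulate --tree '(((hum#1:0.06,chi:0.06):0.04,rhe:0.1):0.08,(dog:0.15,hor:0.15):0.05,rab:0.2);' \
    --n-codons 300 --omega2 4 --seed 1 --out gene1
selscreen branchsite --alignment gene1.fasta --tree tree.nwk --out fit.tsv
selscreen screen --design design.yaml --alignments genes/ --tree tree.nwk --out results/
```

Foreground branches use the `#1` Newick tag convention.  See
`docs/methods.md` for the modelling conventions, numerical choices and
known limitations.
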