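# Methods

## Substitution model and likelihood

The engine implements the four-class branch-site mixture over the 61
sense codons of the universal code (stop codons are excluded from the
state space entirely).  Rates follow the Goldman–Yang form: zero for
changes touching more than one nucleotide, otherwise proportional to the
target codon's equilibrium frequency, multiplied by κ for transitions
and by the class/branch-specific ω for nonsynonymous changes.  Codon
frequencies default to F3x4 (position-specific nucleotide frequencies
estimated from the cleaned alignment, floored at 1e−6 and renormalized);
an `equal` option exists for oracle tests.

**Time-scale convention.**  All site classes share one rate scale: the
unnormalized per-class matrices are divided by the background-mixture
expected flux, Σ_c w_c · rate(Q(ω_bg,c)), where w puts p₀+p₂a on ω₀ and
p₁+p₂b on 1.  Branch lengths therefore read as expected substitutions
per codon under the background mixture, and a foreground ω₂ > 1 class
genuinely evolves faster on the foreground branch rather than merely
changing its synonymous/nonsynonymous composition.  Normalizing each
class separately (the obvious alternative) removes most of the
detectable signal and is not what mainstream implementations do; the
simulator and the inference engine share this convention, and the
brute-force oracle in the test suite re-derives it independently.

Likelihoods are computed by Felsenstein pruning with site-pattern
compression.  Each ω needs one eigendecomposition of the symmetrized
rate matrix (the process is reversible), after which P(t) for every
branch is a batched reconstruction; per-evaluation caches are keyed by
parameter values, never by object identity.  Per-node rescaling against
underflow switches on above 14 taxa; below that, double precision is
ample.  Gap handling mimics a cleandata-style rule: any codon column
containing a gap, an ambiguous base or a stop codon (frameshifted tails)
in any taxon is removed before fitting, with a column map retained so
sites are reported in original 1-based codon coordinates.

## Fitting

Parameters are optimized in unconstrained space: log κ, logit ω₀ within
(1e−6, 1), a softmax for (p₀, p₁), logit-scaled ω₂ within [1, 999] under
the alternative.  Branch lengths are taken from the input tree up to one
global scale factor estimated under the null and held fixed for the
alternative, keeping both fits on a shared tree while bounding the
optimization dimension per gene; full per-branch re-estimation is
deliberately out of scope at desk scale.  L-BFGS-B runs from three
starting points (the default start plus seeded jitter), each with a
coarse tolerance, and the best is polished at ftol 1e−12 (≈1e−8 on lnL
for typical magnitudes).  The alternative model warm-starts from the
null MLE with ω₂ = 2.  Because the models are nested, a fitted
alternative below the null is replaced by the null solution; the LRT
statistic is clamped at zero and referred to χ²₁ (the test is known to
be conservative, since ω₂ = 1 lies on the boundary).  Genes whose
optimization fails are flagged unconverged and excluded downstream
without aborting a screen.  p-values are BH-adjusted per foreground
species; a gene passes at p ≤ 0.01 AND q < 0.05.

## Bayes Empirical Bayes site posteriors

With κ and the tree scale fixed at their alternative-model MLEs, the
class posterior of every site is averaged over a grid prior: d = 10
equispaced values for ω₀ in (0, 1) and for ω₂ in (1, 11], and the
triangular d×d grid for (p₀, p₁), uniform over valid points.  Grid
points are weighted by the full-alignment likelihood; each site's
probability of class 2a or 2b is the weighted average across the grid.
Sites exceeding posterior 0.95 in FDR-passing genes become candidate
positive sites.  Branch lengths do not rescale with the grid's mixture
weights — they stay at their fitted time scale.

## SP penalty filter

Windows are counted in focal-sequence residues, not raw columns: the
walk outward from the site collects columns until 15 focal residues per
stream are found or the focal sequence ends, and intervening columns
where the focal taxon is gapped stay in the window (otherwise gap
penalties could never fire).  The site column itself is excluded — it is
the hypothesis under test, not context (config flag to include it).  Per
column: match 0, mismatch −S, residue/gap −2S, with S = 15/n per stream;
gap/gap columns score 0 since a shared gap carries no pairwise evidence.
The general score sums over all unordered sequence pairs and divides by
the number of sequences N (the alternative focal-pairs reading is
selectable via `SPConfig.general_mode`); the individual score sums the
focal-vs-other pair penalties unaveraged (`individual_averaged` to
switch).  Thresholds −50 (general) and −15 (individual) are strict
inequalities.

A consequence worth knowing: each foreground-specific substitution in a
window costs the individual score roughly one mismatch per background
taxon, so the −15 threshold presumes largely conserved flanks.  At
primate-scale divergence clean windows pass comfortably and corrupted
windows fail decisively; at distant-mammal divergence even clean windows
can breach the threshold — which is the filter behaving as designed
(its published use reports 33–61% of candidate sites discarded), not a
defect of this implementation.  The discrimination tests therefore run
at primate-scale divergence.

## cDNA validation

Mapping is a local nucleotide alignment (match +2, mismatch −3, affine
gap open 5 / extend 2, both orientations, best score kept) with
acceptance floors of 40 score and 30 aligned bases standing in for a
search E-value cutoff.  The mapping records the cDNA base aligned to
every covered CDS position, so codon checks need no re-alignment.  A
site is valid with ≥1 covering cDNA whose three aligned bases match the
codon exactly and ungapped; invalid needs coverage and zero perfect
matches; unmapped sites are excluded from error-rate statistics and
reported separately.  Verdicts are monotone in evidence: adding cDNAs
can only move unmapped→valid/invalid or invalid→valid.  One caveat: a
mismatch at the extreme end of a fragment can be trimmed by the local
alignment, leaving the codon uncovered rather than invalid; coverage is
therefore always the aligner's, not the fragment's nominal extent.

## Ortholog calling

Longest transcript per gene (ties to the lexicographically first
transcript id), then reciprocal best hits under BLOSUM62 local alignment
with gap open 11 / extend 1.  Identity is matches over aligned columns
including internal gaps but excluding end gaps — the local-identity
convention — and hits under 60% are discarded before ranking, with a
raw-score floor of 50 standing in for an E-value cutoff.  Equal scores
break toward the lexicographically first gene id.  Near the 60%
boundary, local-alignment identity can sit slightly above the naive
positional identity of the generating process; the truth-table tests
allow a margin there.

## Synthetic data

The generator emulates exactly what the analysis assumes: site classes
drawn i.i.d. with the Model A proportions, codons evolved along the tree
with class-specific matrices (foreground switch included), all
randomness flowing from one integer seed through numpy's splittable
SeedSequence.  Corruption is three named operators mapping to the three
real-data failure classes — `gap_burst`, `shuffle`, `shift` windows for
misalignment; per-nucleotide substitution errors (stop codons avoided by
redraw) for sequencing error; frameshift indels with length ≢ 0 (mod 3)
for annotation error — plus truth tables recording classes, corrupted
columns and injected positions.  cDNA fragments are contiguous substrings
of the true or corrupted CDS with recorded codon coordinates; proteomes
descend from one ancestral gene set with per-residue decay and optional
diverged paralogs.

What it does **not** emulate: realistic indel processes, aligner
(PRANK-like) behavior, codon frequency biases of real genomes, rate
variation beyond the four classes, or clustered positive sites.  Passing
tests therefore demonstrate correctness of the machinery and calibration
under the model's own assumptions — not robustness to model violation on
real genomes.

## Problem sizes and calibration checks

The test suite runs, at fixed seeds: the brute-force likelihood oracle
on ≤4-taxon, ≤5-codon instances (agreement to 1e−8); type-I error from
200 null genes (6 taxa, 300 codons) checked against a 5% ceiling at
p ≤ 0.01; parameter recovery from 20 replicates at ω₂ = 4 and 1500
codons (median ω₂ estimate within [2, 8], BEB precision above twice the
chance rate); SP discrimination over 20 corrupted/clean fixture pairs
(≥80% / ≥90%); SP scoring against a naive re-implementation on 100
random fixtures (1e−9); cDNA soundness on truth tables; and RBH recovery
on paralog-free proteomes.  The acceptance script re-measures the same
properties at reduced replication (60 null genes, 8 recovery replicates)
— sizes chosen as a sensible desk-scale compromise — alongside the
reporting arithmetic on the shipped count tables.

## Known limitations

- Branch lengths are rescaled, not re-estimated per branch; genes whose
  true tree deviates strongly from the supplied topology/lengths lose
  power (the NJ fallback from Jukes–Cantor distances is a coarse stand-in
  for ML tree search).
- The χ²₁ reference is conservative at the ω₂ = 1 boundary; no mixture
  (½χ²₀ + ½χ²₁) option is provided because the screen's published rule
  uses plain χ²₁.
- BEB uses a fixed 10-point grid; very small class-2 masses can leave
  truly selected sites below the 0.95 bar (low recall, high precision).
- The SP individual threshold is divergence-sensitive (see above); users
  screening distant taxa should expect high candidate attrition.
- F3x4 can misstate codon frequencies under strong codon-usage bias; no
  empirical-frequency estimation from external genomes is attempted.
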