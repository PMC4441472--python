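"""Synthetic data with the statistical structure the screen assumes.

Codon alignments are evolved along a labeled tree under the branch-site
Model A mixture (four site classes; the foreground branch gets omega2 on
classes 2a/2b), then optionally corrupted by operators that mimic the
three failure classes real screens face: misalignment (gap bursts,
shuffled or shifted windows), sequencing error (random substitutions),
and annotation error (frameshifts).  cDNA fragments and small proteome
sets complete the fixtures for the validator and ortholog stages.

All randomness flows from a single integer seed through numpy's
splittable SeedSequence, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon import (
    CODON_INDEX,
    CODONS,
    N_CODONS,
    STOP_CODONS,
    TransitionKernel,
    equal_frequencies,
    mean_rate,
)
from .io import CodonAlignment, LabeledTree

SITE_CLASSES = ("0", "1", "2a", "2b")


@dataclass
class SimulationConfig:
    """Parameters of one branch-site Model A simulation.

    Branch lengths in ``tree_spec`` are expected substitutions per codon.
    ``site_class_proportions`` are (p0, p1); the remaining mass is split
    between classes 2a and 2b in ratio p0:p1, as the model defines.
    """

    tree_spec: str
    foreground_branch: str
    n_codons: int
    site_class_proportions: tuple[float, float] = (0.7, 0.2)
    omega0: float = 0.1
    omega2: float = 4.0
    kappa: float = 2.0
    codon_frequencies: str | np.ndarray = "equal"
    seed: int = 0

    def validate(self) -> None:
        p0, p1 = self.site_class_proportions
        if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-12:
            raise ValueError("p0, p1 must be non-negative with p0 + p1 <= 1")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")

    def frequencies(self) -> np.ndarray:
        if isinstance(self.codon_frequencies, str):
            if self.codon_frequencies != "equal":
                raise ValueError("codon_frequencies must be 'equal' or a 61-vector")
            return equal_frequencies()
        pi = np.asarray(self.codon_frequencies, dtype=float)
        if pi.shape != (N_CODONS,) or abs(pi.sum() - 1) > 1e-8 or (pi < 0).any():
            raise ValueError("codon frequencies must be a probability 61-vector")
        return pi

    def class_proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b) with the Model A split of the class-2 mass."""
        p0, p1 = self.site_class_proportions
        rest = max(0.0, 1.0 - p0 - p1)
        if p0 + p1 == 0:
            # degenerate: all mass in class 2, split evenly
            return np.array([0.0, 0.0, rest / 2, rest / 2])
        return np.array([p0, p1, rest * p0 / (p0 + p1), rest * p1 / (p0 + p1)])


# (background omega key, foreground omega key) per site class
_CLASS_OMEGAS = {
    "0": ("omega0", "omega0"),
    "1": ("one", "one"),
    "2a": ("omega0", "omega2"),
    "2b": ("one", "omega2"),
}


@dataclass
class CorruptionSpec:
    """Declarative description of injected data pathologies.

    misalignment_windows: (taxon, start_column, width, mode) with 1-based
    codon columns and mode in {gap_burst, shuffle, shift}.
    substitution_error_rate applies per nucleotide to ``error_taxon``.
    frameshift is (taxon, codon_position, indel_length) with an indel
    length not divisible by 3 (negative = deletion).
    """

    misalignment_windows: list[tuple[str, int, int, str]] = field(default_factory=list)
    substitution_error_rate: float = 0.0
    error_taxon: str | None = None
    frameshift: tuple[str, int, int] | None = None
    seed: int = 0

    def validate(self, aln: CodonAlignment) -> None:
        for taxon, start, width, mode in self.misalignment_windows:
            if taxon not in aln.taxa:
                raise ValueError(f"unknown taxon {taxon!r}")
            if mode not in ("gap_burst", "shuffle", "shift"):
                raise ValueError(f"unknown corruption mode {mode!r}")
            if start < 1 or width < 1 or start + width - 1 > aln.n_codons:
                raise ValueError("corruption window outside alignment bounds")
        if not (0 <= self.substitution_error_rate <= 1):
            raise ValueError("substitution_error_rate must lie in [0, 1]")
        if self.substitution_error_rate > 0 and self.error_taxon is None:
            raise ValueError("error_taxon required when substitution_error_rate > 0")
        if self.frameshift is not None:
            taxon, pos, k = self.frameshift
            if k % 3 == 0:
                raise ValueError("frameshift indel length must not be divisible by 3")
            if not (1 <= pos <= aln.n_codons):
                raise ValueError("frameshift position outside alignment")


@dataclass
class TruthTable:
    """Ground truth carried alongside simulated/corrupted data."""

    site_classes: list[str] = field(default_factory=list)
    corrupted_columns: dict[str, set[int]] = field(default_factory=dict)  # taxon -> 1-based codon columns
    error_positions: dict[str, list[int]] = field(default_factory=dict)  # taxon -> 0-based nt positions
    original: CodonAlignment | None = None

    def positive_site_columns(self) -> list[int]:
        """1-based codon columns truly under foreground positive selection."""
        return [i + 1 for i, c in enumerate(self.site_classes) if c in ("2a", "2b")]

    def to_tsv(self) -> str:
        lines = ["column\tsite_class\tcorrupted_in"]
        for i, cls in enumerate(self.site_classes, start=1):
            hit = ",".join(sorted(t for t, cols in self.corrupted_columns.items() if i in cols))
            lines.append(f"{i}\t{cls}\t{hit}")
        return "\n".join(lines) + "\n"


def _foreground_edges(tree: LabeledTree) -> set[int]:
    node = tree.foreground_node()
    return {id(node)}


def simulate_alignment(config: SimulationConfig) -> tuple[CodonAlignment, TruthTable]:
    """Evolve a gap-free codon alignment under branch-site Model A.

    Site classes are drawn i.i.d. with the Model A proportions; each site
    then evolves down the tree with its class's omega on background
    branches and, for classes 2a/2b, omega2 on the foreground branch.
    """
    config.validate()
    tree = LabeledTree.from_newick(config.tree_spec, foreground=config.foreground_branch)
    if len(tree.leaf_names()) < 3:
        raise ValueError("tree must have at least 3 leaves")

    pi = config.frequencies()
    props = config.class_proportions()
    # one shared time scale across site classes (codeml-style): branch
    # lengths are expected substitutions per codon under the background
    # mixture, so foreground omega2 classes genuinely evolve faster
    rho = (props[0] + props[2]) * mean_rate(config.kappa, config.omega0, pi) + (
        props[1] + props[3]
    ) * mean_rate(config.kappa, 1.0, pi)
    kernels = {
        "omega0": TransitionKernel(config.kappa, config.omega0, pi, normalize=False, rate_scale=rho),
        "one": TransitionKernel(config.kappa, 1.0, pi, normalize=False, rate_scale=rho),
        "omega2": TransitionKernel(config.kappa, config.omega2, pi, normalize=False, rate_scale=rho),
    }

    root_ss, class_ss, branch_ss = np.random.SeedSequence(config.seed).spawn(3)
    class_rng = np.random.default_rng(class_ss)
    classes = class_rng.choice(len(SITE_CLASSES), size=config.n_codons, p=props)

    rng = np.random.default_rng(root_ss)
    root_states = rng.choice(N_CODONS, size=config.n_codons, p=pi)

    fg_nodes = _foreground_edges(tree)
    branch_rng = np.random.default_rng(branch_ss)
    states = {id(tree.tree.seed_node): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = np.empty_like(parent)
        on_foreground = id(node) in fg_nodes
        for ci, cls in enumerate(SITE_CLASSES):
            mask = classes == ci
            if not mask.any():
                continue
            bg_key, fg_key = _CLASS_OMEGAS[cls]
            kernel = kernels[fg_key if on_foreground else bg_key]
            p = kernel.probability_matrix(t)
            cum = np.cumsum(p, axis=1)
            u = branch_rng.random(mask.sum())
            child[mask] = (cum[parent[mask]] > u[:, None]).argmax(axis=1)
        states[id(node)] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = child

    taxa = tree.leaf_names()
    sequences = ["".join(CODONS[s] for s in leaf_states[t]) for t in taxa]
    aln = CodonAlignment(taxa, sequences)
    truth = TruthTable(site_classes=[SITE_CLASSES[c] for c in classes], original=aln)
    return aln, truth


def _random_non_stop_codon_change(codon: str, pos: int, rng: np.random.Generator) -> str:
    """Substitute position ``pos`` with a different base, avoiding stops."""
    choices = [n for n in "ACGT" if n != codon[pos]]
    rng.shuffle(choices)
    for n in choices:
        new = codon[:pos] + n + codon[pos + 1 :]
        if new not in STOP_CODONS:
            return new
    return codon


def corrupt_alignment(aln: CodonAlignment, spec: CorruptionSpec) -> tuple[CodonAlignment, TruthTable]:
    """Apply declared corruption operators; untouched columns stay byte-identical."""
    spec.validate(aln)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    codon_rows = {t: [aln.sequence_of(t)[i : i + 3] for i in range(0, len(aln.sequences[0]), 3)] for t in aln.taxa}
    truth = TruthTable(original=aln)

    for taxon, start, width, mode in spec.misalignment_windows:
        row = codon_rows[taxon]
        lo, hi = start - 1, start - 1 + width  # 0-based half-open codon window
        window = row[lo:hi]
        if mode == "gap_burst":
            row[lo:hi] = ["---"] * width
        elif mode == "shuffle":
            perm = rng.permutation(width)
            # re-draw until the order actually changes (width >= 2)
            while width > 1 and (perm == np.arange(width)).all():
                perm = rng.permutation(width)
            row[lo:hi] = [window[i] for i in perm]
        elif mode == "shift":
            row[lo:hi] = window[1:] + window[:1]
        truth.corrupted_columns.setdefault(taxon, set()).update(range(start, start + width))

    if spec.substitution_error_rate > 0:
        taxon = spec.error_taxon
        row = codon_rows[taxon]
        positions: list[int] = []
        for ci, codon in enumerate(row):
            if "-" in codon or "N" in codon:
                continue
            for pos in range(3):
                if rng.random() < spec.substitution_error_rate:
                    row[ci] = _random_non_stop_codon_change(row[ci], pos, rng)
                    positions.append(ci * 3 + pos)
                    truth.corrupted_columns.setdefault(taxon, set()).add(ci + 1)
        truth.error_positions[taxon] = positions

    if spec.frameshift is not None:
        taxon, pos, k = spec.frameshift
        row = codon_rows[taxon]
        nt = "".join(row)
        cut = (pos - 1) * 3
        if k < 0:
            nt = nt[:cut] + nt[cut - k :]
        else:
            insert = "".join(rng.choice(list("ACGT")) for _ in range(k))
            nt = nt[:cut] + insert + nt[cut:]
        target_len = 3 * len(row)
        nt = (nt + "-" * target_len)[:target_len]
        codon_rows[taxon] = [nt[i : i + 3] for i in range(0, target_len, 3)]
        truth.corrupted_columns.setdefault(taxon, set()).update(range(pos, len(row) + 1))

    out = CodonAlignment(list(aln.taxa), ["".join(codon_rows[t]) for t in aln.taxa])
    return out, truth


@dataclass
class CdnaFragment:
    """A contiguous transcript fragment with its true CDS coordinates."""

    fragment_id: str
    taxon: str
    start_codon: int  # 1-based, inclusive, on the taxon's ungapped CDS
    end_codon: int
    sequence: str


def emit_cdnas(
    aln: CodonAlignment,
    truth: TruthTable,
    n_fragments: int,
    fragment_span: tuple[int, int],
    with_errors: bool = False,
    seed: int = 0,
    taxa: list[str] | None = None,
) -> list[CdnaFragment]:
    """Cut cDNA-like fragments from each taxon's CDS.

    ``with_errors`` draws fragments from the (possibly corrupted) ``aln``;
    otherwise from the pristine sequences recorded in ``truth.original``.
    Spans are in codons, inclusive on both ends.
    """
    lo, hi = fragment_span
    if lo < 1 or hi < lo:
        raise ValueError("fragment span must cover at least one codon")
    source = aln if with_errors or truth.original is None else truth.original
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fragments: list[CdnaFragment] = []
    for taxon in taxa or source.taxa:
        cds = source.sequence_of(taxon).replace("-", "")
        n_codons = len(cds) // 3
        if hi > n_codons:
            raise ValueError(f"fragment span exceeds CDS length for {taxon}")
        for k in range(n_fragments):
            span = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, n_codons - span + 2))
            end = start + span - 1
            fragments.append(
                CdnaFragment(
                    fragment_id=f"{taxon}_cdna{k + 1}",
                    taxon=taxon,
                    start_codon=start,
                    end_codon=end,
                    sequence=cds[(start - 1) * 3 : end * 3],
                )
            )
    return fragments


from .orthologs import ProteinRecord  # noqa: E402  (shared record type)


@dataclass
class OrthologTruth:
    """True ortholog pairings for generated proteomes."""

    pairs: dict[tuple[str, str], str]  # (species, ref_gene) -> species gene id
    identities: dict[tuple[str, str], float]  # (species, ref_gene) -> % identity vs reference
    sub_threshold: set[tuple[str, str]] = field(default_factory=set)  # pairs below 60%


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            out[i] = _AA[rng.integers(len(_AA))]
    return "".join(out)


def emit_proteomes(
    n_species: int,
    n_genes: int,
    paralog_rate: float = 0.0,
    identity_decay: float = 0.05,
    seed: int = 0,
    min_length: int = 120,
    max_length: int = 300,
) -> tuple[dict[str, list[ProteinRecord]], OrthologTruth]:
    """Generate per-species proteomes descending from one ancestral set.

    Species ``sp1`` is the reference. Every gene has a true 1:1 ortholog in
    each species (per-residue substitution probability ``identity_decay``);
    with probability ``paralog_rate`` a species also carries a paralog, a
    further-diverged duplicate that can decoy best-hit searches.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ancestors = {
        f"g{j + 1}": "".join(_AA[rng.integers(len(_AA))] for _ in range(int(rng.integers(min_length, max_length + 1))))
        for j in range(n_genes)
    }
    species = [f"sp{i + 1}" for i in range(n_species)]
    proteomes: dict[str, list[ProteinRecord]] = {s: [] for s in species}
    truth = OrthologTruth(pairs={}, identities={})

    derived: dict[str, dict[str, str]] = {}
    for sp in species:
        rate = 0.0 if sp == species[0] else identity_decay
        derived[sp] = {g: _mutate_protein(a, rate, rng) for g, a in ancestors.items()}

    ref = species[0]
    for sp in species:
        for gene, seq in derived[sp].items():
            gid = f"{sp}_{gene}"
            proteomes[sp].append(ProteinRecord(sp, gid, f"{gid}_t1", seq))
            if sp != ref:
                ref_seq = derived[ref][gene]
                ident = 100.0 * sum(a == b for a, b in zip(ref_seq, seq)) / len(seq)
                truth.pairs[(sp, f"{ref}_{gene}")] = gid
                truth.identities[(sp, f"{ref}_{gene}")] = ident
                if ident < 60.0:
                    truth.sub_threshold.add((sp, f"{ref}_{gene}"))
        if sp != ref and paralog_rate > 0:
            for gene, seq in list(derived[sp].items()):
                if rng.random() < paralog_rate:
                    para = _mutate_protein(seq, min(1.0, 2 * identity_decay + 0.05), rng)
                    pid = f"{sp}_{gene}p"
                    proteomes[sp].append(ProteinRecord(sp, pid, f"{pid}_t1", para))
    return proteomes, truth
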