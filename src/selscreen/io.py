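"""Core containers and file I/O: codon alignments (FASTA) and labeled trees.

Trees follow the codeml branch-label convention: the foreground branch is
tagged with ``#1`` after the taxon (or internal-node clade) label, e.g.
``((human #1:0.01, chimp:0.01):0.02, mouse:0.1);``.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import CODON_INDEX, STOP_CODONS, translate_codon

_ALLOWED = set("ACGTN-")


@dataclass
class CodonAlignment:
    """An in-frame aligned set of coding sequences.

    taxa are ordered identifiers; sequences are equal-length strings over
    {A,C,G,T,N,-} whose length is divisible by three.
    """

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for name, s in zip(self.taxa, self.sequences):
            bad = set(s) - _ALLOWED
            if bad:
                raise ValueError(f"{name}: illegal characters {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codon(self, taxon: str, column: int) -> str:
        """Codon at 1-based codon column for a taxon."""
        s = self.sequence_of(taxon)
        return s[(column - 1) * 3 : column * 3]

    def codon_column(self, column: int) -> list[str]:
        """All taxa's codons at a 1-based codon column."""
        i = (column - 1) * 3
        return [s[i : i + 3] for s in self.sequences]

    def to_protein(self) -> "ProteinAlignment":
        """Translate codon columns to residues; gaps stay gaps."""
        prot = ["".join(translate_codon(s[i : i + 3]) for i in range(0, len(s), 3)) for s in self.sequences]
        return ProteinAlignment(list(self.taxa), prot)

    def check_no_internal_stops(self) -> None:
        for name, s in zip(self.taxa, self.sequences):
            for i in range(0, len(s) - 3, 3):  # terminal codon exempt
                if s[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {name} at codon {i // 3 + 1}")

    def to_fasta(self) -> str:
        handle = _io.StringIO()
        records = [SeqRecord(Seq(s), id=t, description="") for t, s in zip(self.taxa, self.sequences)]
        SeqIO.write(records, handle, "fasta")
        return handle.getvalue()

    @classmethod
    def from_fasta(cls, source) -> "CodonAlignment":
        """Read from a path or open handle."""
        records = list(SeqIO.parse(source, "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())


@dataclass
class ProteinAlignment:
    taxa: list[str]
    sequences: list[str]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]


_FG_RE = re.compile(r"\s*#\s*1$")


class LabeledTree:
    """A phylogeny with branch lengths and exactly one foreground branch.

    The foreground branch is the edge subtending the node whose label (leaf
    name or internal clade label) carries the ``#1`` tag.
    """

    def __init__(self, tree: dendropy.Tree, foreground: str):
        self.tree = tree
        self.foreground = foreground
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate leaf names")
        self._check_foreground()

    def _check_foreground(self) -> None:
        if self.foreground_node() is None:
            raise ValueError(f"foreground label {self.foreground!r} not found in tree")

    def foreground_node(self):
        for node in self.tree.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            if name == self.foreground:
                return node
        return None

    def leaf_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node.parent_node)

    @classmethod
    def from_newick(cls, newick: str, foreground: str | None = None) -> "LabeledTree":
        """Parse Newick; a ``#1`` suffix on a label marks the foreground.

        An explicit ``foreground`` argument overrides/replaces the tag.
        """
        tagged = None

        # tolerate codeml's spaced form "taxon #1" (quote for the parser)
        newick = re.sub(r"\s*#\s*1(?=[,:()\s;])", "#1", newick + " ")[:-1]
        tree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        for node in tree.preorder_node_iter():
            label_holder = "taxon" if node.taxon else "label"
            label = node.taxon.label if node.taxon else node.label
            if label and _FG_RE.search(label):
                clean = _FG_RE.sub("", label).strip()
                if tagged is not None:
                    raise ValueError("more than one branch tagged #1")
                tagged = clean
                if node.taxon:
                    node.taxon.label = clean
                else:
                    node.label = clean
        fg = foreground if foreground is not None else tagged
        if fg is None:
            raise ValueError("no foreground branch: tag one label with #1 or pass foreground=")
        return cls(tree, fg)

    def to_newick(self) -> str:
        """Newick string with the foreground branch tagged ``#1``."""
        node = self.foreground_node()
        holder = node.taxon if node.taxon else node
        original = holder.label
        holder.label = f"{original} #1"
        try:
            return self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        finally:
            holder.label = original

    def scaled(self, factor: float) -> "LabeledTree":
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return LabeledTree(clone, self.foreground)


def nj_tree(aln: CodonAlignment, foreground: str) -> LabeledTree:
    """Neighbor-joining tree from Jukes-Cantor nucleotide distances.

    A fallback for genes without a supplied phylogeny; a deliberate
    simplification relative to full maximum-likelihood tree search.
    """
    import math

    names = aln.taxa
    if foreground not in names:
        raise ValueError(f"foreground {foreground!r} not among taxa")
    n = len(names)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.sequences[i], aln.sequences[j]
            pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
            p = sum(1 for x, y in pairs if x != y) / len(pairs) if pairs else 0.0
            p = min(p, 0.749)
            d = -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            dist[i][j] = dist[j][i] = d
    csv = "," + ",".join(names) + "\n"
    for i, name in enumerate(names):
        csv += name + "," + ",".join(f"{dist[i][j]:.8f}" for j in range(n)) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(_io.StringIO(csv), delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return LabeledTree(tree, foreground)


def read_fasta_dict(source) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(source, "fasta")}


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
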