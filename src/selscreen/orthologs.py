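"""1:1 ortholog calling by reciprocal best hits with an identity floor.

One record per gene is kept (the longest transcript, ties broken by
transcript id), then each reference gene is searched against the other
species' proteome by affine-gap local alignment (BLOSUM62, gap open 11 /
extend 1 — blastp's defaults).  Hits under 60% identity are discarded
before ranking; a pair is an ortholog only when each member is the
other's best surviving hit.  A minimum raw alignment score stands in for
a search E-value cutoff at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = ["ProteinRecord", "OrthologPair", "RBHConfig", "select_longest_transcript", "best_hit", "reciprocal_best_hits"]


@dataclass(frozen=True)
class ProteinRecord:
    species: str
    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")


@dataclass
class OrthologPair:
    reference_gene: str
    other_species: str
    other_gene: str
    identity: float  # percent over aligned columns
    score: float


@dataclass
class RBHConfig:
    min_identity: float = 60.0
    min_score: float = 50.0  # raw BLOSUM62 score floor (E-value stand-in)
    gap_open: float = -11.0
    gap_extend: float = -1.0


def select_longest_transcript(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """One record per (species, gene): the longest; ties by transcript id."""
    out: list[ProteinRecord] = []
    keyed = sorted(records, key=lambda r: (r.species, r.gene_id))
    for _, group in groupby(keyed, key=lambda r: (r.species, r.gene_id)):
        out.append(min(group, key=lambda r: (-len(r.sequence), r.transcript_id)))
    return out


def _aligner(cfg: RBHConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def _align(aligner: PairwiseAligner, query: str, target: str) -> tuple[float, float]:
    """(score, percent identity over aligned columns incl. internal gaps)."""
    alns = aligner.align(query, target)
    if len(alns) == 0:
        return 0.0, 0.0
    best = alns[0]
    t_blocks, q_blocks = best.aligned
    if len(t_blocks) == 0:
        return float(best.score), 0.0
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += int(ts - prev_t) + int(qs - prev_q)  # internal gaps
        for off in range(int(te - ts)):
            columns += 1
            if query[int(ts) + off] == target[int(qs) + off]:
                matches += 1
        prev_t, prev_q = int(te), int(qe)
    identity = 100.0 * matches / columns if columns else 0.0
    return float(best.score), identity


def best_hit(
    query: ProteinRecord, targets: list[ProteinRecord], config: RBHConfig | None = None
) -> tuple[ProteinRecord, float, float] | None:
    """Highest-scoring target at >= the identity floor, or None.

    Returns (target, identity, score); equal scores break toward the
    lexicographically first gene id.
    """
    if not targets:
        return None
    config = config or RBHConfig()
    aligner = _aligner(config)
    best: tuple[ProteinRecord, float, float] | None = None
    for target in sorted(targets, key=lambda r: r.gene_id):
        score, identity = _align(aligner, query.sequence, target.sequence)
        if identity < config.min_identity or score < config.min_score:
            continue
        if best is None or score > best[2]:
            best = (target, identity, score)
    return best


def reciprocal_best_hits(
    reference: list[ProteinRecord], other: list[ProteinRecord], config: RBHConfig | None = None
) -> list[OrthologPair]:
    """Pairs (a, b) where a's best hit is b and b's best hit is a."""
    config = config or RBHConfig()
    reference = select_longest_transcript(reference)
    other = select_longest_transcript(other)
    pairs: list[OrthologPair] = []
    if not other or not reference:
        return pairs
    forward: dict[str, tuple[ProteinRecord, float, float]] = {}
    for query in reference:
        hit = best_hit(query, other, config)
        if hit is not None:
            forward[query.gene_id] = hit
    back_cache: dict[str, str | None] = {}
    ref_by_gene = {r.gene_id: r for r in reference}
    for ref_gene, (target, identity, score) in sorted(forward.items()):
        if target.gene_id not in back_cache:
            back = best_hit(target, reference, config)
            back_cache[target.gene_id] = back[0].gene_id if back else None
        if back_cache[target.gene_id] == ref_gene:
            pairs.append(
                OrthologPair(
                    reference_gene=ref_gene,
                    other_species=target.species,
                    other_gene=target.gene_id,
                    identity=identity,
                    score=score,
                )
            )
    return pairs
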