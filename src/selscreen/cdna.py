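"""Validation of candidate positive sites against cDNA evidence.

Each cDNA is locally aligned to the gene's coding sequence (both
orientations; blastn-like scoring).  A site is checked against every cDNA
whose mapped interval covers all three codon positions: it is *valid* if
at least one covering cDNA matches the codon base-for-base with no gaps,
*invalid* if covering cDNAs exist but none matches, and *unmapped* when
no cDNA covers the codon at all (such sites are excluded from error-rate
statistics and reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .branchsite import PositiveSiteRecord
from .io import CodonAlignment

__all__ = [
    "CdnaMapConfig",
    "CdnaMapping",
    "CdnaMatchResult",
    "SiteValidation",
    "ValidationSummary",
    "map_cdna",
    "validate_site",
    "validation_summary",
    "alignment_column_to_cds_codon",
]


@dataclass
class CdnaMapConfig:
    """blastn-flavored local alignment scoring and acceptance floors."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 40.0  # ~20 matched bases
    min_length: int = 30  # aligned bases
    check_reverse: bool = True


@dataclass
class CdnaMapping:
    cdna_id: str
    score: float
    strand: str  # "+" or "-"
    cds_start: int  # 1-based, inclusive, on the CDS
    cds_end: int
    # cds 0-based position -> cdna base aligned there (None = gap in cdna)
    base_by_cds_pos: dict[int, str | None] = field(default_factory=dict)


def _make_aligner(cfg: CdnaMapConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def _map_one_strand(cds: str, cdna: str, cfg: CdnaMapConfig):
    aligner = _make_aligner(cfg)
    alns = aligner.align(cds, cdna)
    if len(alns) == 0:
        return None
    return alns[0]


def map_cdna(cds: str, cdna: str, cdna_id: str = "cdna", config: CdnaMapConfig | None = None) -> CdnaMapping | None:
    """Best local alignment of a cDNA onto a CDS, or None if unacceptable.

    Both orientations are tried when ``check_reverse``; the mapping
    records, for every covered CDS position, the cDNA base aligned to it
    (None where the cDNA has a gap), so codon identity can be checked
    without re-aligning.
    """
    if not cds or not cdna:
        raise ValueError("both sequences must be non-empty")
    config = config or CdnaMapConfig()
    candidates = []
    fwd = _map_one_strand(cds, cdna, config)
    if fwd is not None:
        candidates.append(("+", fwd))
    if config.check_reverse:
        rev = _map_one_strand(cds, str(Seq(cdna).reverse_complement()), config)
        if rev is not None:
            candidates.append(("-", rev))
    if not candidates:
        return None
    strand, best = max(candidates, key=lambda c: c[1].score)
    target_blocks, query_blocks = best.aligned
    if len(target_blocks) == 0:
        return None
    aligned_len = sum(int(e - s) for s, e in target_blocks)
    if best.score < config.min_score or aligned_len < config.min_length:
        return None

    query_seq = str(Seq(cdna).reverse_complement()) if strand == "-" else cdna
    base_by_pos: dict[int, str | None] = {}
    prev_t_end = None
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if prev_t_end is not None:
            for p in range(prev_t_end, int(ts)):  # deletion in cdna
                base_by_pos[p] = None
        for off in range(int(te - ts)):
            base_by_pos[int(ts) + off] = query_seq[int(qs) + off]
        prev_t_end = int(te)

    cds_start = int(target_blocks[0][0]) + 1
    cds_end = int(target_blocks[-1][1])
    return CdnaMapping(
        cdna_id=cdna_id,
        score=float(best.score),
        strand=strand,
        cds_start=cds_start,
        cds_end=cds_end,
        base_by_cds_pos=base_by_pos,
    )


@dataclass
class CdnaMatchResult:
    site: PositiveSiteRecord | None
    cdna_id: str
    covered: bool
    codon_identical: bool


@dataclass
class SiteValidation:
    site: PositiveSiteRecord | None
    n_cdnas_mapped: int
    n_covering: int
    verdict: str  # valid | invalid | unmapped
    matches: list[CdnaMatchResult] = field(default_factory=list)


def alignment_column_to_cds_codon(aln: CodonAlignment, taxon: str, column: int) -> int | None:
    """1-based codon index on the taxon's ungapped CDS for an alignment column."""
    seq = aln.sequence_of(taxon)
    codon = seq[(column - 1) * 3 : column * 3]
    if "-" in codon:
        return None
    return sum(1 for i in range(0, (column - 1) * 3, 3) if "-" not in seq[i : i + 3]) + 1


def validate_site(
    site: PositiveSiteRecord | None,
    cds: str,
    cdnas: dict[str, str],
    codon_index: int | None = None,
    config: CdnaMapConfig | None = None,
) -> SiteValidation:
    """Verdict for one site given its CDS and that species' cDNA set.

    ``codon_index`` is the 1-based codon position on the (ungapped) CDS;
    when omitted it is taken from ``site.column`` (then the CDS must be
    the ungapped row, i.e. column and codon index coincide).
    """
    config = config or CdnaMapConfig()
    if codon_index is None:
        if site is None:
            raise ValueError("need a site or an explicit codon_index")
        codon_index = site.column
    lo = (codon_index - 1) * 3  # 0-based nt positions lo, lo+1, lo+2
    if lo + 3 > len(cds):
        raise ValueError("codon index beyond CDS end")
    codon = cds[lo : lo + 3]

    n_mapped = 0
    matches: list[CdnaMatchResult] = []
    any_identical = False
    n_covering = 0
    for cdna_id in sorted(cdnas):
        mapping = map_cdna(cds, cdnas[cdna_id], cdna_id=cdna_id, config=config)
        if mapping is None:
            continue
        n_mapped += 1
        bases = [mapping.base_by_cds_pos.get(p) for p in (lo, lo + 1, lo + 2)]
        covered = all(p in mapping.base_by_cds_pos for p in (lo, lo + 1, lo + 2))
        identical = covered and all(b is not None for b in bases) and "".join(bases) == codon
        if covered:
            n_covering += 1
        any_identical = any_identical or identical
        matches.append(CdnaMatchResult(site=site, cdna_id=cdna_id, covered=covered, codon_identical=identical))

    if n_covering == 0:
        verdict = "unmapped"
    elif any_identical:
        verdict = "valid"
    else:
        verdict = "invalid"
    if site is not None:
        site.cdna_verdict = verdict
    return SiteValidation(site=site, n_cdnas_mapped=n_mapped, n_covering=n_covering, verdict=verdict, matches=matches)


@dataclass
class ValidationSummary:
    n_total: int
    n_mapped: int  # sites with >=1 covering cDNA
    n_valid: int
    n_invalid: int
    coverage_pct: float  # 100 * n_mapped / n_total
    fpr_pct: float  # 100 * n_invalid / n_mapped
    surviving_genes: list[str]


def validation_summary(validations: list[SiteValidation]) -> ValidationSummary:
    """Coverage and cDNA-level error-rate roll-up for one screen.

    A gene survives if at least one of its sites is valid; unmapped sites
    carry no evidence either way and are excluded from the error rate.
    """
    n_total = len(validations)
    mapped = [v for v in validations if v.verdict != "unmapped"]
    n_valid = sum(1 for v in mapped if v.verdict == "valid")
    n_invalid = sum(1 for v in mapped if v.verdict == "invalid")
    coverage = 100.0 * len(mapped) / n_total if n_total else 0.0
    fpr = 100.0 * n_invalid / len(mapped) if mapped else 0.0
    genes = sorted({v.site.gene for v in mapped if v.verdict == "valid" and v.site is not None})
    return ValidationSummary(
        n_total=n_total,
        n_mapped=len(mapped),
        n_valid=n_valid,
        n_invalid=n_invalid,
        coverage_pct=coverage,
        fpr_pct=fpr,
        surviving_genes=genes,
    )
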