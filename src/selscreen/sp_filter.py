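"""Sum-of-pairs (SP) penalty screening of candidate positive sites.

A candidate site is trusted only if the +/-15-residue windows flanking it
align cleanly across the species.  Each stream (upstream, downstream) is
scored per column: 0 for a perfect match, -S for a mismatch, -2S for a
residue opposite a gap, where the base penalty S = 15/n grows when a site
sits near a sequence edge and only n < 15 focal residues are available.
Two aggregates gate the site: the general score (sum over all unordered
sequence pairs, divided by the number of sequences N) must exceed -50 and
the individual score (focal sequence against every other, unaveraged)
must exceed -15, both strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .branchsite import PositiveSiteRecord
from .io import CodonAlignment, ProteinAlignment

__all__ = ["SPConfig", "SPScoreResult", "extract_window", "pairwise_penalty", "score_site", "filter_sites"]


@dataclass
class SPConfig:
    window: int = 15  # residues per stream (45 bp)
    general_threshold: float = -50.0
    individual_threshold: float = -15.0
    # "pairsum_over_n": sum over all unordered pairs, divided by N
    # "focal_mean": focal-vs-other pairs only, divided by N (alternative reading)
    general_mode: str = "pairsum_over_n"
    individual_averaged: bool = False
    include_site_column: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.general_mode not in ("pairsum_over_n", "focal_mean"):
            raise ValueError("unknown general_mode")


@dataclass
class SPScoreResult:
    site: PositiveSiteRecord | None
    n_up: int
    n_down: int
    s_up: float  # 15/n_up, 0.0 when the stream is empty
    s_down: float
    general_score: float
    individual_score: float
    passed: bool


def extract_window(
    aln: ProteinAlignment, focal_taxon: str, site_column: int, window: int = 15
) -> tuple[list[int], list[int], int, int]:
    """Alignment columns flanking a site, counted in focal residues.

    Walks outward from ``site_column`` (1-based) until ``window`` focal
    non-gap residues are collected per stream or the focal sequence ends.
    Every intervening column — including columns where the focal taxon is
    gapped — belongs to the window; the site column itself does not.
    Returns (upstream columns, downstream columns, n_up, n_down).
    """
    focal = aln.sequence_of(focal_taxon)
    if not (1 <= site_column <= len(focal)):
        raise ValueError("site column outside alignment")
    if focal[site_column - 1] == "-":
        raise ValueError(f"focal taxon {focal_taxon!r} is gapped at column {site_column}")

    up_cols: list[int] = []
    n_up = 0
    for col in range(site_column - 1, 0, -1):
        if focal[col - 1] != "-":
            n_up += 1
            up_cols.append(col)
            if n_up == window:
                break
        else:
            up_cols.append(col)
    # trim leading columns where the focal taxon is gapped beyond its last residue
    while up_cols and focal[up_cols[-1] - 1] == "-":
        up_cols.pop()
    up_cols.reverse()

    down_cols: list[int] = []
    n_down = 0
    for col in range(site_column + 1, len(focal) + 1):
        if focal[col - 1] != "-":
            n_down += 1
            down_cols.append(col)
            if n_down == window:
                break
        else:
            down_cols.append(col)
    while down_cols and focal[down_cols[-1] - 1] == "-":
        down_cols.pop()
    return up_cols, down_cols, n_up, n_down


def pairwise_penalty(window_a: str, window_b: str, s: float) -> float:
    """SP penalty of two extracted windows.

    Per column: identical residues 0, mismatch -s, residue/gap -2s;
    gap/gap carries no pairwise evidence and scores 0.
    """
    if len(window_a) != len(window_b):
        raise ValueError("window length mismatch")
    total = 0.0
    for a, b in zip(window_a, window_b):
        if a == "-" and b == "-":
            continue
        if a == "-" or b == "-":
            total -= 2 * s
        elif a != b:
            total -= s
    return total


def _columns_text(aln: ProteinAlignment, cols: list[int]) -> list[str]:
    return ["".join(seq[c - 1] for c in cols) for seq in aln.sequences]


def score_site(
    aln: ProteinAlignment | CodonAlignment,
    site: PositiveSiteRecord,
    config: SPConfig | None = None,
) -> SPScoreResult:
    """General and individual SP penalty scores for one candidate site."""
    config = config or SPConfig()
    if isinstance(aln, CodonAlignment):
        aln = aln.to_protein()
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 sequences to score")
    up_cols, down_cols, n_up, n_down = extract_window(aln, site.foreground, site.column, config.window)
    if config.include_site_column:
        up_cols = up_cols + [site.column]
    s_up = config.window / n_up if n_up else 0.0
    s_down = config.window / n_down if n_down else 0.0
    up_text = _columns_text(aln, up_cols)
    down_text = _columns_text(aln, down_cols)

    n_seq = aln.n_taxa
    focal_idx = aln.taxa.index(site.foreground)

    def pair_score(i: int, j: int) -> float:
        total = 0.0
        if n_up:
            total += pairwise_penalty(up_text[i], up_text[j], s_up)
        if n_down:
            total += pairwise_penalty(down_text[i], down_text[j], s_down)
        return total

    if config.general_mode == "pairsum_over_n":
        general = sum(pair_score(i, j) for i, j in combinations(range(n_seq), 2)) / n_seq
    else:  # focal_mean
        general = sum(pair_score(focal_idx, j) for j in range(n_seq) if j != focal_idx) / n_seq

    individual = sum(pair_score(focal_idx, j) for j in range(n_seq) if j != focal_idx)
    if config.individual_averaged:
        individual /= n_seq

    passed = general > config.general_threshold and individual > config.individual_threshold
    return SPScoreResult(
        site=site,
        n_up=n_up,
        n_down=n_down,
        s_up=s_up,
        s_down=s_down,
        general_score=general,
        individual_score=individual,
        passed=passed,
    )


@dataclass
class SpeciesRetention:
    total: int = 0
    retained: int = 0

    @property
    def fpr(self) -> float:
        """Misalignment false-positive rate 1 - retained/total, in percent."""
        if self.total == 0:
            return 0.0
        return 100.0 * (1.0 - self.retained / self.total)


def filter_sites(
    sites: list[PositiveSiteRecord],
    alignments: dict[str, ProteinAlignment | CodonAlignment],
    config: SPConfig | None = None,
) -> tuple[list[SPScoreResult], dict[str, SpeciesRetention], list[PositiveSiteRecord]]:
    """Score every site and summarize per-species retention.

    Returns (per-site results, per-foreground-species retention summary,
    orphan sites whose gene has no alignment — reported, not scored).
    """
    config = config or SPConfig()
    results: list[SPScoreResult] = []
    summary: dict[str, SpeciesRetention] = {}
    orphans: list[PositiveSiteRecord] = []
    for site in sites:
        aln = alignments.get(site.gene)
        if aln is None:
            orphans.append(site)
            continue
        res = score_site(aln, site, config)
        site.sp_pass = res.passed
        results.append(res)
        entry = summary.setdefault(site.foreground, SpeciesRetention())
        entry.total += 1
        entry.retained += int(res.passed)
    return results, summary, orphans
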