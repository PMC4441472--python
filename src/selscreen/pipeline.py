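"""Orchestration of the full screen and its summary arithmetic.

Stages, per foreground species: branch-site test over all genes (with
per-species BH-FDR), SP-score filtering of the BEB candidate sites, then
cDNA validation of the survivors.  The reporting helpers compute the
derived statistics such screens publish: per-group mean gene counts,
cross-group fold changes, overall site retention, and per-species
misalignment false-positive rates.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .branchsite import (
    BranchSiteFit,
    PositiveSiteRecord,
    ScreenThresholds,
    gene_passes,
    screen_genes,
)
from .cdna import CdnaMapConfig, SiteValidation, ValidationSummary, alignment_column_to_cds_codon, validate_site, validation_summary
from .io import CodonAlignment, LabeledTree
from .sp_filter import SPConfig, SpeciesRetention, filter_sites

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesGroupDesign",
    "SpeciesSummary",
    "ScreenSummary",
    "run_screen",
    "group_means_and_fold",
    "retention_overall",
]


@dataclass
class SpeciesGroupDesign:
    """Which species belong to which (e.g. breeding-strategy) group.

    Every species of a set is tested once as foreground; its group mates
    are the designated backgrounds (the branch-site model itself treats
    all non-foreground branches as background).
    """

    name: str
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.groups.values():
            for sp in members:
                if sp in seen:
                    raise ValueError(f"species {sp!r} assigned to more than one group")
                seen.add(sp)

    def group_of(self, species: str) -> str:
        for label, members in self.groups.items():
            if species in members:
                return label
        raise KeyError(species)

    def all_species(self) -> list[str]:
        return [sp for members in self.groups.values() for sp in members]


@dataclass
class SpeciesSummary:
    species: str
    group: str
    n_tested: int
    n_failed: int
    n_p001: int
    n_fdr: int
    n_sp: int
    n_sites_beb: int
    n_sites_sp: int

    @property
    def fpr_misalignment(self) -> float:
        """Percent of BEB sites discarded by the SP filter."""
        if self.n_sites_beb == 0:
            return 0.0
        return 100.0 * (1.0 - self.n_sites_sp / self.n_sites_beb)


@dataclass
class ScreenSummary:
    design: str
    per_species: dict[str, SpeciesSummary]
    validation: ValidationSummary | None = None

    def counts_by_group(self, field_name: str, design: SpeciesGroupDesign) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {g: [] for g in design.groups}
        for sp, summ in self.per_species.items():
            out[summ.group].append(getattr(summ, field_name))
        return out


def group_means_and_fold(
    counts_by_group: dict[str, list[float]], numerator: str, denominator: str
) -> tuple[dict[str, float], float | None]:
    """Arithmetic group means and their ratio.

    The fold change is mean(numerator group) / mean(denominator group);
    None when the denominator mean is zero (reported as undefined).
    """
    means = {}
    for label, values in counts_by_group.items():
        if not values:
            raise ValueError(f"group {label!r} has no species")
        means[label] = sum(values) / len(values)
    fold = None if means[denominator] == 0 else means[numerator] / means[denominator]
    return means, fold


def retention_overall(site_counts: list[tuple[int, int]]) -> float:
    """Percent of candidate sites kept: 100 * sum(retained)/sum(total)."""
    total = sum(t for t, _ in site_counts)
    retained = sum(r for _, r in site_counts)
    if total == 0:
        return 100.0
    return 100.0 * retained / total


def _fits_frame(fits: list[BranchSiteFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "foreground": [f.foreground for f in fits],
            "lnl_alt": [f.lnl_alt for f in fits],
            "lnl_null": [f.lnl_null for f in fits],
            "lrt_stat": [f.lrt_stat for f in fits],
            "p_value": [f.p_value for f in fits],
            "q_value": [f.q_value for f in fits],
            "omega2_hat": [f.params_alt.omega2 for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def _sites_frame(sites: list[PositiveSiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene for s in sites],
            "foreground": [s.foreground for s in sites],
            "column": [s.column for s in sites],
            "residue": [s.residue for s in sites],
            "posterior": [s.posterior for s in sites],
            "sp_pass": [s.sp_pass for s in sites],
            "cdna_verdict": [s.cdna_verdict for s in sites],
        }
    )


def run_screen(
    design: SpeciesGroupDesign,
    alignments: dict[str, CodonAlignment],
    trees: "dict[str, LabeledTree] | LabeledTree",
    cdnas: dict[str, dict[str, dict[str, str]]] | None = None,
    thresholds: ScreenThresholds | None = None,
    sp_config: SPConfig | None = None,
    cdna_config: CdnaMapConfig | None = None,
    out_dir: str | Path | None = None,
    resume: bool = False,
    seed: int = 0,
    codon_freq: str = "f3x4",
    n_starts: int = 3,
) -> tuple[ScreenSummary, dict[str, list[BranchSiteFit]], list[PositiveSiteRecord]]:
    """Execute the full screen for every species in the design.

    ``cdnas`` maps gene -> taxon -> {cdna_id: sequence}.  When ``out_dir``
    is given, per-stage TSVs are persisted; with ``resume`` the expensive
    branch-site stage is reloaded from them when present.  Per-gene
    failures are logged and counted, never fatal.
    """
    thresholds = thresholds or ScreenThresholds()
    sp_config = sp_config or SPConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    missing = [sp for sp in design.all_species() if not any(sp in a.taxa for a in alignments.values())]
    if missing:
        raise ValueError(f"designed species absent from every alignment: {missing}")

    per_species: dict[str, SpeciesSummary] = {}
    fits_by_species: dict[str, list[BranchSiteFit]] = {}
    all_sites: list[PositiveSiteRecord] = []

    for si, species in enumerate(design.all_species()):
        t0 = time.perf_counter()
        testable = {g: a for g, a in alignments.items() if species in a.taxa}
        fits_file = out_path / f"fits_{species}.tsv" if out_path else None
        sites_file = out_path / f"sites_{species}.tsv" if out_path else None

        if resume and fits_file is not None and fits_file.exists() and sites_file.exists():
            fits, sites = _load_stage(fits_file, sites_file)
        else:
            sp_trees = _retag(trees, species)
            fits, sites = screen_genes(
                testable, sp_trees, thresholds, codon_freq=codon_freq, n_starts=n_starts, seed=seed + 1013 * si
            )
            if fits_file is not None:
                _fits_frame(fits).to_csv(fits_file, sep="\t", index=False)
                _sites_frame(sites).to_csv(sites_file, sep="\t", index=False)

        # SP filtering of candidate sites
        _, retention, _orphans = filter_sites(sites, alignments, sp_config)
        ret = retention.get(species, SpeciesRetention())

        passing = {f.gene for f in fits if f.converged and gene_passes(f.p_value, f.q_value, thresholds)}
        genes_with_sp_site = {s.gene for s in sites if s.sp_pass}
        summ = SpeciesSummary(
            species=species,
            group=design.group_of(species),
            n_tested=len(fits),
            n_failed=sum(1 for f in fits if not f.converged),
            n_p001=sum(1 for f in fits if f.converged and f.p_value <= thresholds.p_value),
            n_fdr=len(passing),
            n_sp=len(passing & genes_with_sp_site),
            n_sites_beb=ret.total,
            n_sites_sp=ret.retained,
        )
        per_species[species] = summ
        fits_by_species[species] = fits
        all_sites.extend(sites)
        logger.info("species %s screened in %.1fs", species, time.perf_counter() - t0)

    # cDNA validation of SP-surviving sites
    validation = None
    if cdnas is not None:
        validations: list[SiteValidation] = []
        for site in all_sites:
            if not site.sp_pass:
                continue
            gene_cdnas = cdnas.get(site.gene, {}).get(site.foreground)
            if not gene_cdnas:
                site.cdna_verdict = "unmapped"
                validations.append(SiteValidation(site=site, n_cdnas_mapped=0, n_covering=0, verdict="unmapped"))
                continue
            aln = alignments[site.gene]
            cds = aln.sequence_of(site.foreground).replace("-", "")
            codon_index = alignment_column_to_cds_codon(aln, site.foreground, site.column)
            if codon_index is None:
                site.cdna_verdict = "unmapped"
                validations.append(SiteValidation(site=site, n_cdnas_mapped=0, n_covering=0, verdict="unmapped"))
                continue
            validations.append(validate_site(site, cds, gene_cdnas, codon_index=codon_index, config=cdna_config))
        validation = validation_summary(validations)
        if out_path is not None:
            pd.DataFrame(
                {
                    "gene": [v.site.gene for v in validations],
                    "foreground": [v.site.foreground for v in validations],
                    "column": [v.site.column for v in validations],
                    "n_covering": [v.n_covering for v in validations],
                    "verdict": [v.verdict for v in validations],
                }
            ).to_csv(out_path / "validations.tsv", sep="\t", index=False)

    summary = ScreenSummary(design=design.name, per_species=per_species, validation=validation)
    if out_path is not None:
        pd.DataFrame(
            {
                "species": [s.species for s in per_species.values()],
                "group": [s.group for s in per_species.values()],
                "n_tested": [s.n_tested for s in per_species.values()],
                "n_failed": [s.n_failed for s in per_species.values()],
                "n_p001": [s.n_p001 for s in per_species.values()],
                "n_fdr": [s.n_fdr for s in per_species.values()],
                "n_sp": [s.n_sp for s in per_species.values()],
                "n_sites_beb": [s.n_sites_beb for s in per_species.values()],
                "n_sites_sp": [s.n_sites_sp for s in per_species.values()],
                "fpr_misalignment": [round(s.fpr_misalignment, 2) for s in per_species.values()],
            }
        ).to_csv(out_path / "summary.tsv", sep="\t", index=False)
    return summary, fits_by_species, all_sites


def _retag(trees: "dict[str, LabeledTree] | LabeledTree", species: str):
    if isinstance(trees, LabeledTree):
        return LabeledTree(trees.tree, species)
    return {g: LabeledTree(t.tree, species) for g, t in trees.items()}


def _load_stage(fits_file: Path, sites_file: Path) -> tuple[list[BranchSiteFit], list[PositiveSiteRecord]]:
    from .branchsite import BranchSiteParams

    fdf = pd.read_csv(fits_file, sep="\t")
    fits = [
        BranchSiteFit(
            gene=row.gene,
            foreground=row.foreground,
            lnl_alt=row.lnl_alt,
            lnl_null=row.lnl_null,
            params_alt=BranchSiteParams(1.0, 0.5, row.omega2_hat, 0.5, 0.4),
            params_null=BranchSiteParams(1.0, 0.5, 1.0, 0.5, 0.4),
            lrt_stat=row.lrt_stat,
            p_value=row.p_value,
            q_value=None if pd.isna(row.q_value) else row.q_value,
            converged=bool(row.converged),
        )
        for row in fdf.itertuples()
    ]
    sdf = pd.read_csv(sites_file, sep="\t")
    sites = [
        PositiveSiteRecord(
            gene=row.gene,
            foreground=row.foreground,
            column=int(row.column),
            residue=row.residue,
            posterior=row.posterior,
        )
        for row in sdf.itertuples()
    ]
    return fits, sites
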