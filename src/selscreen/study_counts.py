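"""Per-species counts from a published genome-wide branch-site screen of
seasonal vs non-seasonal breeding mammals.

These are the printed summary tables of that screen — gene counts under
successive filters (raw chi-square p <= 0.01, Benjamini-Hochberg FDR <
0.05, SP-score filtering) and candidate-site counts before/after SP
filtering — for its two study designs: a Distant-Species set (primates,
rodents, carnivores, horse, rabbit) and a Close-Species set (primates
only).  They serve as inputs to the reporting arithmetic (group means,
fold changes, retention and misalignment false-positive rates), which is
how the headline statistics of such a screen are derived from raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

NON_SEASONAL = "non_seasonal"
SEASONAL = "seasonal"


@dataclass(frozen=True)
class GeneCounts:
    species: str
    p001: int  # genes with chi-square p <= 0.01
    fdr: int  # of those, genes with BH FDR < 0.05
    sp: int  # of those, genes surviving SP-score filtering


@dataclass(frozen=True)
class SiteCounts:
    species: str
    beb: int  # sites with BEB posterior > 0.95
    sp_filtered: int  # of those, sites surviving SP-score filtering
    printed_fpr: float = float("nan")  # the FPR column as printed, in percent


DISTANT_GENES: dict[str, list[GeneCounts]] = {
    NON_SEASONAL: [
        GeneCounts("Human", 88, 16, 4),
        GeneCounts("Chimpanzee", 207, 68, 27),
        GeneCounts("Cynomolgus", 113, 62, 27),
        GeneCounts("Mouse", 228, 15, 4),
        GeneCounts("Rat", 274, 43, 18),
    ],
    SEASONAL: [
        GeneCounts("Indian rhesus", 453, 361, 131),
        GeneCounts("Chinese rhesus", 203, 110, 51),
        GeneCounts("Dog", 499, 158, 54),
        GeneCounts("Horse", 463, 157, 55),
        GeneCounts("Rabbit", 444, 129, 58),
    ],
}

CLOSE_GENES: dict[str, list[GeneCounts]] = {
    NON_SEASONAL: [
        GeneCounts("Human", 116, 20, 4),
        GeneCounts("Gorilla", 274, 163, 34),
        GeneCounts("Chimpanzee", 289, 117, 48),
        GeneCounts("Cynomolgus", 266, 159, 69),
    ],
    SEASONAL: [
        GeneCounts("Orangutan", 446, 303, 147),
        GeneCounts("Indian rhesus", 603, 464, 157),
        GeneCounts("Chinese rhesus", 229, 130, 57),
        GeneCounts("Marmoset", 688, 314, 107),
    ],
}

DISTANT_SITES: dict[str, list[SiteCounts]] = {
    NON_SEASONAL: [
        SiteCounts("Human", 26, 16, 38.46),
        SiteCounts("Chimpanzee", 103, 65, 36.89),
        SiteCounts("Cynomolgus", 92, 54, 41.3),
        SiteCounts("Mouse", 10, 5, 50.0),
        SiteCounts("Rat", 66, 42, 36.36),
    ],
    SEASONAL: [
        SiteCounts("Indian rhesus", 532, 206, 61.28),
        SiteCounts("Chinese rhesus", 153, 77, 49.67),
        SiteCounts("Dog", 261, 106, 59.39),
        SiteCounts("Horse", 262, 134, 48.85),
        SiteCounts("Rabbit", 241, 127, 47.3),
    ],
}

CLOSE_SITES: dict[str, list[SiteCounts]] = {
    NON_SEASONAL: [
        SiteCounts("Human", 9, 6, 33.33),
        SiteCounts("Gorilla", 158, 84, 46.84),
        SiteCounts("Chimpanzee", 132, 90, 31.82),
        SiteCounts("Cynomolgus", 237, 131, 44.73),
    ],
    SEASONAL: [
        SiteCounts("Orangutan", 444, 246, 44.59),
        SiteCounts("Indian rhesus", 531, 299, 43.69),
        SiteCounts("Chinese rhesus", 189, 89, 52.91),
        SiteCounts("Marmoset", 364, 232, 36.26),
    ],
}

#: Genes that survived the final cDNA-mapping validation, by breeding group.
CDNA_VALIDATED_GENES: dict[str, list[str]] = {
    NON_SEASONAL: [
        "CGA", "TOMM6", "CD151", "RRP8", "ACCN4", "CHRNA1",  # human
        "SNX5", "NCAPG", "VPS33A",  # cynomolgus
        "SWI5", "NID2", "DHDH", "DNAH1",  # mouse
        "INVS", "GALK2",  # rat
    ],
    SEASONAL: [
        "TADA1", "LGALS3BP", "ZFR", "THRAP3", "MTMR12", "TMCC2", "SLC44A2",
        "MIPEP", "XRN2", "RBM47", "MBTPS1", "FAM69A", "SLC43A2", "RAB1B",
        "CMTM6", "DARS2", "AARS", "TH1L",  # orangutan
        "PLEK", "SNX25",  # rabbit
        "ALB",  # dog
        "SMC4", "ANO6", "GLIPR1",  # horse
    ],
}

#: Site-level totals of the cDNA validation stage: of all SP-surviving
#: sites, the number covered by >=1 cDNA and, of those, the number whose
#: codon disagreed with every covering cDNA.
CDNA_SITE_TOTALS = {"sp_filtered_total": 2009, "covered": 193, "inconsistent": 120, "consistent": 74}


def all_site_counts() -> list[SiteCounts]:
    out: list[SiteCounts] = []
    for table in (DISTANT_SITES, CLOSE_SITES):
        for group in (NON_SEASONAL, SEASONAL):
            out.extend(table[group])
    return out
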