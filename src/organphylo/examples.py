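"""Reference worked-example datasets for the Nannochloropsis organelle
phylotyping workflow: the MLST allele table distinguishing three N. oceanica
strains (CCMP531, IMET1, CCMP1779), the SSR panel separating IMET1 from
CCMP531, interspecies marker sensitivity values, and genus-level SNP and
substitution-rate summaries. Compact reference inputs used in tests,
documentation and the acceptance script.
"""

from __future__ import annotations

from ._util import canonical_rotation
from .align_dist import SnpSummary
from .marker_screen import MarkerEvaluation
from .mlst import MlstLocus, read_allele_table
from .ssr import SsrLocus

MLST_STRAINS = ["CCMP531", "IMET1", "CCMP1779"]

# allele table: one row per variant position, 1-based mt-genome coordinates on
# the IMET1 reference; '-' is an indel allele retained as a genotype character
MLST_ALLELE_TABLE = """\
region\tlocation\tCCMP531\tIMET1\tCCMP1779
rps11_mt-nad4\t8512\tG\tA\tA
rps11_mt-nad4\t8513\tC\tT\tT
rps11_mt-nad4\t8555\t-\tG\tG
rps11_mt-nad4\t8577\tC\tA\tA
nad4\t8710\tT\tC\tC
nad4\t8720\tG\tA\tA
nad4\t8941\tC\tA\tA
nad4\t8956\tC\tT\tT
rps3_mt\t21403\tG\tC\tC
rps3_mt\t21488\tT\tC\tC
rps3_mt\t21583\tA\tT\tT
rps3_mt\t21637\tA\tG\tG
rps3_mt\t21682\tA\tG\tG
rps3_mt\t21940\tG\tA\tA
cox2-rrn16_mt\t34621\tG\tT\tT
cox2-rrn16_mt\t34727\tA\tG\tG
cox2-rrn16_mt\t34756\tC\tT\tT
cox2-rrn16_mt\t34801\tA\tG\tG
cox2-rrn16_mt\t34866\t-\tT\tT
cox2-rrn16_mt\t34867\t-\tT\tT
cox2-rrn16_mt\t34870\t-\tA\tA
cox2-rrn16_mt\t34871\t-\tA\tA
cox2-rrn16_mt\t34880\tA\t-\t-
cox2-rrn16_mt\t34885\tA\t-\t-
cox2-rrn16_mt\t34898\tT\tC\tC
cox2-rrn16_mt\t34927\t-\tA\tA
cox2-rrn16_mt\t34934\tC\tT\tT
cox2-rrn16_mt\t34971\tG\tA\tA
cox2-rrn16_mt\t34995\tA\tA\tT
"""


def mlst_example_loci() -> list[MlstLocus]:
    return read_allele_table(MLST_ALLELE_TABLE, from_string=True)


# SSR panel: (motif as printed, total length, context, locus, organelle, strains)
SSR_PANEL_ROWS = [
    ("A", 10, "intergenic", "psbB-petF", "pt", ("IMET1", "CCMP531")),
    ("T", 10, "genic", "rps12", "pt", ("IMET1", "CCMP531")),
    ("T", 10, "intergenic", "rpl16-rps3", "pt", ("IMET1", "CCMP531")),
    ("A", 10, "intergenic", "secA-rpl34", "pt", ("IMET1", "CCMP531")),
    ("G", 14, "intergenic", "psbV-clpC", "pt", ("IMET1",)),
    ("TA", 14, "intergenic", "trnK(uuu)-trnG(gcc)", "pt", ("IMET1",)),
    ("T", 10, "intergenic", "tufA-rps7", "pt", ("CCMP531",)),
    ("T", 11, "genic", "coxI", "mt", ("IMET1", "CCMP531")),
    ("A", 11, "genic", "atp1", "mt", ("IMET1", "CCMP531")),
    ("A", 10, "intergenic", "orf321", "mt", ("IMET1", "CCMP531")),
    ("A", 10, "genic", "rpl14", "mt", ("IMET1", "CCMP531")),
    ("T", 10, "intergenic", "trnD(gtc)-trnG(tcc)", "mt", ("IMET1", "CCMP531")),
    ("A", 10, "genic", "rps13", "mt", ("IMET1", "CCMP531")),
    ("T", 10, "intergenic", "trnK(ttt)-nad4L", "mt", ("IMET1", "CCMP531")),
    ("A", 12, "genic", "rps3", "mt", ("CCMP531",)),
]


def ssr_example_loci() -> dict[str, list[SsrLocus]]:
    """Per-strain SSR locus lists for the two N. oceanica strains.

    Start coordinates are synthetic placeholders (the panel records motif,
    length, organelle and locus context, which is all the comparison keys on).
    """
    per_strain: dict[str, list[SsrLocus]] = {"IMET1": [], "CCMP531": []}
    for i, (motif, length, context, locus, organelle, strains) in enumerate(SSR_PANEL_ROWS):
        u = len(motif)
        start = 1000 * (i + 1)
        for s in strains:
            per_strain[s].append(
                SsrLocus(
                    genome=s, organelle=organelle, motif=canonical_rotation(motif),
                    unit_len=u, copies=length // u, total_len=(length // u) * u,
                    start=start, end=start + (length // u) * u - 1,
                    context=context, context_name=locus,
                )
            )
    return per_strain


# interspecies marker sensitivities (% nucleotide difference) and origins for
# the twelve proposed markers, the ITS2 baseline and a few presently used
# markers below it
MARKER_SENSITIVITY_ROWS = [
    ("rps14_mt", "mt", (297, 297), 37.71),
    ("ycf34", "pt", (252, 261), 33.72),
    ("rps14_mt-atp9", "mt", (102, 195), 32.83),
    ("rps4_mt", "mt", (726, 726), 32.09),
    ("rpl6_mt", "mt", (552, 552), 32.07),
    ("ycf34-psbD", "pt", (204, 224), 31.72),
    ("rpl5_mt", "mt", (525, 540), 31.67),
    ("clpA", "pt", (447, 450), 29.33),
    ("orf53", "mt", (156, 162), 29.01),
    ("rpl14_mt", "mt", (381, 381), 28.35),
    ("trnQ(uug)-groEL", "pt", (269, 274), 28.00),
    ("trnL(uag)-trnW(cca)", "pt", (648, 673), 27.99),
    ("ITS2", "nc", (385, 499), 27.67),
    ("rps2-rpoC2", "pt", (162, 193), 25.63),
    ("cox1", "mt", (1521, 1521), 17.55),
    ("cox2", "mt", (909, 909), 13.53),
    ("rbcL", "pt", (1464, 1464), 10.04),
    ("psbA", "pt", (1083, 1083), 4.16),
    ("18S", "nc", (1790, 1792), 2.51),
]


def marker_example_evaluations() -> list[MarkerEvaluation]:
    """Marker rows as consistent candidates, ready for rank_markers."""
    return [
        MarkerEvaluation(
            region_id=rid, origin=origin, size_range=size,
            pct_difference_interspecies=pct, consistent=True, n_members=7,
        )
        for rid, origin, size, pct in MARKER_SENSITIVITY_ROWS
    ]


# coding-region SNP partitions per organelle compartment across the genus
SNP_PARTITIONS = {
    "pt": {"n_transition": 6856, "n_transversion": 4871, "n_indel": 22},
    "mt": {"n_transition": 2985, "n_transversion": 1997, "n_indel": 8},
}


def snp_example_summary(compartment: str) -> SnpSummary:
    return SnpSummary.from_counts(**SNP_PARTITIONS[compartment])


# mean per-gene evolutionary rates by genome compartment (nuclear from an
# external genome comparison, organellar from the organelle gene set)
RATE_MEANS = {"pt": 0.031, "mt": 0.064, "nuclear": 0.093}
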