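"""Small curated worked-example datasets.

These encode the published endpoint of a three-generation familial
colorectal-cancer exome analysis: the two top-ranked coding candidates
(missense variants in *PTGES* and *SLC15A4*) with their reported annotation
scores, and the differential transcription-factor binding calls for the
*SLC15A4* upstream promoter variant. They serve as worked examples and
regression anchors for the cascade and the regulatory arm.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pwm import TFBSHit
from .simulate import make_pedigree
from .types import AnnotatedVariant, PedigreeRoles, ScorePanel


def crc_family_pedigree() -> PedigreeRoles:
    """The worked-example family: four affected siblings (III2..III5), one
    possible carrier (IV2, early-onset polyps), one healthy cousin control."""
    return make_pedigree(n_cases=4, n_controls=1, n_carriers=1)


def crc_family_top_variants() -> list[AnnotatedVariant]:
    """The two top coding candidates with their reported annotation values.

    CADD, GERP, PhyloP, PhastCons and the allele frequencies are the reported
    per-variant numbers. The per-tool categorical calls and raw intolerance
    scores were not itemized in the source table, which reports only the vote
    percentages; the panels below reconstruct score sets that realize exactly
    those percentages (PTGES: 3/4 intolerance criteria and 8/10 tools;
    SLC15A4: 4/4 and 9/10).
    """
    roles = crc_family_pedigree()
    seg = {s: "het" for s in roles.cases + roles.possible_carriers}
    seg.update({s: "hom_ref" for s in roles.controls})
    common = dict(
        genotypes=dict(seg),
        region_class="exonic",
        exonic_effect="missense",
        qual=60.0, depth=40, fwd_reads=12, rev_reads=11, caller_filter="PASS",
    )
    ptges = AnnotatedVariant(
        chrom="9", pos=132501952, ref="C", alt="T",
        gene="PTGES",
        pop_afs={
            "exac_nontcga_nfe": 2.10e-4,
            "gnomad_nfe": 8.43e-5,  # report-only population
        },
        scores=ScorePanel(
            cadd_phred=34.0, gerp=4.67, phylop=7.72, phastcons=1.0,
            # 3 of 4 intolerance criteria met (missense Z fails) -> 75%
            intolerance_scores={"local": -0.5, "esp6500": -0.3, "exac": -0.2},
            exac_z=-0.1,
            # 8 of 10 favorable tool calls -> 80%
            tool_predictions={
                "sift": "D", "pp2_humdiv": "D", "pp2_humvar": "P", "lrt": "D",
                "mutation_taster": "D", "mutation_assessor": "M",
                "fathmm": "T", "reliability_index": 4.0,
                "vest3": 0.74, "provean": "D",
            },
            snap2_effect=16.0, snap2_accuracy=59.0,
        ),
        **common,
    )
    slc15a4 = AnnotatedVariant(
        chrom="12", pos=129285482, ref="T", alt="C",
        gene="SLC15A4",
        pop_afs={"exac_nontcga_nfe": 0.0, "gnomad_nfe": 0.0},
        scores=ScorePanel(
            cadd_phred=23.7, gerp=5.49, phylop=5.60, phastcons=0.91,
            # all four intolerance criteria met -> 100%
            intolerance_scores={"local": -1.1, "esp6500": -0.9, "exac": -0.6},
            exac_z=2.3,
            # 9 of 10 favorable tool calls -> 90%
            tool_predictions={
                "sift": "D", "pp2_humdiv": "D", "pp2_humvar": "D", "lrt": "D",
                "mutation_taster": "D", "mutation_assessor": "H",
                "fathmm": "T", "reliability_index": 8.0,
                "vest3": 0.91, "provean": "D",
            },
            snap2_effect=44.0, snap2_accuracy=71.0,
        ),
        **common,
    )
    return [ptges, slc15a4]


def load_upstream_tfbs_demo() -> tuple[list[TFBSHit], list[TFBSHit]]:
    """Differential TFBS hit lists for the *SLC15A4* upstream C>T variant.

    Returns (wild-type exclusive hits, mutant exclusive hits) in window-local
    1-based coordinates, as reported for the promoter scan at the 80% relative
    profile score threshold. Several factors carry two matrix versions
    (STAT1, SCRT1, SCRT2) or hits on both strands (TGIF2LX/Y).
    """
    with resources.files("famvar.data").joinpath("slc15a4_upstream_tfbs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    wt, mut = [], []
    for row in df.itertuples(index=False):
        hit = TFBSHit(
            matrix_id=row.matrix_id, tf_name=row.tf_name,
            start=int(row.start), end=int(row.end), strand=row.strand,
            rel_score=float(row.rel_score), site_seq=row.site_seq,
        )
        (wt if row.targeting == "WT" else mut).append(hit)
    return wt, mut
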