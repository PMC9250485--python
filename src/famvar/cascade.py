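"""The coding-variant prioritization cascade.

After segregation filtering, coding candidates pass through, in order:

1. region split (coding vs near-gene non-coding vs discarded),
2. synonymous exclusion,
3. CADD PHRED >= 10 (the most deleterious ~10% of substitutions),
4. conservation vote: >= 2 of {GERP >= 2.0, PhastCons > 0.3, PhyloP >= 3.0},
5. intolerance vote: >= 60% of four gene-intolerance criteria,
6. deleteriousness vote: >= 60% of ten ensemble prediction tools.

Every stage is recorded in a funnel report. Missing scores count as failed
votes over fixed denominators by default, so reported percentages stay
directly comparable across variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import CascadeConfig
from .funnel import FunnelReport
from .types import CORE_TOOLS, AnnotatedVariant, ScorePanel

log = logging.getLogger(__name__)

CODING_REGIONS = frozenset({"exonic", "splicing"})
NEAR_GENE_REGIONS = frozenset({"UTR5", "UTR3", "upstream", "downstream"})
DISCARDED_REGIONS = frozenset({"intronic", "intergenic", "ncRNA"})

#: exonic effects retained after synonymous exclusion
DELETERIOUS_EFFECTS = frozenset({"missense", "stopgain", "stoploss", "frameshift"})
#: loss-of-function classes that use pLI as the class-specific intolerance criterion
LOF_EFFECTS = frozenset({"stopgain", "frameshift"})

_warned_tokens: set[str] = set()


@dataclass
class VoteResult:
    votes: int
    denominator: int
    passed: bool

    @property
    def fraction(self) -> float:
        return self.votes / self.denominator if self.denominator else 0.0


def split_by_region(
    variants: list[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition by region class into (coding, near-gene, discarded).

    Coding = exonic/splicing; near-gene = UTRs and up/downstream (fed to the
    regulatory arm); intronic, intergenic and ncRNA variants are discarded.
    """
    coding, near_gene, discarded = [], [], []
    unknown = sorted(
        {v.region_class for v in variants}
        - CODING_REGIONS - NEAR_GENE_REGIONS - DISCARDED_REGIONS
    , key=str)
    if unknown:
        raise ValueError(f"unknown region_class labels: {unknown}")
    for v in variants:
        if v.region_class in CODING_REGIONS:
            coding.append(v)
        elif v.region_class in NEAR_GENE_REGIONS:
            near_gene.append(v)
        else:
            discarded.append(v)
    return coding, near_gene, discarded


def exclude_synonymous(
    coding: list[AnnotatedVariant], keep_splicing: bool = True
) -> list[AnnotatedVariant]:
    """Drop synonymous variants; keep missense/nonsense/frameshift (and, by
    default, splicing-region variants, which carry no exonic effect)."""
    kept = []
    for v in coding:
        if v.region_class == "splicing":
            if keep_splicing:
                kept.append(v)
            continue
        if v.exonic_effect in DELETERIOUS_EFFECTS:
            kept.append(v)
    return kept


def conservation_vote(p: ScorePanel, cfg: CascadeConfig | None = None) -> VoteResult:
    """2-of-3 evolutionary conservation vote.

    GERP and PhyloP thresholds are inclusive (>=); PhastCons is strict (>).
    A missing score is a failed vote.
    """
    cfg = cfg or CascadeConfig()
    votes = sum([
        p.gerp is not None and p.gerp >= cfg.gerp_min,
        p.phastcons is not None and p.phastcons > cfg.phastcons_min_exclusive,
        p.phylop is not None and p.phylop >= cfg.phylop_min,
    ])
    return VoteResult(votes, 3, votes >= cfg.conservation_votes_needed)


def _intolerance_criteria(
    p: ScorePanel, effect: str | None, region_class: str | None
) -> list[bool | None]:
    """Four criteria; ``None`` marks 'undefined for this variant class'."""
    def neg(key: str) -> bool:
        v = p.intolerance_scores.get(key)
        return v is not None and v < 0

    crits: list[bool | None] = [neg("local"), neg("esp6500"), neg("exac")]
    if effect == "missense":
        crits.append(p.exac_z is not None and p.exac_z > 0)
    elif effect in LOF_EFFECTS or region_class == "splicing":
        crits.append(p.exac_pli is not None and p.exac_pli >= 0.9)
    else:
        crits.append(None)
    return crits


def intolerance_vote(
    p: ScorePanel,
    effect: str | None,
    cfg: CascadeConfig | None = None,
    region_class: str | None = None,
) -> VoteResult:
    """Gene-intolerance vote: three residual-variation intolerance scores
    (negative = intolerant) plus a class-specific fourth criterion — ExAC
    missense Z > 0 for missense variants, pLI >= 0.9 for loss-of-function
    and splicing variants.

    Default mode scores over a fixed denominator of 4 (undefined or missing
    criteria count as failed); ``denominator='available'`` shrinks the
    denominator to the criteria defined for the variant class.
    """
    cfg = cfg or CascadeConfig()
    crits = _intolerance_criteria(p, effect, region_class)
    if cfg.denominator == "available":
        defined = [c for c in crits if c is not None]
        denom = len(defined) or 1
        votes = sum(defined)
    else:
        denom = 4
        votes = sum(bool(c) for c in crits)
    return VoteResult(votes, denom, votes / denom >= cfg.intolerance_fraction)


#: per-tool favorable-prediction predicates (categorical letters per the
#: dbNSFP conventions; Reliability Index and VEST3 are numeric)
TOOL_PREDICATES: dict[str, callable] = {
    "sift": lambda x: x == "D",
    "pp2_humdiv": lambda x: x in ("D", "P"),
    "pp2_humvar": lambda x: x in ("D", "P"),
    "lrt": lambda x: x == "D",
    "mutation_taster": lambda x: x in ("D", "A"),
    "mutation_assessor": lambda x: x in ("H", "M"),
    "fathmm": lambda x: x == "D",
    "reliability_index": lambda x: float(x) >= 5,
    "vest3": lambda x: float(x) >= 0.5,
    "provean": lambda x: x == "D",
    # accepted but excluded from the default ten-tool vote
    "metasvm": lambda x: x == "D",
    "metalr": lambda x: x == "D",
}

_CATEGORICAL_TOKENS = frozenset("DPATNHMLU") | {"B", "."}


def _tool_passes(tool: str, value: object) -> bool:
    try:
        return bool(TOOL_PREDICATES[tool](value))
    except (TypeError, ValueError):
        token = f"{tool}:{value}"
        if token not in _warned_tokens:
            _warned_tokens.add(token)
            log.warning("unrecognized prediction %r for %s counted as fail", value, tool)
        return False


def deleteriousness_vote(
    p: ScorePanel, cfg: CascadeConfig | None = None, tools: tuple[str, ...] = CORE_TOOLS
) -> VoteResult:
    """Ensemble deleteriousness vote over the ten prediction tools.

    A tool votes 'deleterious' per its own favorable-call predicate; missing
    predictions fail. MetaSVM/MetaLR are parsed upstream but excluded from the
    default tool set so the ten-tool percentage stays interpretable.
    """
    cfg = cfg or CascadeConfig()
    if cfg.denominator == "available":
        present = [t for t in tools if t in p.tool_predictions]
        denom = len(present) or 1
        votes = sum(_tool_passes(t, p.tool_predictions[t]) for t in present)
    else:
        denom = len(tools)
        votes = sum(
            t in p.tool_predictions and _tool_passes(t, p.tool_predictions[t])
            for t in tools
        )
    return VoteResult(votes, denom, votes / denom >= cfg.deleteriousness_fraction)


def passes_cascade(v: AnnotatedVariant, cfg: CascadeConfig | None = None) -> bool:
    """Order-free conjunction of all cascade predicates for one variant."""
    cfg = cfg or CascadeConfig()
    if v.region_class not in CODING_REGIONS:
        return False
    if v.region_class == "splicing":
        if not cfg.keep_splicing:
            return False
    elif v.exonic_effect not in DELETERIOUS_EFFECTS:
        return False
    sc = v.scores
    if sc.cadd_phred is None or sc.cadd_phred < cfg.cadd_min:
        return False
    return (
        conservation_vote(sc, cfg).passed
        and intolerance_vote(sc, v.exonic_effect, cfg, v.region_class).passed
        and deleteriousness_vote(sc, cfg).passed
    )


def run_coding_cascade(
    variants: list[AnnotatedVariant], cfg: CascadeConfig | None = None
) -> tuple[list[AnnotatedVariant], FunnelReport]:
    """Run the staged cascade with funnel accounting.

    Input is assumed to be quality/MAF/segregation-filtered already. Survivors
    are sorted by CADD descending, then variant id.
    """
    cfg = cfg or CascadeConfig()
    report = FunnelReport()
    ids = lambda vs: [v.variant_id for v in vs]  # noqa: E731

    coding, near_gene, _ = split_by_region(variants)
    report.add("region_split_coding", ids(variants), ids(coding))
    if near_gene:
        log.info("%d near-gene non-coding variants routed to the regulatory arm", len(near_gene))

    nonsyn = exclude_synonymous(coding, cfg.keep_splicing)
    report.add("exclude_synonymous", ids(coding), ids(nonsyn))

    cadd = [
        v for v in nonsyn
        if v.scores.cadd_phred is not None and v.scores.cadd_phred >= cfg.cadd_min
    ]
    report.add("cadd", ids(nonsyn), ids(cadd))

    cons = [v for v in cadd if conservation_vote(v.scores, cfg).passed]
    report.add("conservation", ids(cadd), ids(cons))

    intol = [
        v for v in cons
        if intolerance_vote(v.scores, v.exonic_effect, cfg, v.region_class).passed
    ]
    report.add("intolerance", ids(cons), ids(intol))

    delet = [v for v in intol if deleteriousness_vote(v.scores, cfg).passed]
    report.add("deleteriousness", ids(intol), ids(delet))

    survivors = sorted(
        delet, key=lambda v: (-(v.scores.cadd_phred or 0.0), v.variant_id)
    )
    return survivors, report
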