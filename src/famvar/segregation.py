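"""Pre-filters and pedigree segregation.

Call quality and rarity are filtered per variant; the segregation filter then
keeps only variants whose genotype pattern matches the family's disease
pattern under a dominant model: carried by every case, absent from every
control, with "possible carriers" (e.g. a polyp-bearing descendant) left
unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .funnel import FunnelStage
from .types import HET, HOM_ALT, HOM_REF, MISSING, AnnotatedVariant, PedigreeRoles

log = logging.getLogger(__name__)


@dataclass
class SegregationRule:
    """How the family genotype pattern is matched.

    Defaults: every case must carry the allele (het or hom-alt), every control
    must be hom-ref, possible carriers are unconstrained.
    """

    require_in_cases: str = "all"  # "all" | "any"
    forbid_in_controls: bool = True
    min_carrier_genotype: str = HET  # het counts as carrying (dominant model)
    missing_case_genotype: str = "strict"  # strict = drop | permissive = keep

    def __post_init__(self) -> None:
        if self.require_in_cases not in ("all", "any"):
            raise ValueError("require_in_cases must be 'all' or 'any'")
        if self.min_carrier_genotype not in (HET, HOM_ALT):
            raise ValueError("min_carrier_genotype must be het or hom_alt")
        if self.missing_case_genotype not in ("strict", "permissive"):
            raise ValueError("missing_case_genotype must be 'strict' or 'permissive'")

    def counts_as_carrier(self, gt: str) -> bool:
        if self.min_carrier_genotype == HOM_ALT:
            return gt == HOM_ALT
        return gt in (HET, HOM_ALT)


def quality_filter(
    v: AnnotatedVariant, min_qual: float = 20.0, min_depth: int = 5
) -> tuple[bool, str | None]:
    """Call-quality gate: PHRED quality, coverage, strand support, caller flags.

    SNVs need at least one supporting read on each strand (strand-bias guard);
    indels must carry the caller's PASS flag. Returns (passed, failure reason).
    """
    if v.qual is None or v.depth is None:
        return False, "missing_quality"
    if v.qual < min_qual:
        return False, "low_qual"
    if v.depth < min_depth:
        return False, "low_depth"
    if v.variant_class == "SNV":
        if not v.fwd_reads or not v.rev_reads:
            return False, "strand_bias"
    else:  # insertion / deletion
        if v.caller_filter != "PASS":
            return False, "caller_filter"
    return True, None


def maf_filter(
    v: AnnotatedVariant, populations: list[str], max_af: float = 0.001
) -> bool:
    """Rarity gate: allele frequency <= ``max_af`` in *every* listed population.

    A population absent from the variant's AF map is treated as frequency 0
    (the variant is unobserved there), so missing columns never block a rare
    variant.
    """
    if not 0.0 < max_af < 1.0:
        raise ValueError(f"max_af must lie in (0,1), got {max_af}")
    return all(v.pop_afs.get(pop, 0.0) <= max_af for pop in populations)


def segregates(
    v: AnnotatedVariant, roles: PedigreeRoles, rule: SegregationRule | None = None
) -> tuple[bool, str | None]:
    """Per-variant segregation predicate. Returns (kept, drop reason)."""
    rule = rule or SegregationRule()
    for sid in roles.cases + roles.controls:
        if sid not in v.genotypes:
            raise KeyError(f"sample {sid!r} from pedigree missing in genotype map of {v.variant_id}")
    case_gts = [v.genotypes[s] for s in roles.cases]
    if any(g == MISSING for g in case_gts):
        if rule.missing_case_genotype == "strict":
            return False, "missing_case_gt"
        case_gts = [g for g in case_gts if g != MISSING]
    carried = [rule.counts_as_carrier(g) for g in case_gts]
    if rule.require_in_cases == "all":
        if not all(carried):
            return False, "case_noncarrier"
    elif not any(carried):
        return False, "no_case_carrier"
    if rule.forbid_in_controls:
        for s in roles.controls:
            if v.genotypes[s] != HOM_REF:
                return False, "control_carrier"
    return True, None


def segregation_filter(
    variants: list[AnnotatedVariant],
    roles: PedigreeRoles,
    rule: SegregationRule | None = None,
) -> tuple[list[AnnotatedVariant], FunnelStage]:
    """Apply :func:`segregates` across a variant list, with funnel accounting."""
    roles.require_cases_and_controls()
    rule = rule or SegregationRule()
    kept = [v for v in variants if segregates(v, roles, rule)[0]]
    stage = FunnelStage(
        "segregation", len(variants), len(kept), [v.variant_id for v in kept]
    )
    return kept, stage


def relatedness_matrix(
    variants: list[AnnotatedVariant], roles: PedigreeRoles
) -> "np.ndarray":
    """Pairwise sample relatedness as Jaccard similarity of carrier sets.

    Entry (i, j) = |carriers(i) & carriers(j)| / |carriers(i) | carriers(j)|
    over the supplied (rare) variants; a sample carrying no variant gets 0
    against everything, including itself, with a warning. Intended as the
    sample-swap / relatedness sanity check, not a formal kinship estimate.
    """
    ids = roles.sample_ids
    if len(ids) < 2:
        raise ValueError("relatedness requires at least 2 samples")
    carrier_sets = {
        s: {v.variant_id for v in variants if v.is_carrier(s)} for s in ids
    }
    n = len(ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(ids):
        if not carrier_sets[a]:
            log.warning("sample %s carries no variants; relatedness set to 0", a)
        for j, b in enumerate(ids):
            union = carrier_sets[a] | carrier_sets[b]
            if union:
                mat[i, j] = len(carrier_sets[a] & carrier_sets[b]) / len(union)
    return mat
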