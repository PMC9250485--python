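"""Deterministic synthetic cohorts, promoters and motifs.

The study's sequencing data are protected, so this module generates data
with the same structure the pipeline assumes: a six-sample pedigree (four
affected siblings, one possible carrier, one healthy control), a rare-variant
table on the scale of the real cohort (~11k rare variants) with annotation
scores drawn from documented background distributions, *planted* variants
engineered to survive — or fail at a chosen stage of — the cascade, and toy
promoter sequences with planted motifs whose disruption by a planted SNV is
verified at generation time.

All randomness flows through one seeded generator; the same seed yields
byte-identical outputs. Background distributions are testability choices,
not reported cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cascade as _cascade
from .pwm import PWM, pwm_scan, reverse_complement
from .segregation import SegregationRule, maf_filter, quality_filter, segregates
from .types import (
    ALPHABET,
    HET,
    HOM_REF,
    AnnotatedVariant,
    PedigreeRoles,
    PedigreeSample,
    PFMRecord,
    ScorePanel,
)

#: stages at which a planted variant may be made to fail, in pipeline order
PLANT_STAGES = (
    "quality", "maf", "segregation", "region", "synonymous",
    "cadd", "conservation", "intolerance", "deleteriousness",
)

FILTER_POPULATIONS = ("thousand_genomes_eur", "exac_nontcga_nfe", "esp6500", "local")


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with a prescribed fate.

    ``fail_stage=None`` plants a full survivor; otherwise the variant is
    engineered to be eliminated at exactly that stage (scores just inside or
    outside each threshold). Stages after the first failure are unreachable,
    which is why the profile is a single stage rather than a set.
    """

    fail_stage: str | None = None
    gene: str = "PLANTED"

    def __post_init__(self) -> None:
        if self.fail_stage is not None and self.fail_stage not in PLANT_STAGES:
            raise ValueError(
                f"unrealizable plant profile: unknown stage {self.fail_stage!r} "
                f"(known: {PLANT_STAGES})"
            )


@dataclass
class SimConfig:
    """Cohort generator settings.

    Defaults emulate the study conditions: 4 cases / 1 possible carrier /
    1 control and 11,076 rare variants. ``carrier_prob`` is the i.i.d.
    per-sample heterozygous-carrier probability of background variants;
    background score distributions are documented in the methods note.
    """

    seed: int = 0
    n_variants: int = 11_076
    n_cases: int = 4
    n_controls: int = 1
    n_carriers: int = 1
    planted: list[PlantedVariant] = field(default_factory=list)
    carrier_prob: float = 0.3
    af_log10_range: tuple[float, float] = (-6.0, -2.0)
    cadd_deleterious_frac: float = 0.1
    tool_damaging_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.n_variants < len(self.planted):
            raise ValueError("n_variants must cover the planted variants")
        if not 0.0 < self.carrier_prob < 1.0:
            raise ValueError("carrier_prob must lie in (0,1)")


def make_pedigree(n_cases: int = 4, n_controls: int = 1, n_carriers: int = 1) -> PedigreeRoles:
    """Family roles in the study layout: affected siblings III2..III5, the
    possible carrier IV2 (child of III2), and a healthy cousin as control."""
    samples = [
        PedigreeSample(f"III{i + 2}", "II1", "II2", "0", "case")
        for i in range(n_cases)
    ]
    samples += [
        PedigreeSample(f"IV{i + 2}", "III2", "0", "0", "possible_carrier")
        for i in range(n_carriers)
    ]
    samples += [
        PedigreeSample(f"III{n_cases + 2 + i}", "II3", "II4", "0", "control")
        for i in range(n_controls)
    ]
    return PedigreeRoles(samples)


_TOOL_TOKENS = {
    "sift": ("D", "T"),
    "pp2_humdiv": ("D", "B"),
    "pp2_humvar": ("P", "B"),
    "lrt": ("D", "N"),
    "mutation_taster": ("D", "N"),
    "mutation_assessor": ("M", "L"),
    "fathmm": ("D", "T"),
    "provean": ("D", "N"),
}


def _background_panel(rng: np.random.Generator, cfg: SimConfig) -> ScorePanel:
    if rng.random() < cfg.cadd_deleterious_frac:
        cadd = rng.uniform(10.0, 40.0)
    else:
        cadd = rng.uniform(0.0, 10.0)
    tools: dict[str, object] = {}
    for tool, (dam, benign) in _TOOL_TOKENS.items():
        tools[tool] = dam if rng.random() < cfg.tool_damaging_prob else benign
    tools["reliability_index"] = float(rng.integers(0, 11))
    tools["vest3"] = float(rng.uniform(0.0, 1.0))
    return ScorePanel(
        cadd_phred=float(cadd),
        gerp=float(rng.normal(0.0, 2.5)),
        phastcons=float(rng.beta(0.4, 0.6)),
        phylop=float(rng.normal(0.0, 2.0)),
        intolerance_scores={
            k: float(rng.normal(0.0, 1.0)) for k in ("local", "esp6500", "exac")
        },
        exac_z=float(rng.normal(0.0, 1.5)),
        exac_pli=float(rng.beta(0.2, 0.8)),
        tool_predictions=tools,
    )


def _passing_panel() -> ScorePanel:
    """Scores comfortably inside every cascade threshold (10/10 tools)."""
    return ScorePanel(
        cadd_phred=25.0, gerp=5.0, phastcons=0.9, phylop=4.5,
        intolerance_scores={"local": -1.0, "esp6500": -1.2, "exac": -0.8},
        exac_z=1.5, exac_pli=0.95,
        tool_predictions={
            "sift": "D", "pp2_humdiv": "D", "pp2_humvar": "P", "lrt": "D",
            "mutation_taster": "A", "mutation_assessor": "H", "fathmm": "D",
            "provean": "D", "reliability_index": 9.0, "vest3": 0.8,
        },
    )


def _segregating_genotypes(roles: PedigreeRoles) -> dict[str, str]:
    gts = {s: HET for s in roles.cases + roles.possible_carriers}
    gts.update({s: HOM_REF for s in roles.controls})
    return gts


def _realize_plant(
    plant: PlantedVariant, roles: PedigreeRoles, index: int
) -> AnnotatedVariant:
    pos = 1_000_000 + index  # reserved coordinate block, disjoint from background
    v = AnnotatedVariant(
        chrom="20",
        pos=pos,
        ref="A",
        alt="G",
        genotypes=_segregating_genotypes(roles),
        region_class="exonic",
        exonic_effect="missense",
        gene=plant.gene,
        qual=60.0, depth=30, fwd_reads=10, rev_reads=10, caller_filter="PASS",
        pop_afs={p: 1e-5 for p in FILTER_POPULATIONS},
        scores=_passing_panel(),
    )
    stage = plant.fail_stage
    if stage == "quality":
        v.qual = 10.0
    elif stage == "maf":
        v.pop_afs["local"] = 0.01
    elif stage == "segregation":
        v.genotypes[roles.controls[0]] = HET
    elif stage == "region":
        v.region_class = "intronic"
        v.exonic_effect = "NA"
    elif stage == "synonymous":
        v.exonic_effect = "synonymous"
    elif stage == "cadd":
        v.scores.cadd_phred = 9.99
    elif stage == "conservation":
        # exactly one of three votes: GERP passes, the rest fail
        v.scores.gerp = 2.5
        v.scores.phastcons = 0.2
        v.scores.phylop = 1.0
    elif stage == "intolerance":
        # 2 of 4 criteria < the 60% bar
        v.scores.intolerance_scores = {"local": -1.0, "esp6500": -1.0, "exac": 0.5}
        v.scores.exac_z = -1.0
    elif stage == "deleteriousness":
        # 5 of 10 favorable calls < the 60% bar
        v.scores.tool_predictions.update(
            {"sift": "T", "pp2_humdiv": "B", "pp2_humvar": "B",
             "lrt": "N", "mutation_taster": "N"}
        )
    _verify_plant(v, plant, roles)
    return v


def _verify_plant(v: AnnotatedVariant, plant: PlantedVariant, roles: PedigreeRoles) -> None:
    """Check at generation time that the variant's fate matches its profile."""
    stage = plant.fail_stage

    def expect(cond: bool, at: str) -> None:
        should_pass = stage != at
        if cond != should_pass:
            raise RuntimeError(
                f"planted variant {v.variant_id} does not realize profile "
                f"fail_stage={stage!r} at stage {at!r}"
            )

    expect(quality_filter(v)[0], "quality")
    expect(maf_filter(v, list(FILTER_POPULATIONS)), "maf")
    expect(segregates(v, roles, SegregationRule())[0], "segregation")
    expect(v.region_class in _cascade.CODING_REGIONS, "region")
    if v.region_class in _cascade.CODING_REGIONS:
        expect(bool(exclude := v.exonic_effect in _cascade.DELETERIOUS_EFFECTS), "synonymous")
        if exclude:
            sc = v.scores
            expect(sc.cadd_phred is not None and sc.cadd_phred >= 10.0, "cadd")
            expect(_cascade.conservation_vote(sc).passed, "conservation")
            expect(
                _cascade.intolerance_vote(sc, v.exonic_effect, region_class=v.region_class).passed,
                "intolerance",
            )
            expect(_cascade.deleteriousness_vote(sc).passed, "deleteriousness")


_REGION_CHOICES = (
    ("exonic", 0.45), ("intronic", 0.25), ("intergenic", 0.10),
    ("UTR5", 0.04), ("UTR3", 0.04), ("upstream", 0.05), ("downstream", 0.04),
    ("ncRNA", 0.03),
)
_EFFECT_CHOICES = (("missense", 0.55), ("synonymous", 0.40), ("stopgain", 0.05))


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[PedigreeRoles, list[AnnotatedVariant], pd.DataFrame]:
    """Generate (pedigree, annotated variant table, truth table).

    Planted variants realize their profiles exactly (verified at generation);
    background rows are i.i.d. draws from the documented distributions. The
    truth table records each variant's intended fate.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = make_pedigree(cfg.n_cases, cfg.n_controls, cfg.n_carriers)
    sample_ids = roles.sample_ids

    variants: list[AnnotatedVariant] = []
    truth_rows: list[dict] = []
    for i, plant in enumerate(cfg.planted):
        v = _realize_plant(plant, roles, i)
        variants.append(v)
        truth_rows.append({
            "variant_id": v.variant_id, "planted": True,
            "fail_stage": plant.fail_stage or "",
            "expected_survivor": plant.fail_stage is None,
        })

    n_bg = cfg.n_variants - len(cfg.planted)
    region_names = [r for r, _ in _REGION_CHOICES]
    region_p = np.array([p for _, p in _REGION_CHOICES])
    effect_names = [e for e, _ in _EFFECT_CHOICES]
    effect_p = np.array([p for _, p in _EFFECT_CHOICES])
    lo10, hi10 = cfg.af_log10_range
    # strictly increasing positions guarantee unique variant ids
    positions = 2_000_000 + np.cumsum(rng.integers(1, 1000, size=max(n_bg, 1)))
    for i in range(n_bg):
        region = str(rng.choice(region_names, p=region_p))
        effect = str(rng.choice(effect_names, p=effect_p)) if region == "exonic" else "NA"
        ref, alt = rng.choice(list(ALPHABET), size=2, replace=False)
        gts = {
            s: (HET if rng.random() < cfg.carrier_prob else HOM_REF)
            for s in sample_ids
        }
        v = AnnotatedVariant(
            chrom=str(rng.integers(1, 23)),
            pos=int(positions[i]),
            ref=str(ref), alt=str(alt),
            genotypes=gts,
            region_class=region,
            exonic_effect=effect,
            gene=f"GENE{i % 997}",
            qual=float(rng.uniform(10.0, 90.0)),
            depth=int(rng.poisson(30)) + 1,
            fwd_reads=int(rng.integers(0, 20)),
            rev_reads=int(rng.integers(0, 20)),
            caller_filter="PASS" if rng.random() < 0.9 else "badReads",
            pop_afs={
                p: float(10 ** rng.uniform(lo10, hi10)) for p in FILTER_POPULATIONS
            },
            scores=_background_panel(rng, cfg),
        )
        variants.append(v)
        truth_rows.append({
            "variant_id": v.variant_id, "planted": False, "fail_stage": "",
            "expected_survivor": _cascade.passes_cascade(v)
            and segregates(v, roles)[0]
            and maf_filter(v, list(FILTER_POPULATIONS))
            and quality_filter(v)[0],
        })
    return roles, variants, pd.DataFrame(truth_rows)


# -- promoter / motif simulation ---------------------------------------------


@dataclass
class PromoterSimConfig:
    """Toy promoter with one planted motif and the SNV that disrupts it."""

    seed: int = 0
    length: int = 130
    chrom: str = "12"
    window_start: int = 129_308_459  # 1-based genomic anchor of the window
    motif_length: int = 10
    offset: int | None = None  # 0-based plant offset; None = centered
    strand: str = "+"
    peak_count: float = 97.0
    n_decoy_pfms: int = 2
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.motif_length > self.length:
            raise ValueError("motif longer than promoter")


def _sharp_pfm(rng: np.random.Generator, matrix_id: str, tf: str,
               length: int, peak: float) -> PFMRecord:
    counts = np.full((4, length), 1.0)
    for j in range(length):
        counts[rng.integers(0, 4), j] = peak
    return PFMRecord(matrix_id, tf, counts)


def _planted_pfm(rng: np.random.Generator, matrix_id: str, tf: str,
                 length: int, sharp_col: int, sharp_count: float,
                 mild_count: float = 4.0) -> PFMRecord:
    """Motif whose information content concentrates in one column.

    Losing a single column of a uniformly sharp motif costs only 1/L of the
    score range, which a 0.8 relative threshold never notices; concentrating
    the counts in ``sharp_col`` makes one substitution there drop the best
    attainable relative score well below the threshold.
    """
    counts = np.full((4, length), 1.0)
    for j in range(length):
        counts[rng.integers(0, 4), j] = sharp_count if j == sharp_col else mild_count
    return PFMRecord(matrix_id, tf, counts)


def simulate_promoter(
    cfg: PromoterSimConfig,
) -> tuple[str, AnnotatedVariant, list[PFMRecord], dict]:
    """Generate (wild-type sequence, disrupting SNV, PFM set, truth).

    The wild-type sequence carries the planted PFM's consensus at the chosen
    offset; the SNV sits at a maximum-information motif column and swaps the
    consensus base for the least-favored one. Generation verifies that the
    planted TF scores >= threshold on the wild type and < threshold everywhere
    on the mutant; if a random background spoils this the generator retries
    with a sharper matrix, then errors.
    """
    rng = np.random.default_rng(cfg.seed)
    peak = cfg.peak_count
    for attempt in range(4):
        pfm = _planted_pfm(
            rng, "SYN0001.1", "SYNTF1", cfg.motif_length,
            sharp_col=cfg.motif_length // 2, sharp_count=peak,
        )
        seq = "".join(rng.choice(list(ALPHABET), size=cfg.length))
        offset = cfg.offset if cfg.offset is not None else (cfg.length - cfg.motif_length) // 2
        planted_site = pfm.consensus()
        if cfg.strand == "-":
            planted_site = reverse_complement(planted_site)
        wt = seq[:offset] + planted_site + seq[offset + cfg.motif_length:]

        # disrupt the central (maximum-information) motif column
        col = cfg.motif_length // 2
        weak_base = ALPHABET[int(pfm.counts[:, col].argmin())]
        site_pos = (
            offset + col if cfg.strand == "+"
            else offset + cfg.motif_length - 1 - col
        )
        ref_base = wt[site_pos]
        alt_base = weak_base if cfg.strand == "+" else reverse_complement(weak_base)
        if alt_base == ref_base:  # least-favored equals consensus complement clash
            alt_base = next(b for b in ALPHABET if b != ref_base)
        mut = wt[:site_pos] + alt_base + wt[site_pos + 1:]

        pwm = PWM(pfm)
        wt_ok = any(h.rel_score >= cfg.threshold for h in pwm_scan(wt, pwm, cfg.threshold))
        mut_ok = not pwm_scan(mut, pwm, cfg.threshold)
        if wt_ok and mut_ok:
            break
        peak *= 2.0  # sharpen and retry
    else:
        raise RuntimeError("planted mutation failed to cross the score threshold")

    decoys = [
        _sharp_pfm(rng, f"SYN{i + 2:04d}.1", f"SYNTF{i + 2}", cfg.motif_length, 5.0)
        for i in range(cfg.n_decoy_pfms)
    ]
    roles = make_pedigree()
    variant = AnnotatedVariant(
        chrom=cfg.chrom,
        pos=cfg.window_start + site_pos,
        ref=ref_base,
        alt=alt_base,
        genotypes=_segregating_genotypes(roles),
        region_class="upstream",
        exonic_effect="NA",
        gene="SYNGENE",
        qual=60.0, depth=30, fwd_reads=10, rev_reads=10, caller_filter="PASS",
        pop_afs={p: 0.0 for p in FILTER_POPULATIONS},
        scores=ScorePanel(cadd_phred=12.0),
    )
    truth = {
        "planted_tf": pfm.tf_name,
        "expected_wt_only": {pfm.tf_name},
        "plant_offset": offset,
        "disrupted_column": cfg.motif_length // 2,
        "strand": cfg.strand,
    }
    return wt, variant, [pfm] + decoys, truth
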