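"""Core domain types shared across the pipeline.

The pipeline operates on variants that have already been called and annotated
upstream (aligner, caller, ANNOVAR/dbNSFP/CADD-style annotators); everything
here models the *annotated* variant, the family structure that drives
segregation filtering, and the genomic/motif primitives used by the regulatory
arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# -- genotype encoding --------------------------------------------------------

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

#: tokens accepted for each canonical genotype (annotator dialects vary)
GENOTYPE_ALIASES: dict[str, str] = {
    "0/0": HOM_REF, "0|0": HOM_REF, "ref": HOM_REF, "hom_ref": HOM_REF,
    "0/1": HET, "1/0": HET, "0|1": HET, "1|0": HET, "het": HET,
    "1/1": HOM_ALT, "1|1": HOM_ALT, "hom": HOM_ALT, "hom_alt": HOM_ALT,
    "./.": MISSING, ".|.": MISSING, ".": MISSING, "na": MISSING,
    "missing": MISSING,
}

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})
REGION_CLASSES = frozenset({
    "exonic", "splicing", "UTR5", "UTR3", "upstream", "downstream",
    "intronic", "intergenic", "ncRNA",
})
EXONIC_EFFECTS = frozenset({
    "synonymous", "missense", "stopgain", "stoploss", "frameshift",
    "nonframeshift", "unknown", "NA",
})

ROLES = frozenset({"case", "control", "possible_carrier", "unknown"})

#: the ten ensemble deleteriousness tools that enter the default vote
CORE_TOOLS = (
    "sift", "pp2_humdiv", "pp2_humvar", "lrt", "mutation_taster",
    "mutation_assessor", "fathmm", "reliability_index", "vest3", "provean",
)
#: parsed when present, excluded from the default 10-tool vote
EXTRA_TOOLS = ("metasvm", "metalr")
RECOGNIZED_TOOLS = frozenset(CORE_TOOLS) | frozenset(EXTRA_TOOLS)


def parse_genotype(token: str) -> str:
    """Map an annotator genotype token to the canonical encoding.

    Unrecognized tokens are treated as missing rather than raising: a single
    odd cell should not abort a whole-cohort run.
    """
    return GENOTYPE_ALIASES.get(str(token).strip().lower(), MISSING)


def infer_variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV"
    return "insertion" if len(ref) < len(alt) else "deletion"


@dataclass
class ScorePanel:
    """Per-variant annotation scores consumed by the coding cascade.

    All fields are optional (``None`` = not annotated); the voting operations
    treat a missing score as a failed vote so that the denominators stay fixed.
    ``tool_predictions`` maps a tool id from :data:`RECOGNIZED_TOOLS` to the
    categorical letter or numeric value the annotator emitted.
    """

    cadd_phred: float | None = None
    gerp: float | None = None
    phastcons: float | None = None
    phylop: float | None = None
    intolerance_scores: dict[str, float | None] = field(default_factory=dict)
    exac_z: float | None = None
    exac_pli: float | None = None
    tool_predictions: dict[str, object] = field(default_factory=dict)
    snap2_effect: float | None = None
    snap2_accuracy: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.tool_predictions) - RECOGNIZED_TOOLS
        if unknown:
            raise ValueError(f"unrecognized tool ids: {sorted(unknown)}")
        if self.exac_pli is not None and not 0.0 <= self.exac_pli <= 1.0:
            raise ValueError(f"pLI must lie in [0,1], got {self.exac_pli}")
        if self.phastcons is not None and not 0.0 <= self.phastcons <= 1.0:
            raise ValueError(f"PhastCons must lie in [0,1], got {self.phastcons}")


@dataclass
class AnnotatedVariant:
    """One annotated variant row: identity, genotypes, call quality, allele
    frequencies and the score panel."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, str]
    variant_class: str | None = None
    region_class: str | None = None
    exonic_effect: str | None = None
    gene: str | None = None
    qual: float | None = None
    depth: int | None = None
    fwd_reads: int | None = None
    rev_reads: int | None = None
    caller_filter: str | None = None
    pop_afs: dict[str, float] = field(default_factory=dict)
    scores: ScorePanel = field(default_factory=ScorePanel)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.genotypes:
            raise ValueError("genotypes map must be non-empty")
        if self.variant_class is None:
            self.variant_class = infer_variant_class(self.ref, self.alt)
        elif self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        for gt in self.genotypes.values():
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype token {gt!r}")
        for pop, af in self.pop_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"AF for {pop} outside [0,1]: {af}")

    @property
    def variant_id(self) -> str:
        """Identifier in ``chrom_pos_ref_alt`` convention, e.g. 12_129285482_T_C."""
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    def is_carrier(self, sample_id: str) -> bool:
        """Dominant-model presence: het or hom-alt counts as carrying."""
        return self.genotypes.get(sample_id, MISSING) in (HET, HOM_ALT)


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: str = "0"
    role: str = "unknown"


@dataclass
class PedigreeRoles:
    """Family samples labeled by the role they play in segregation filtering."""

    samples: list[PedigreeSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in pedigree")
        for s in self.samples:
            if s.role not in ROLES:
                raise ValueError(f"unknown role {s.role!r} for {s.sample_id}")

    def by_role(self, role: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == role]

    @property
    def cases(self) -> list[str]:
        return self.by_role("case")

    @property
    def controls(self) -> list[str]:
        return self.by_role("control")

    @property
    def possible_carriers(self) -> list[str]:
        return self.by_role("possible_carrier")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def require_cases_and_controls(self) -> None:
        if not self.cases or not self.controls:
            raise ValueError(
                "segregation filtering requires at least one case and one "
                f"control (found {len(self.cases)} cases, {len(self.controls)} controls)"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED-native internally; user-facing
    output converts to 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_position(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


ALPHABET = ("A", "C", "G", "T")


@dataclass
class PFMRecord:
    """A position frequency matrix (counts over A,C,G,T per motif column)."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"counts must be 4xL, got shape {self.counts.shape}")
        if self.counts.shape[1] < 1:
            raise ValueError("motif length must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("negative counts in PFM")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError(f"{self.matrix_id}: column with all-zero counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))
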