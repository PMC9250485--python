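"""The non-coding (regulatory) arm.

Near-gene variants are intersected with regulatory-element tracks (promoters,
enhancers, super-enhancers), joined with precomputed chromatin-state
annotations (ChromHMM / Segway, consumed as inputs), and — where a covering
sequence is available — the wild-type and mutant alleles of the surrounding
window are scanned against a PFM library to call transcription factors whose
predicted binding is disrupted (wild-type-only) or created (mutant-only) by
the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .config import PipelineConfig
from .pwm import PWM, TFBSHit, pwm_scan
from .types import AnnotatedVariant, GenomicInterval, PFMRecord

log = logging.getLogger(__name__)

CHROMHMM_STATES = frozenset({
    "TssA", "TssAFInk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
})


@dataclass
class RegulatoryAnnotation:
    """Chromatin context of one variant: overlapping regulatory elements plus
    precomputed chromatin-state fields copied from the annotation table."""

    chromhmm_state: str | None = None
    chromhmm_score: float | None = None
    segway_label: str | None = None
    overlapping_elements: list[GenomicInterval] = field(default_factory=list)
    tfbs_count: int | None = None
    tfbs_peak_count: int | None = None

    def __post_init__(self) -> None:
        if self.chromhmm_score is not None and not 0.0 <= self.chromhmm_score <= 1.0:
            raise ValueError(f"chromhmm_score outside [0,1]: {self.chromhmm_score}")
        if self.chromhmm_state is not None and self.chromhmm_state not in CHROMHMM_STATES:
            raise ValueError(f"unknown ChromHMM state {self.chromhmm_state!r}")


@dataclass
class SequenceRegion:
    """A genomically anchored sequence window (e.g. a promoter FASTA record
    whose header carries ``chrom:start-end``, 1-based inclusive)."""

    name: str
    chrom: str
    start_1based: int
    seq: str

    @property
    def end_1based(self) -> int:
        return self.start_1based + len(self.seq) - 1

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_1based <= pos <= self.end_1based


def annotate_regulatory(
    v: AnnotatedVariant,
    tracks: dict[str, list[GenomicInterval]],
    state_table: dict[str, dict] | None = None,
) -> RegulatoryAnnotation:
    """Interval-intersect one variant against regulatory-element tracks and
    join the precomputed chromatin-state row for it.

    ``state_table`` maps variant id to a dict with any of chromhmm_state,
    chromhmm_score, segway_label, tfbs_count, tfbs_peak_count. A track on a
    different chromosome naming scheme yields an empty overlap with a warning.
    """
    overlaps: list[GenomicInterval] = []
    for track_name, intervals in tracks.items():
        chroms = {iv.chrom for iv in intervals}
        if intervals and v.chrom not in chroms:
            log.warning(
                "track %s has no intervals on chromosome %s (naming mismatch?)",
                track_name, v.chrom,
            )
            continue
        tree = IntervalTree()
        for iv in intervals:
            if iv.chrom == v.chrom:
                tree.addi(iv.start, iv.end, iv)
        overlaps.extend(
            hit.data
            for hit in sorted(
                tree.at(v.pos - 1), key=lambda h: (h.begin, h.end, h.data.name)
            )
        )
    row = (state_table or {}).get(v.variant_id, {})
    return RegulatoryAnnotation(
        chromhmm_state=row.get("chromhmm_state"),
        chromhmm_score=row.get("chromhmm_score"),
        segway_label=row.get("segway_label"),
        overlapping_elements=overlaps,
        tfbs_count=row.get("tfbs_count"),
        tfbs_peak_count=row.get("tfbs_peak_count"),
    )


def build_mutant_sequence(
    wt: str, window_start: int, v: AnnotatedVariant
) -> str:
    """Substitute an SNV into a sequence window (``window_start`` is the
    1-based genomic position of the window's first base).

    The reference base at the variant offset is checked against the variant's
    REF allele; a mismatch raises, guarding against off-by-one and strand
    errors in window construction.
    """
    if v.variant_class != "SNV":
        raise ValueError(f"{v.variant_id}: only SNVs are supported for mutant windows")
    offset = v.pos - window_start
    if not 0 <= offset < len(wt):
        raise ValueError(f"{v.variant_id}: position outside the window")
    observed = wt[offset].upper()
    if observed != v.ref.upper():
        raise ValueError(
            f"{v.variant_id}: reference mismatch at window offset {offset}: "
            f"expected {v.ref}, observed {observed}"
        )
    return wt[:offset] + v.alt.upper() + wt[offset + 1:]


@dataclass
class DifferentialTFBSResult:
    """TF-level partition of predicted binding between two alleles."""

    wt_only: set[str]
    mut_only: set[str]
    shared: set[str]
    hits_wt: list[TFBSHit]
    hits_mut: list[TFBSHit]

    @property
    def n_affected(self) -> int:
        """TFs predicted to bind exactly one of the two sequences."""
        return len(self.wt_only) + len(self.mut_only)


def differential_tfbs(
    hits_wt: list[TFBSHit], hits_mut: list[TFBSHit]
) -> DifferentialTFBSResult:
    """Compare hit lists from the same window/threshold at the TF level.

    The grouping key is the TF name, so a factor represented by several
    matrix versions (e.g. two STAT1 matrices) counts once; a TF with any hit
    on both sequences is shared.
    """
    tfs_wt = {h.tf_name for h in hits_wt}
    tfs_mut = {h.tf_name for h in hits_mut}
    return DifferentialTFBSResult(
        wt_only=tfs_wt - tfs_mut,
        mut_only=tfs_mut - tfs_wt,
        shared=tfs_wt & tfs_mut,
        hits_wt=list(hits_wt),
        hits_mut=list(hits_mut),
    )


@dataclass
class NoncodingVariantReport:
    variant_id: str
    annotation: RegulatoryAnnotation
    cadd_flag: bool
    differential: DifferentialTFBSResult | None


def run_noncoding(
    near_gene: list[AnnotatedVariant],
    tracks: dict[str, list[GenomicInterval]],
    state_table: dict[str, dict] | None,
    sequences: list[SequenceRegion],
    pfms: list[PFMRecord],
    cfg: PipelineConfig | None = None,
) -> list[NoncodingVariantReport]:
    """Full regulatory analysis of the near-gene variants.

    Per variant: regulatory-element overlaps, chromatin-state join, a CADD
    flag (same >= 10 cutoff as the coding arm), and — for SNVs with a covering
    sequence — wild-type vs mutant PWM scans of the variant +/- flank window
    and the TF-level differential. Variants without a covering sequence keep
    their annotation row but no TFBS comparison.
    """
    cfg = cfg or PipelineConfig()
    pwms = [PWM(p, pseudocount=cfg.pwm_pseudocount) for p in pfms]
    reports: list[NoncodingVariantReport] = []
    for v in near_gene:
        ann = annotate_regulatory(v, tracks, state_table)
        cadd_flag = (
            v.scores.cadd_phred is not None and v.scores.cadd_phred >= cfg.cascade.cadd_min
        )
        region = next((s for s in sequences if s.covers(v.chrom, v.pos)), None)
        diff = None
        if region is None:
            log.warning("%s: no covering sequence; TFBS comparison skipped", v.variant_id)
        elif v.variant_class == "SNV":
            lo = max(region.start_1based, v.pos - cfg.scan_flank)
            hi = min(region.end_1based, v.pos + cfg.scan_flank)
            wt = region.seq[lo - region.start_1based: hi - region.start_1based + 1]
            mut = build_mutant_sequence(wt, lo, v)
            hits_wt: list[TFBSHit] = []
            hits_mut: list[TFBSHit] = []
            for pwm in pwms:
                hits_wt.extend(pwm_scan(wt, pwm, cfg.pwm_threshold))
                hits_mut.extend(pwm_scan(mut, pwm, cfg.pwm_threshold))
            diff = differential_tfbs(hits_wt, hits_mut)
        reports.append(NoncodingVariantReport(v.variant_id, ann, cadd_flag, diff))
    return reports


def differential_table_rows(result: DifferentialTFBSResult) -> list[dict]:
    """Flatten a differential result into report rows (one per exclusive hit):
    TF, targeting (WT/MUT), matrix id, relative score, start, end, strand,
    predicted sequence."""
    rows = []
    for targeting, hits, tfset in (
        ("WT", result.hits_wt, result.wt_only),
        ("MUT", result.hits_mut, result.mut_only),
    ):
        for h in sorted(hits, key=lambda h: (h.tf_name, h.matrix_id, h.start, h.strand)):
            if h.tf_name in tfset:
                rows.append({
                    "tf_name": h.tf_name, "targeting": targeting,
                    "matrix_id": h.matrix_id, "rel_score": round(h.rel_score, 2),
                    "start": h.start, "end": h.end, "strand": h.strand,
                    "site_seq": h.site_seq,
                })
    return rows


def read_region_fasta(path, default_chrom: str | None = None) -> list[SequenceRegion]:
    """Read FASTA records whose headers carry a ``chrom:start-end`` anchor
    (1-based inclusive), e.g. ``>SLC15A4_promoter 12:129308487-129308588``.

    Records without an anchor are admitted at position 1 of ``default_chrom``
    (or their own name) so plain FASTA still works for window-local analyses.
    """
    from Bio import SeqIO

    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has length 0")
        chrom, start = default_chrom or rec.id, 1
        for tok in rec.description.split()[1:]:
            if ":" in tok and "-" in tok.split(":", 1)[1]:
                c, span = tok.split(":", 1)
                a, b = span.split("-", 1)
                try:
                    lo, hi = int(a.replace(",", "")), int(b.replace(",", ""))
                except ValueError:
                    continue
                if hi - lo + 1 != len(seq):
                    raise ValueError(
                        f"{rec.id}: anchored span length {hi - lo + 1} != sequence length {len(seq)}"
                    )
                chrom, start = c, lo
                break
        regions.append(SequenceRegion(rec.id, chrom, start, seq))
    return regions
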