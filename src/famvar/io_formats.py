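"""Readers and writers for the external formats the pipeline touches.

TSV variant tables, PED-like pedigrees with a role column, BED tracks,
FASTA, and JASPAR-style position frequency matrices. All coordinate
conversion happens here: BED stays 0-based half-open internally and
everything user-facing is 1-based inclusive.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .funnel import read_funnel_report, write_funnel_report  # noqa: F401  (re-export)
from .types import (
    ALPHABET,
    AnnotatedVariant,
    GenomicInterval,
    PedigreeRoles,
    PedigreeSample,
    PFMRecord,
    RECOGNIZED_TOOLS,
    ScorePanel,
    parse_genotype,
)

log = logging.getLogger(__name__)

MISSING_TOKENS = {"", ".", "na", "nan", "none"}

#: canonical numeric score columns -> ScorePanel destination
SCORE_COLUMNS = (
    "cadd_phred", "gerp", "phastcons", "phylop",
    "intol_local", "intol_esp6500", "intol_exac",
    "exac_z", "exac_pli", "snap2_effect", "snap2_accuracy",
)
NUMERIC_TOOLS = {"reliability_index", "vest3"}


@dataclass
class TableDialect:
    """Column registry for the annotated variant TSV.

    ``column_map`` renames external headers to canonical names before any other
    processing; genotype columns are ``<genotype_prefix><sample_id>`` and
    allele-frequency columns ``<af_prefix><population_id>``. Tool prediction
    columns are named by tool id (``sift``, ``pp2_humdiv``, ...).
    """

    column_map: dict[str, str] = field(default_factory=dict)
    genotype_prefix: str = "gt_"
    af_prefix: str = "af_"


def _is_missing(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return True
    return str(cell).strip().lower() in MISSING_TOKENS


def _opt_float(cell: object, bad_counter: list) -> float | None:
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        bad_counter.append(cell)
        return None


def _opt_int(cell: object) -> int | None:
    if _is_missing(cell):
        return None
    return int(float(cell))


def read_variant_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[AnnotatedVariant]:
    """Read an annotated variant TSV into :class:`AnnotatedVariant` records.

    Required columns: chrom, pos, ref, alt and at least one genotype column.
    Score columns are optional; unparseable score cells become missing values
    (counted and logged). Row order is preserved.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=dialect.column_map)

    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"variant table is missing required column {col!r}")
    gt_cols = [c for c in df.columns if c.startswith(dialect.genotype_prefix)]
    if not gt_cols:
        raise ValueError(
            f"variant table has no genotype columns (prefix {dialect.genotype_prefix!r})"
        )
    af_cols = [c for c in df.columns if c.startswith(dialect.af_prefix)]
    tool_cols = [c for c in df.columns if c in RECOGNIZED_TOOLS]

    bad_cells: list = []
    variants: list[AnnotatedVariant] = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        intol = {
            "local": _opt_float(r.get("intol_local"), bad_cells),
            "esp6500": _opt_float(r.get("intol_esp6500"), bad_cells),
            "exac": _opt_float(r.get("intol_exac"), bad_cells),
        }
        tools: dict[str, object] = {}
        for c in tool_cols:
            if _is_missing(r[c]):
                continue
            tools[c] = _opt_float(r[c], bad_cells) if c in NUMERIC_TOOLS else str(r[c]).strip()
            if tools[c] is None:
                del tools[c]
        panel = ScorePanel(
            cadd_phred=_opt_float(r.get("cadd_phred"), bad_cells),
            gerp=_opt_float(r.get("gerp"), bad_cells),
            phastcons=_opt_float(r.get("phastcons"), bad_cells),
            phylop=_opt_float(r.get("phylop"), bad_cells),
            intolerance_scores=intol,
            exac_z=_opt_float(r.get("exac_z"), bad_cells),
            exac_pli=_opt_float(r.get("exac_pli"), bad_cells),
            tool_predictions=tools,
            snap2_effect=_opt_float(r.get("snap2_effect"), bad_cells),
            snap2_accuracy=_opt_float(r.get("snap2_accuracy"), bad_cells),
        )
        variants.append(
            AnnotatedVariant(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref=str(r["ref"]).upper(),
                alt=str(r["alt"]).upper(),
                genotypes={
                    c[len(dialect.genotype_prefix):]: parse_genotype(r[c]) for c in gt_cols
                },
                variant_class=None if _is_missing(r.get("variant_class")) else r["variant_class"],
                region_class=None if _is_missing(r.get("region_class")) else r["region_class"],
                exonic_effect=None if _is_missing(r.get("exonic_effect")) else r["exonic_effect"],
                gene=None if _is_missing(r.get("gene")) else r["gene"],
                qual=_opt_float(r.get("qual"), bad_cells),
                depth=_opt_int(r.get("depth")),
                fwd_reads=_opt_int(r.get("fwd_reads")),
                rev_reads=_opt_int(r.get("rev_reads")),
                caller_filter=None if _is_missing(r.get("caller_filter")) else r["caller_filter"],
                pop_afs={
                    c[len(dialect.af_prefix):]: float(r[c])
                    for c in af_cols
                    if not _is_missing(r[c])
                },
                scores=panel,
            )
        )
    ids = [v.variant_id for v in variants]
    dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise ValueError(f"duplicate variant ids in table: {dupes}")
    if bad_cells:
        log.warning("%d unparseable score cells treated as missing", len(bad_cells))
    return variants


def write_variant_table(
    variants: list[AnnotatedVariant], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Inverse of :func:`read_variant_table`; missing values written as '.'."""
    dialect = dialect or TableDialect()
    samples: list[str] = []
    pops: list[str] = []
    tools: list[str] = []
    for v in variants:
        for s in v.genotypes:
            if s not in samples:
                samples.append(s)
        for p in v.pop_afs:
            if p not in pops:
                pops.append(p)
        for t in v.scores.tool_predictions:
            if t not in tools:
                tools.append(t)

    def cell(x: object) -> str:
        return "." if x is None else (repr(x) if isinstance(x, float) else str(x))

    rows = []
    for v in variants:
        row: dict[str, str] = {
            "chrom": v.chrom, "pos": str(v.pos), "ref": v.ref, "alt": v.alt,
            "variant_class": cell(v.variant_class),
            "region_class": cell(v.region_class),
            "exonic_effect": cell(v.exonic_effect),
            "gene": cell(v.gene),
            "qual": cell(v.qual), "depth": cell(v.depth),
            "fwd_reads": cell(v.fwd_reads), "rev_reads": cell(v.rev_reads),
            "caller_filter": cell(v.caller_filter),
        }
        for s in samples:
            row[dialect.genotype_prefix + s] = v.genotypes.get(s, "missing")
        for p in pops:
            af = v.pop_afs.get(p)
            row[dialect.af_prefix + p] = "." if af is None else repr(af)
        sc = v.scores
        row.update({
            "cadd_phred": cell(sc.cadd_phred), "gerp": cell(sc.gerp),
            "phastcons": cell(sc.phastcons), "phylop": cell(sc.phylop),
            "intol_local": cell(sc.intolerance_scores.get("local")),
            "intol_esp6500": cell(sc.intolerance_scores.get("esp6500")),
            "intol_exac": cell(sc.intolerance_scores.get("exac")),
            "exac_z": cell(sc.exac_z), "exac_pli": cell(sc.exac_pli),
            "snap2_effect": cell(sc.snap2_effect),
            "snap2_accuracy": cell(sc.snap2_accuracy),
        })
        for t in tools:
            row[t] = cell(sc.tool_predictions.get(t))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


ROLE_ALIASES = {
    "case": "case", "affected": "case", "2": "case",
    "control": "control", "unaffected": "control", "healthy": "control",
    "1": "control",
    "possible_carrier": "possible_carrier", "carrier": "possible_carrier",
    "possible": "possible_carrier",
    "unknown": "unknown", "0": "unknown",
}


def read_pedigree(path: str | Path) -> PedigreeRoles:
    """Read a PED-like whitespace table with a 7th role column.

    Columns: family, sample, father, mother, sex, phenotype, role. Role tokens
    are alias-mapped (``affected`` -> case, ...); unrecognized tokens become
    ``unknown`` with a warning. Raises if no case or no control is present,
    since segregation filtering would be undefined.
    """
    samples = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"pedigree line {lineno}: expected 7 columns, got {len(parts)}")
        _fam, sid, father, mother, sex, _pheno, role_token = parts[:7]
        role = ROLE_ALIASES.get(role_token.strip().lower())
        if role is None:
            log.warning("pedigree line %d: unknown role token %r -> unknown", lineno, role_token)
            role = "unknown"
        samples.append(PedigreeSample(sid, father, mother, sex, role))
    roles = PedigreeRoles(samples)
    roles.require_cases_and_controls()
    return roles


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file, keeping coordinates 0-based half-open."""
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
        name = parts[3] if len(parts) > 3 else "."
        strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
        intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return intervals


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{record id: uppercased sequence}``; empty records raise."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has length 0")
        out[rec.id] = seq
    return out


_JASPAR_ROW = re.compile(r"^\s*([ACGT])?\s*\[?\s*([0-9.\s]+?)\s*\]?\s*$")


def read_jaspar_pfm(path: str | Path) -> list[PFMRecord]:
    """Parse JASPAR-format position frequency matrices.

    Accepts both the bracketed 2020 dialect (``A  [ 0  3 79 ... ]``) and bare
    4-row count matrices in A,C,G,T order, under ``>MATRIX_ID TF_NAME``
    headers. Ragged matrices raise a format error.
    """
    records: list[PFMRecord] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush() -> None:
        nonlocal rows, order
        if header is None:
            return
        if len(order) != 4:
            raise ValueError(f"{header[0]}: expected 4 matrix rows, got {len(order)}")
        lengths = {len(rows[b]) for b in order}
        if len(lengths) != 1:
            raise ValueError(f"{header[0]}: ragged matrix rows (lengths {sorted(lengths)})")
        counts = np.array([rows[b] for b in ALPHABET])
        records.append(PFMRecord(header[0], header[1], counts))
        rows, order = {}, []

    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            toks = line[1:].replace("\t", " ").split(None, 1)
            header = (toks[0], toks[1].strip() if len(toks) > 1 else toks[0])
            continue
        if header is None:
            raise ValueError("matrix rows before any '>' header")
        m = _JASPAR_ROW.match(line)
        if not m:
            raise ValueError(f"{header[0]}: unparseable matrix row {line!r}")
        base = m.group(1) or ALPHABET[len(order)]
        if base in rows:
            raise ValueError(f"{header[0]}: duplicate row for base {base}")
        rows[base] = [float(x) for x in m.group(2).split()]
        order.append(base)
    flush()
    return records
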