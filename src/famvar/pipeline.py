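"""End-to-end orchestration and the run manifest.

``run_all`` chains the pre-filters (quality, rarity), the segregation filter,
the coding cascade and — when tracks/sequences/PFMs are supplied — the
regulatory arm, producing one funnel report covering every stage plus
tabular outputs and a manifest that makes the run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cascade import run_coding_cascade
from .config import PipelineConfig
from .funnel import FunnelReport, write_funnel_report
from .io_formats import write_variant_table
from .regulatory import NoncodingVariantReport, differential_table_rows, run_noncoding
from .segregation import SegregationRule, maf_filter, quality_filter, segregation_filter
from .types import AnnotatedVariant, PedigreeRoles

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    seed: int | None
    config: dict
    input_digests: dict[str, str]
    stage_timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunResult:
    survivors: list[AnnotatedVariant]
    funnel: FunnelReport
    noncoding: list[NoncodingVariantReport]
    manifest: RunManifest


def run_all(
    variants: list[AnnotatedVariant],
    roles: PedigreeRoles,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    tracks: dict | None = None,
    state_table: dict | None = None,
    sequences: list | None = None,
    pfms: list | None = None,
    seed: int | None = None,
    input_digests: dict[str, str] | None = None,
) -> RunResult:
    """Run the whole pipeline; deterministic given inputs and seed.

    An empty survivor set is a valid outcome (logged as a warning), not an
    error. When ``out_dir`` is given, writes funnel.json, top_coding.tsv,
    noncoding_report.tsv and manifest.json.
    """
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}
    funnel = FunnelReport()
    ids = lambda vs: [v.variant_id for v in vs]  # noqa: E731

    t0 = time.perf_counter()
    qual_kept = [v for v in variants if quality_filter(v, cfg.min_qual, cfg.min_depth)[0]]
    funnel.add("quality", ids(variants), ids(qual_kept))
    timings["quality"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rare = [v for v in qual_kept if maf_filter(v, cfg.filter_populations, cfg.max_af)]
    funnel.add("maf", ids(qual_kept), ids(rare))
    timings["maf"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rule = SegregationRule(missing_case_genotype=cfg.missing_case_genotype)
    seg_kept, seg_stage = segregation_filter(rare, roles, rule)
    funnel.stages.append(seg_stage)
    timings["segregation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    survivors, cascade_funnel = run_coding_cascade(seg_kept, cfg.cascade)
    funnel.stages.extend(cascade_funnel.stages)
    timings["coding_cascade"] = time.perf_counter() - t0

    noncoding_reports: list[NoncodingVariantReport] = []
    if tracks is not None or sequences is not None or pfms is not None:
        t0 = time.perf_counter()
        from .cascade import split_by_region

        _, near_gene, _ = split_by_region(seg_kept)
        noncoding_reports = run_noncoding(
            near_gene, tracks or {}, state_table, sequences or [], pfms or [], cfg
        )
        timings["noncoding"] = time.perf_counter() - t0

    for s in funnel.stages:
        log.info("stage %-22s %6d -> %6d", s.name, s.n_in, s.n_out)
    if not survivors:
        log.warning("no coding variant survived the full cascade")

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config=dataclasses.asdict(cfg),
        input_digests=input_digests or {},
        stage_timings=timings,
    )
    result = RunResult(survivors, funnel, noncoding_reports, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_funnel_report(funnel, out_dir / "funnel.json")
        write_variant_table(survivors, out_dir / "top_coding.tsv")
        rows = []
        for rep in noncoding_reports:
            if rep.differential is None:
                rows.append({"variant_id": rep.variant_id, "tf_name": "", "targeting": ""})
                continue
            for r in differential_table_rows(rep.differential):
                rows.append({"variant_id": rep.variant_id, **r})
        pd.DataFrame(rows).to_csv(out_dir / "noncoding_report.tsv", sep="\t", index=False)
        manifest.write(out_dir / "manifest.json")
    return result
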