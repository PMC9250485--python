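"""Funnel accounting: per-stage survivor counts and ids.

Every filtering stage appends a :class:`FunnelStage`; the resulting
:class:`FunnelReport` is the machine-readable analogue of the usual
filtering-funnel figure in a prioritization study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    surviving_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.name}: n_out {self.n_out} > n_in {self.n_in}")
        if len(self.surviving_ids) != self.n_out:
            raise ValueError(f"stage {self.name}: id list length != n_out")


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, name: str, input_ids: list[str], surviving_ids: list[str]) -> FunnelStage:
        stage = FunnelStage(name, len(input_ids), len(surviving_ids), list(surviving_ids))
        if self.stages and self.stages[-1].surviving_ids != list(input_ids):
            raise ValueError(
                f"stage {name}: input ids do not match previous stage's survivors"
            )
        self.stages.append(stage)
        return stage

    @property
    def counts(self) -> list[int]:
        return [s.n_out for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "surviving_ids": s.surviving_ids,
                }
                for s in self.stages
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunnelReport":
        rep = cls()
        for s in d["stages"]:
            rep.stages.append(
                FunnelStage(s["name"], s["n_in"], s["n_out"], list(s["surviving_ids"]))
            )
        return rep


def write_funnel_report(report: FunnelReport, path: str | Path) -> None:
    """Serialize a funnel as JSON (``.json``) or TSV (anything else).

    The TSV form holds one row per stage with a comma-joined id list; JSON is
    the lossless round-trip format.
    """
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(), indent=1) + "\n")
        return
    lines = ["stage\tn_in\tn_out\tsurviving_ids"]
    for s in report.stages:
        lines.append(f"{s.name}\t{s.n_in}\t{s.n_out}\t{','.join(s.surviving_ids)}")
    path.write_text("\n".join(lines) + "\n")


def read_funnel_report(path: str | Path) -> FunnelReport:
    path = Path(path)
    if path.suffix == ".json":
        return FunnelReport.from_dict(json.loads(path.read_text()))
    rep = FunnelReport()
    lines = path.read_text().splitlines()
    for line in lines[1:]:
        name, n_in, n_out, ids = line.split("\t")
        id_list = ids.split(",") if ids else []
        rep.stages.append(FunnelStage(name, int(n_in), int(n_out), id_list))
    return rep
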