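"""Pipeline configuration: score thresholds, vote fractions, population lists.

Defaults encode the published cascade cutoffs: CADD PHRED >= 10,
GERP >= 2.0 / PhastCons > 0.3 / PhyloP >= 3.0 with 2-of-3 required,
>= 60% of four intolerance criteria, >= 60% of ten deleteriousness tools,
MAF <= 0.1% in every filtering population.

Config files are TOML; unknown keys are hard errors so a mistyped threshold
cannot silently fall back to a default.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass
class CascadeConfig:
    cadd_min: float = 10.0
    gerp_min: float = 2.0
    phastcons_min_exclusive: float = 0.3
    phylop_min: float = 3.0
    conservation_votes_needed: int = 2
    intolerance_fraction: float = 0.6
    deleteriousness_fraction: float = 0.6
    # "fixed": missing score = failed vote over the full denominator (default);
    # "available": denominators shrink to the scores actually present
    denominator: str = "fixed"
    keep_splicing: bool = True

    def __post_init__(self) -> None:
        for name in ("intolerance_fraction", "deleteriousness_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1], got {v}")
        if not 0 <= self.conservation_votes_needed <= 3:
            raise ValueError("conservation_votes_needed must be 0..3")
        if self.denominator not in ("fixed", "available"):
            raise ValueError(f"denominator must be 'fixed' or 'available', got {self.denominator!r}")

    @property
    def intolerance_votes_needed(self) -> int:
        """ceil(fraction * 4): with the default 60% this is 3 of 4."""
        return math.ceil(self.intolerance_fraction * 4)

    @property
    def deleteriousness_votes_needed(self) -> int:
        """ceil(fraction * 10): with the default 60% this is 6 of 10."""
        return math.ceil(self.deleteriousness_fraction * 10)


@dataclass
class PipelineConfig:
    """Full run configuration: cascade thresholds plus the pre-filters."""

    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    min_qual: float = 20.0
    min_depth: int = 5
    max_af: float = 0.001
    #: ordered allele-frequency columns used for the rarity filter; report-only
    #: populations (e.g. gnomAD NFE) are carried through but never filtered on
    filter_populations: list[str] = field(default_factory=lambda: [
        "thousand_genomes_eur", "exac_nontcga_nfe", "esp6500", "local",
    ])
    missing_case_genotype: str = "strict"  # strict = drop variant, permissive = keep
    pwm_threshold: float = 0.8
    pwm_pseudocount: float = 0.8
    scan_flank: int = 60

    def __post_init__(self) -> None:
        if not 0.0 < self.max_af < 1.0:
            raise ValueError(f"max_af must lie in (0,1), got {self.max_af}")
        if not 0.0 < self.pwm_threshold <= 1.0:
            raise ValueError(f"pwm_threshold must lie in (0,1], got {self.pwm_threshold}")
        if self.missing_case_genotype not in ("strict", "permissive"):
            raise ValueError("missing_case_genotype must be 'strict' or 'permissive'")


def _apply_section(obj, section: dict, path: str):
    known = {f.name for f in fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return replace(obj, **section)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a TOML config file into a :class:`PipelineConfig`.

    Layout: top-level keys map to PipelineConfig fields; a ``[cascade]`` table
    maps to CascadeConfig. Unknown keys anywhere raise ``ValueError``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cascade_raw = raw.pop("cascade", {})
    cfg = _apply_section(PipelineConfig(), raw, "top level")
    cfg = replace(cfg, cascade=_apply_section(CascadeConfig(), cascade_raw, "[cascade]"))
    return cfg
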