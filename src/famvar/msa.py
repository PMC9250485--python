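"""Ortholog-alignment conservation checks around a mutation site.

Consumes an already-aligned protein FASTA (gap character '-'), maps an
ungapped residue position of the human reference row to its alignment column,
and reports whether the mutated position is universally conserved plus the
windowed percent identity of the surrounding region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

GAP = "-"


@dataclass
class ProteinMSA:
    names: list[str]
    rows: list[str]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(widths)}")
        ref = self.rows[self.reference_index]
        if not ref.replace(GAP, ""):
            raise ValueError("reference row is empty")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> str:
        return self.rows[self.reference_index]


def read_msa(path: str | Path, reference: str | int = 0) -> ProteinMSA:
    """Load an aligned FASTA; ``reference`` selects the human row by name or index."""
    aln = AlignIO.read(str(path), "fasta")
    names = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    ref_idx = names.index(reference) if isinstance(reference, str) else reference
    return ProteinMSA(names, rows, ref_idx)


def column_of_residue(msa: ProteinMSA, reference_position: int) -> int:
    """Alignment column (1-based) holding the reference row's Nth ungapped
    residue, so a protein change like p.Y444C can be located in the MSA."""
    if reference_position < 1:
        raise ValueError("reference_position is 1-based")
    count = 0
    for col, aa in enumerate(msa.reference, start=1):
        if aa != GAP:
            count += 1
            if count == reference_position:
                return col
    raise ValueError(
        f"position {reference_position} beyond ungapped reference length {count}"
    )


def is_position_conserved(msa: ProteinMSA, column: int) -> bool:
    """True iff every non-gap residue in the column is identical (and at
    least one non-gap residue exists)."""
    if not 1 <= column <= msa.n_columns:
        raise ValueError(f"column {column} outside alignment of width {msa.n_columns}")
    residues = {row[column - 1] for row in msa.rows} - {GAP}
    return len(residues) == 1


def window_identity(
    msa: ProteinMSA, column: int, flank: int = 5, scheme: str = "reference"
) -> float:
    """Percent identity of the window ``column +/- flank`` (clipped to the
    alignment), as a mean over ortholog rows of the fraction of window columns
    identical to the reference; a gap in either sequence counts as mismatch.

    ``scheme='all_pairs'`` averages over all unordered row pairs instead.
    """
    if not 1 <= column <= msa.n_columns:
        raise ValueError(f"column {column} outside alignment of width {msa.n_columns}")
    if len(msa.rows) < 2:
        raise ValueError("percent identity undefined for a single-sequence alignment")
    lo = max(1, column - flank) - 1
    hi = min(msa.n_columns, column + flank)
    width = hi - lo

    def pair_identity(a: str, b: str) -> float:
        same = sum(
            1 for x, y in zip(a[lo:hi], b[lo:hi]) if x == y and x != GAP
        )
        return same / width

    if scheme == "reference":
        ref = msa.reference
        others = [r for i, r in enumerate(msa.rows) if i != msa.reference_index]
        return 100.0 * sum(pair_identity(ref, r) for r in others) / len(others)
    if scheme == "all_pairs":
        vals = [
            pair_identity(msa.rows[i], msa.rows[j])
            for i in range(len(msa.rows))
            for j in range(i + 1, len(msa.rows))
        ]
        return 100.0 * sum(vals) / len(vals)
    raise ValueError(f"unknown scheme {scheme!r}")
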