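"""Position-weight-matrix scanning with JASPAR-style relative scoring.

A position frequency matrix is converted to log2 odds against a uniform
background with a pseudocount, and every window of a sequence is scored on
both strands. The *relative score* min-max normalizes the raw log-odds sum
into [0, 1] over the matrix's own score range, so a hit threshold of 0.8
means "within the top 20% of what this motif can score"; 1.0 is attained
exactly by a per-column-maximal sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ALPHABET, PFMRecord

_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Log-odds scoring matrix derived from a PFM.

    Column probabilities use a total pseudocount distributed by the background
    (JASPAR-convention default 0.8, uniform background 0.25 per base); odds are
    log base 2 against the same background.
    """

    source: PFMRecord
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        counts = self.source.counts
        probs = (counts + self.pseudocount * self.background[:, None]) / (
            counts.sum(axis=0) + self.pseudocount
        )
        self.log_odds = np.log2(probs / self.background[:, None])
        self.col_min = self.log_odds.min(axis=0)
        self.col_max = self.log_odds.max(axis=0)
        self.score_min = float(self.col_min.sum())
        self.score_max = float(self.col_max.sum())
        if not self.score_min < self.score_max:
            raise ValueError(f"{self.source.matrix_id}: degenerate score range")

    @property
    def length(self) -> int:
        return self.source.length

    def raw_score(self, window: str) -> float:
        """Sum of log-odds for one window (must match the motif length)."""
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != motif length {self.length}")
        return float(sum(self.log_odds[_INDEX[b], j] for j, b in enumerate(window)))

    def relative_score(self, window: str) -> float:
        return (self.raw_score(window) - self.score_min) / (self.score_max - self.score_min)


@dataclass(frozen=True)
class TFBSHit:
    """One predicted binding site, in 1-based inclusive window coordinates.

    Minus-strand hits are scored on the reverse complement but reported in
    plus-strand coordinates of the scanned window.
    """

    matrix_id: str
    tf_name: str
    start: int
    end: int
    strand: str
    rel_score: float
    site_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.site_seq):
            raise ValueError("hit span does not match site sequence length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def pwm_scan(
    seq: str,
    pwm: PWM,
    threshold: float = 0.8,
    both_strands: bool = True,
) -> list[TFBSHit]:
    """Scan a sequence for motif hits at or above a relative-score threshold.

    Windows containing N are skipped. Hits are returned sorted by (start,
    strand). Lowering the threshold can only add hits, never remove one.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0,1], got {threshold}")
    seq = seq.upper()
    L = pwm.length
    n = len(seq)
    if n < L:
        return []

    # vectorized window scoring over an integer-encoded sequence
    enc = np.full(n, -1, dtype=np.int64)
    for b, i in _INDEX.items():
        enc[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    valid_base = enc >= 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    usable = np.lib.stride_tricks.sliding_window_view(valid_base, L).all(axis=1)
    span = pwm.score_max - pwm.score_min

    def scores_for(lo: np.ndarray) -> np.ndarray:
        cols = np.arange(L)
        raw = np.where(usable, lo[np.clip(windows, 0, 3), cols].sum(axis=1), -np.inf)
        return (raw - pwm.score_min) / span

    hits: list[TFBSHit] = []
    rel_fwd = scores_for(pwm.log_odds)
    for off in np.nonzero(rel_fwd >= threshold)[0]:
        hits.append(TFBSHit(
            pwm.source.matrix_id, pwm.source.tf_name,
            int(off) + 1, int(off) + L, "+",
            float(rel_fwd[off]), seq[off:off + L],
        ))
    if both_strands:
        # scoring the reverse complement of each window == scanning with the
        # reverse-complemented matrix in plus-strand orientation
        lo_rc = pwm.log_odds[::-1, ::-1]
        rel_rev = scores_for(lo_rc)
        for off in np.nonzero(rel_rev >= threshold)[0]:
            hits.append(TFBSHit(
                pwm.source.matrix_id, pwm.source.tf_name,
                int(off) + 1, int(off) + L, "-",
                float(rel_rev[off]), reverse_complement(seq[off:off + L]),
            ))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
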