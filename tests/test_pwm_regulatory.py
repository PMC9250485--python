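"""PWM scanning and the regulatory arm: exhaustive and library oracles,
strand symmetry, interval intersection, differential TFBS grouping."""

import itertools

import numpy as np
import pytest
from conftest import make_variant

from famvar.io_formats import read_bed
from famvar.pwm import PWM, TFBSHit, pwm_scan, reverse_complement
from famvar.regulatory import (
    SequenceRegion,
    annotate_regulatory,
    build_mutant_sequence,
    differential_tfbs,
    run_noncoding,
)
from famvar.types import GenomicInterval, PFMRecord


@pytest.fixture
def toy_pfm():
    # length-3 motif with consensus ACG
    counts = np.array([
        [8, 1, 1],
        [1, 8, 1],
        [1, 1, 8],
        [1, 1, 1],
    ], dtype=float)
    return PFMRecord("TOY0001.1", "TOYTF", counts)


class TestPWMScores:
    def test_consensus_scores_relative_one(self, toy_pfm):
        pwm = PWM(toy_pfm)
        assert pwm.relative_score(toy_pfm.consensus()) == pytest.approx(1.0)

    def test_relative_scores_bounded_and_one_only_at_consensus(self, toy_pfm):
        pwm = PWM(toy_pfm)
        for window in itertools.product("ACGT", repeat=3):
            rel = pwm.relative_score("".join(window))
            assert 0.0 <= rel <= 1.0 + 1e-12
            if "".join(window) != "ACG":
                assert rel < 1.0

    def test_matches_biopython_pssm(self, toy_pfm):
        """Independent oracle: Bio.motifs log-odds with the equivalent
        per-cell pseudocount must reproduce raw scores and the score range."""
        motifs = pytest.importorskip("Bio.motifs")
        m = motifs.Motif(counts={
            b: list(toy_pfm.counts[i]) for i, b in enumerate("ACGT")
        })
        # famvar distributes a total pseudocount of 0.8 by the uniform
        # background: 0.2 per cell, biopython's flat per-cell convention
        pssm = m.counts.normalize(pseudocounts=0.2).log_odds()
        pwm = PWM(toy_pfm, pseudocount=0.8)
        for window in ("ACG", "TTT", "AAA", "CGT"):
            expected = sum(pssm[b][j] for j, b in enumerate(window))
            assert pwm.raw_score(window) == pytest.approx(expected)
        assert pwm.score_max == pytest.approx(pssm.max)
        assert pwm.score_min == pytest.approx(pssm.min)

    def test_degenerate_single_base_matrix_rejected(self):
        # a 1-column uniform matrix has no score range
        counts = np.ones((4, 1))
        with pytest.raises(ValueError, match="degenerate"):
            PWM(PFMRecord("X1", "X", counts))


class TestScan:
    def test_hits_equal_exhaustive_enumeration(self, toy_pfm, rng):
        """Scan of a random sequence == scoring every window independently,
        on both strands, for every threshold."""
        pwm = PWM(toy_pfm)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        for threshold in (0.6, 0.8, 0.95):
            hits = pwm_scan(seq, pwm, threshold)
            expected = set()
            for off in range(len(seq) - 2):
                window = seq[off:off + 3]
                if pwm.relative_score(window) >= threshold:
                    expected.add((off + 1, "+", window))
                rc = reverse_complement(window)
                if pwm.relative_score(rc) >= threshold:
                    expected.add((off + 1, "-", rc))
            assert {(h.start, h.strand, h.site_seq) for h in hits} == expected

    def test_windows_with_n_skipped(self, toy_pfm):
        pwm = PWM(toy_pfm)
        assert pwm_scan("ANCGT", pwm, 0.1) == pwm_scan("ANCGT", pwm, 0.1)
        hits = pwm_scan("NACGN", pwm, 0.5)
        assert all("N" not in h.site_seq for h in hits)
        # the clean central window is still found
        assert any(h.start == 2 and h.strand == "+" for h in hits)

    def test_strand_symmetry(self, toy_pfm, rng):
        """Scanning the reverse complement swaps strands and mirrors
        coordinates, with identical score multisets."""
        pwm = PWM(toy_pfm)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        n = len(seq)
        fwd = pwm_scan(seq, pwm, 0.7)
        rev = pwm_scan(reverse_complement(seq), pwm, 0.7)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (n - h.end + 1, flip[h.strand], round(h.rel_score, 9), h.site_seq)
            for h in fwd
        }
        observed = {
            (h.start, h.strand, round(h.rel_score, 9), h.site_seq) for h in rev
        }
        assert mirrored == observed

    def test_threshold_monotonicity(self, toy_pfm, rng):
        pwm = PWM(toy_pfm)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        strict = {(h.start, h.strand) for h in pwm_scan(seq, pwm, 0.85)}
        loose = {(h.start, h.strand) for h in pwm_scan(seq, pwm, 0.80)}
        assert strict <= loose

    def test_bad_threshold_rejected(self, toy_pfm):
        with pytest.raises(ValueError, match="threshold"):
            pwm_scan("ACGT", PWM(toy_pfm), threshold=0.0)

    def test_sequence_shorter_than_motif(self, toy_pfm):
        assert pwm_scan("AC", PWM(toy_pfm)) == []


class TestIntervalIntersection:
    def test_promoter_overlap_at_reported_positions(self, tmp_path):
        bed = tmp_path / "promoter.bed"
        bed.write_text("12\t129308486\t129308588\tSLC15A4_promoter\n")
        tracks = {"promoters": read_bed(bed)}
        inside = make_variant(chrom="12", pos=129308531)
        outside = make_variant(chrom="12", pos=129308600)
        assert [iv.name for iv in annotate_regulatory(inside, tracks).overlapping_elements] == [
            "SLC15A4_promoter"
        ]
        assert annotate_regulatory(outside, tracks).overlapping_elements == []

    def test_matches_quadratic_oracle_on_random_intervals(self, rng):
        intervals = []
        for i in range(1000):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(1, 50))
            intervals.append(GenomicInterval("7", start, end, name=f"iv{i}"))
        tracks = {"t": intervals}
        for pos in rng.integers(1, 10_050, size=60):
            v = make_variant(chrom="7", pos=int(pos))
            fast = {iv.name for iv in annotate_regulatory(v, tracks).overlapping_elements}
            brute = {iv.name for iv in intervals if iv.start <= pos - 1 < iv.end}
            assert fast == brute

    def test_chromosome_mismatch_gives_empty_overlap(self):
        tracks = {"t": [GenomicInterval("chr12", 0, 100)]}
        v = make_variant(chrom="12", pos=50)
        assert annotate_regulatory(v, tracks).overlapping_elements == []

    def test_state_table_join(self):
        v = make_variant(chrom="12", pos=129308531)
        ann = annotate_regulatory(v, {}, {
            v.variant_id: {"chromhmm_state": "TssA", "chromhmm_score": 0.969,
                           "segway_label": "TSS", "tfbs_count": 52,
                           "tfbs_peak_count": 115}
        })
        assert ann.chromhmm_state == "TssA"
        assert ann.chromhmm_score == pytest.approx(0.969)
        assert ann.tfbs_peak_count == 115


class TestMutantSequence:
    def test_snv_substituted(self):
        v = make_variant(chrom="12", pos=129308531, ref="C", alt="T")
        wt = "AAC" + "C" + "GGA"  # variant at offset 3
        mut = build_mutant_sequence(wt, 129308528, v)
        assert mut == "AACTGGA"
        assert len(mut) == len(wt)

    def test_reference_mismatch_reports_bases(self):
        v = make_variant(chrom="12", pos=10, ref="C", alt="T")
        with pytest.raises(ValueError, match="expected C, observed A"):
            build_mutant_sequence("AAAAA", 8, v)

    def test_position_outside_window_rejected(self):
        v = make_variant(chrom="12", pos=100, ref="C", alt="T")
        with pytest.raises(ValueError, match="outside"):
            build_mutant_sequence("ACGT", 1, v)


def hit(tf, matrix, start=1, end=3, strand="+", score=0.9, seq="ACG"):
    return TFBSHit(matrix, tf, start, end, strand, score, seq)


class TestDifferentialTFBS:
    def test_sets_partition_the_tf_universe(self):
        wt = [hit("A", "M1"), hit("B", "M2"), hit("C", "M3")]
        mut = [hit("B", "M2"), hit("D", "M4")]
        d = differential_tfbs(wt, mut)
        assert d.wt_only == {"A", "C"}
        assert d.mut_only == {"D"}
        assert d.shared == {"B"}
        universe = {h.tf_name for h in wt + mut}
        assert d.wt_only | d.mut_only | d.shared == universe
        assert not (d.wt_only & d.mut_only or d.wt_only & d.shared or d.mut_only & d.shared)

    def test_identical_hit_lists_all_shared(self):
        hits = [hit("A", "M1"), hit("B", "M2")]
        d = differential_tfbs(hits, list(hits))
        assert d.wt_only == set() and d.mut_only == set()
        assert d.n_affected == 0

    def test_two_matrices_of_one_tf_collapse(self):
        wt = [hit("STAT1", "MA0137.2"), hit("STAT1", "MA0137.3")]
        d = differential_tfbs(wt, [])
        assert d.wt_only == {"STAT1"}

    def test_matrix_split_across_alleles_is_shared(self):
        d = differential_tfbs([hit("A", "M1")], [hit("A", "M2")])
        assert d.shared == {"A"} and d.n_affected == 0


class TestRunNoncoding:
    def test_variant_without_sequence_reported_without_differential(self):
        v = make_variant(chrom="1", pos=500, region_class="upstream")
        (rep,) = run_noncoding([v], {}, None, [], [], None)
        assert rep.differential is None
        assert rep.cadd_flag is False

    def test_cadd_flag_uses_coding_cutoff(self):
        from famvar.types import ScorePanel

        v = make_variant(chrom="1", pos=500, region_class="upstream",
                         scores=ScorePanel(cadd_phred=11.38))
        (rep,) = run_noncoding([v], {}, None, [], [], None)
        assert rep.cadd_flag is True
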