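"""The coding cascade: region split, votes, boundary semantics, funnel
invariants, and the order-free conjunction oracle."""

import pytest
from conftest import make_variant

from famvar.cascade import (
    conservation_vote,
    deleteriousness_vote,
    exclude_synonymous,
    intolerance_vote,
    passes_cascade,
    run_coding_cascade,
    split_by_region,
)
from famvar.config import CascadeConfig
from famvar.types import ScorePanel


def coding_variant(pos, cadd=25.0, gerp=5.0, phastcons=0.9, phylop=4.0,
                   intol=(-1.0, -1.0, -1.0), z=1.0, effect="missense",
                   region="exonic", n_damaging=10):
    tools = {}
    damaging = {"sift": "D", "pp2_humdiv": "D", "pp2_humvar": "P", "lrt": "D",
                "mutation_taster": "D", "mutation_assessor": "M", "fathmm": "D",
                "provean": "D", "reliability_index": 9.0, "vest3": 0.8}
    benign = {"sift": "T", "pp2_humdiv": "B", "pp2_humvar": "B", "lrt": "N",
              "mutation_taster": "N", "mutation_assessor": "L", "fathmm": "T",
              "provean": "N", "reliability_index": 2.0, "vest3": 0.1}
    for i, tool in enumerate(damaging):
        tools[tool] = damaging[tool] if i < n_damaging else benign[tool]
    return make_variant(
        pos=pos, region_class=region, exonic_effect=effect,
        scores=ScorePanel(
            cadd_phred=cadd, gerp=gerp, phastcons=phastcons, phylop=phylop,
            intolerance_scores={"local": intol[0], "esp6500": intol[1], "exac": intol[2]},
            exac_z=z, exac_pli=0.95, tool_predictions=tools,
        ),
    )


class TestRegionSplit:
    @pytest.mark.parametrize("region,bucket", [
        ("exonic", 0), ("splicing", 0),
        ("UTR5", 1), ("UTR3", 1), ("upstream", 1), ("downstream", 1),
        ("intronic", 2), ("intergenic", 2), ("ncRNA", 2),
    ])
    def test_every_region_label_routed(self, region, bucket):
        v = make_variant(region_class=region)
        buckets = split_by_region([v])
        assert [len(b) for b in buckets] == [
            1 if i == bucket else 0 for i in range(3)
        ]

    def test_unknown_label_raises_with_label(self):
        v = make_variant(region_class=None)
        with pytest.raises(ValueError, match="None"):
            split_by_region([v])


class TestSynonymousExclusion:
    def test_synonymous_dropped_missense_kept(self):
        syn = make_variant(pos=1, region_class="exonic", exonic_effect="synonymous")
        mis = make_variant(pos=2, region_class="exonic", exonic_effect="missense")
        assert exclude_synonymous([syn, mis]) == [mis]

    def test_splicing_kept_by_default_but_droppable(self):
        sp = make_variant(region_class="splicing", exonic_effect="NA")
        assert exclude_synonymous([sp]) == [sp]
        assert exclude_synonymous([sp], keep_splicing=False) == []

    def test_empty_input_empty_output(self):
        assert exclude_synonymous([]) == []


class TestConservationVote:
    def test_all_three_tools_pass(self):
        p = ScorePanel(gerp=5.49, phylop=5.60, phastcons=0.91)
        res = conservation_vote(p)
        assert (res.votes, res.passed) == (3, True)

    def test_boundary_semantics_gerp_phylop_inclusive_phastcons_strict(self):
        p = ScorePanel(gerp=2.0, phastcons=0.3, phylop=3.0)
        res = conservation_vote(p)
        assert (res.votes, res.passed) == (2, True)  # phastcons 0.3 fails (>)

    def test_all_missing_scores_fail(self):
        res = conservation_vote(ScorePanel())
        assert (res.votes, res.passed) == (0, False)

    def test_single_vote_fails(self):
        p = ScorePanel(gerp=2.5, phastcons=0.1, phylop=0.0)
        assert not conservation_vote(p).passed


class TestIntoleranceVote:
    def test_all_four_criteria_full_fraction(self):
        p = ScorePanel(
            intolerance_scores={"local": -1, "esp6500": -1, "exac": -1}, exac_z=1.0
        )
        res = intolerance_vote(p, "missense")
        assert res.fraction == 1.0 and res.passed

    def test_three_of_four_passes(self):
        p = ScorePanel(
            intolerance_scores={"local": -1, "esp6500": -1, "exac": -1}, exac_z=-1.0
        )
        res = intolerance_vote(p, "missense")
        assert res.fraction == 0.75 and res.passed

    def test_two_of_four_fails(self):
        p = ScorePanel(
            intolerance_scores={"local": -1, "esp6500": -1, "exac": 0.5}, exac_z=-1.0
        )
        res = intolerance_vote(p, "missense")
        assert res.fraction == 0.5 and not res.passed

    def test_lof_uses_pli(self):
        p = ScorePanel(
            intolerance_scores={"local": -1, "esp6500": -1, "exac": -1},
            exac_z=-5.0, exac_pli=0.9,
        )
        res = intolerance_vote(p, "stopgain")
        assert res.fraction == 1.0  # pLI >= 0.9, Z ignored for LoF

    def test_available_denominator_mode(self):
        cfg = CascadeConfig(denominator="available")
        p = ScorePanel(intolerance_scores={"local": -1, "esp6500": -1, "exac": -1})
        # stoploss has no class-specific criterion: 3/3 in available mode
        assert intolerance_vote(p, "stoploss", cfg).fraction == 1.0
        assert intolerance_vote(p, "stoploss").fraction == 0.75  # fixed: 3/4


class TestDeleteriousnessVote:
    @pytest.mark.parametrize("n_damaging,fraction,passed", [
        (10, 1.0, True), (9, 0.9, True), (8, 0.8, True),
        (6, 0.6, True), (5, 0.5, False), (0, 0.0, False),
    ])
    def test_vote_fractions(self, n_damaging, fraction, passed):
        v = coding_variant(1, n_damaging=n_damaging)
        res = deleteriousness_vote(v.scores)
        assert res.fraction == pytest.approx(fraction)
        assert res.passed is passed

    def test_vest3_boundary_inclusive(self):
        p = ScorePanel(tool_predictions={"vest3": 0.5})
        assert deleteriousness_vote(p).votes == 1

    def test_reliability_index_boundary_inclusive(self):
        p = ScorePanel(tool_predictions={"reliability_index": 5.0})
        assert deleteriousness_vote(p).votes == 1
        assert deleteriousness_vote(ScorePanel(tool_predictions={"reliability_index": 4.0})).votes == 0

    def test_metasvm_metalr_parsed_but_not_voted(self):
        p = ScorePanel(tool_predictions={"metasvm": "D", "metalr": "D"})
        assert deleteriousness_vote(p).votes == 0

    def test_unrecognized_token_counts_as_fail(self):
        p = ScorePanel(tool_predictions={"vest3": "not-a-number"})
        assert deleteriousness_vote(p).votes == 0

    def test_vote_arithmetic_effective_integer_thresholds(self):
        cfg = CascadeConfig()
        assert cfg.intolerance_votes_needed == 3  # ceil(0.6 * 4)
        assert cfg.deleteriousness_votes_needed == 6  # ceil(0.6 * 10)


class TestCascade:
    def test_cadd_failure_recorded_in_funnel(self):
        good = coding_variant(1)
        low = coding_variant(2, cadd=9.99)
        survivors, rep = run_coding_cascade([good, low])
        assert [v.pos for v in survivors] == [1]
        stage = {s.name: s for s in rep.stages}["cadd"]
        assert stage.n_in == 2 and stage.n_out == 1
        assert low.variant_id not in stage.surviving_ids

    def test_funnel_monotone_and_nested(self, rng):
        variants = [
            coding_variant(
                pos=i,
                cadd=float(rng.uniform(0, 40)),
                gerp=float(rng.normal(0, 3)),
                phastcons=float(rng.random()),
                phylop=float(rng.normal(0, 3)),
                intol=tuple(rng.normal(0, 1, size=3)),
                z=float(rng.normal(0, 1)),
                effect=str(rng.choice(["missense", "synonymous", "stopgain"])),
                region=str(rng.choice(["exonic", "splicing", "intronic", "UTR5"])),
                n_damaging=int(rng.integers(0, 11)),
            )
            for i in range(1, 401)
        ]
        survivors, rep = run_coding_cascade(variants)
        prev = None
        for s in rep.stages:
            assert s.n_out <= s.n_in
            if prev is not None:
                assert set(s.surviving_ids) <= set(prev.surviving_ids)
            prev = s

        # order-free oracle: the cascade equals the conjunction of predicates
        expected = {v.variant_id for v in variants if passes_cascade(v)}
        assert {v.variant_id for v in survivors} == expected

    def test_raising_cadd_min_never_adds_survivors(self, rng):
        variants = [
            coding_variant(pos=i, cadd=float(rng.uniform(5, 20)))
            for i in range(1, 101)
        ]
        base, _ = run_coding_cascade(variants, CascadeConfig(cadd_min=10.0))
        strict, _ = run_coding_cascade(variants, CascadeConfig(cadd_min=15.0))
        assert {v.variant_id for v in strict} <= {v.variant_id for v in base}

    def test_survivors_sorted_by_cadd_desc_then_id(self):
        a = coding_variant(5, cadd=20.0)
        b = coding_variant(3, cadd=30.0)
        c = coding_variant(4, cadd=20.0)
        survivors, _ = run_coding_cascade([a, b, c])
        assert [v.pos for v in survivors] == [3, 4, 5]
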