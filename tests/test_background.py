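"""Background-knowledge exploitation: mediators, xrefs, expansion,
logical definitions, and mapping-gain selection."""

from __future__ import annotations

import itertools

import pytest

from ontoalign import (
    Alignment,
    BKSource,
    LogicalDefinition,
    Mapping,
    MatchConfig,
    build_bridge,
    build_lexicon,
    lexical_expansion,
    lexical_match,
    logicaldef_match,
    mapping_gain,
    mediating_match,
    select_bk,
    xref_match,
)

from .conftest import make_ontology, single_name_lexicon


def bk_from_terms(prefix: str, terms: dict) -> BKSource:
    onto = make_ontology(prefix, terms)
    return BKSource(name=prefix, ontology=onto, lexicon=build_lexicon(onto))


class TestMediatingMatch:
    def test_chained_exact_names(self):
        lex_a = single_name_lexicon("A", {"A:1": "pubis"})
        lex_b = single_name_lexicon("B", {"B:1": "pubis"})
        bk = bk_from_terms("M", {"M:1": {"label": "pubis"}})
        result = mediating_match(lex_a, lex_b, bk)
        assert result.get("A:1", "B:1").similarity == 1.0

    def test_one_sided_anchor_no_mapping(self):
        lex_a = single_name_lexicon("A", {"A:1": "pubis"})
        lex_b = single_name_lexicon("B", {"B:1": "ischium"})
        bk = bk_from_terms("M", {"M:1": {"label": "pubis"}})
        assert len(mediating_match(lex_a, lex_b, bk)) == 0

    def test_two_mediating_classes_max_of_min_scores(self):
        lex_a = single_name_lexicon("A", {"A:1": "pubis"})
        lex_b = single_name_lexicon("B", {"B:1": "pubic bone"})
        # M:1 anchors B via an exact synonym (min 0.95); M:2 via a related
        # synonym (min 0.85): the mapping keeps the best bridge
        bk = bk_from_terms(
            "M",
            {
                "M:1": {"label": "pubis", "exact": ["pubic bone"]},
                "M:2": {"label": "pubis", "other": ["pubic bone"]},
            },
        )
        result = mediating_match(lex_a, lex_b, bk)
        assert result.get("A:1", "B:1").similarity == pytest.approx(0.95)


class TestXrefMatch:
    def test_shared_reference_links_inputs(self):
        onto_a = make_ontology("FMA", {"FMA:16595": {"label": "pubis"}})
        onto_b = make_ontology("NCI", {"NCI:C33423": {"label": "pubic bone"}})
        bk = bk_from_terms(
            "UBERON",
            {
                "UBERON:0001275": {
                    "label": "pubis",
                    "xref": ["FMA:16595", "NCI:C33423"],
                }
            },
        )
        result = xref_match(onto_a, onto_b, bk)
        mapping = result.get("FMA:16595", "NCI:C33423")
        assert mapping is not None
        assert mapping.similarity == pytest.approx(0.99)

    def test_no_xrefs_empty_alignment(self):
        onto_a = make_ontology("A", {"A:1": {"label": "pubis"}})
        onto_b = make_ontology("B", {"B:1": {"label": "pubis"}})
        bk = bk_from_terms("M", {"M:1": {"label": "pubis"}})
        assert len(xref_match(onto_a, onto_b, bk)) == 0

    def test_lexical_supplement_on_coverage_rule(self):
        # xrefs cover 1 class of A; lexical anchors cover 2 (>= 2x) so the
        # lexical anchors are added and A:2 gets mapped through the BK
        onto_a = make_ontology(
            "A", {"A:1": {"label": "pubis"}, "A:2": {"label": "ischium"}}
        )
        onto_b = make_ontology(
            "B", {"B:1": {"label": "pubis"}, "B:2": {"label": "ischium"}}
        )
        bk = bk_from_terms(
            "M",
            {
                "M:1": {"label": "pubis", "xref": ["A:1", "B:1"]},
                "M:2": {"label": "ischium"},
            },
        )
        lex_a, lex_b = build_lexicon(onto_a), build_lexicon(onto_b)
        result = xref_match(onto_a, onto_b, bk, lex_a, lex_b)
        assert ("A:2", "B:2") in result

    def test_no_supplement_below_coverage_rule(self):
        onto_a = make_ontology(
            "A", {"A:1": {"label": "pubis"}, "A:2": {"label": "ischium"}}
        )
        onto_b = make_ontology(
            "B", {"B:1": {"label": "pubis"}, "B:2": {"label": "ischium"}}
        )
        # xrefs cover both classes of each side: lexical coverage (2) is
        # below twice the xref coverage (2), so no supplement happens
        bk = bk_from_terms(
            "M",
            {
                "M:1": {"label": "pubis", "xref": ["A:1", "B:1"]},
                "M:2": {"xref": ["A:2", "B:2"]},
            },
        )
        lex_a, lex_b = build_lexicon(onto_a), build_lexicon(onto_b)
        result = xref_match(onto_a, onto_b, bk, lex_a, lex_b)
        for m in result:
            assert m.similarity == pytest.approx(0.99)


class TestLexicalExpansion:
    def test_anchored_class_gains_bk_names(self):
        lex = single_name_lexicon("A", {"A:1": "heart"})
        bk = bk_from_terms(
            "U", {"U:948": {"label": "heart", "exact": ["vertebrate heart"]}}
        )
        anchors = lexical_match(lex, bk.lexicon)
        expanded = lexical_expansion(lex, bk.lexicon, anchors)
        names = {e.name for e in expanded.entries_for_class("A:1")}
        assert "vertebrate heart" in names
        gained = next(
            e for e in expanded.entries_for_class("A:1") if e.origin == "expansion"
        )
        assert gained.weight < 1.0

    def test_unanchored_class_unchanged(self):
        lex = single_name_lexicon("A", {"A:1": "spleen"})
        bk = bk_from_terms("U", {"U:948": {"label": "heart", "exact": ["cardium"]}})
        anchors = lexical_match(lex, bk.lexicon)
        expanded = lexical_expansion(lex, bk.lexicon, anchors)
        assert sorted(expanded.entries()) == sorted(lex.entries())

    def test_expansion_enables_lexical_match(self):
        # A says "heart", B says only "vertebrate heart"; the BK bridges
        lex_a = single_name_lexicon("A", {"A:1": "heart"})
        lex_b = single_name_lexicon("B", {"B:1": "vertebrate heart"})
        bk = bk_from_terms(
            "U", {"U:948": {"label": "heart", "exact": ["vertebrate heart"]}}
        )
        assert len(lexical_match(lex_a, lex_b)) == 0
        anchors = lexical_match(lex_a, bk.lexicon)
        expanded = lexical_expansion(lex_a, bk.lexicon, anchors)
        assert lexical_match(expanded, lex_b).get("A:1", "B:1") is not None


class TestMappingGain:
    def base(self, n: int, prefix_s="A", prefix_t="B") -> Alignment:
        return Alignment(
            Mapping(f"{prefix_s}:{i}", f"{prefix_t}:{i}", 1.0) for i in range(n)
        )

    def test_identical_alignments_zero_gain(self):
        base = self.base(10)
        assert mapping_gain(base, base) == 0.0

    def test_two_new_sources_over_ten(self):
        base = self.base(10)
        candidate = Alignment(
            [Mapping("A:100", "B:100", 1.0), Mapping("A:101", "B:101", 1.0)]
        )
        assert mapping_gain(candidate, base) == pytest.approx(0.2)

    def test_subset_candidate_zero_gain(self):
        base = self.base(10)
        candidate = self.base(4)
        assert mapping_gain(candidate, base) == 0.0

    def test_empty_baseline_degenerate_convention(self):
        candidate = self.base(3)
        assert mapping_gain(candidate, Alignment()) == 3.0

    def test_candidate_denominator_switch(self):
        base = self.base(10)
        candidate = Alignment(
            [Mapping("A:100", "B:100", 1.0), Mapping("A:5", "B:50", 1.0)]
        )
        assert mapping_gain(candidate, base, "candidate") == pytest.approx(0.5)


class TestSelectBK:
    def inputs(self):
        lex_a = single_name_lexicon(
            "A", {"A:1": "pubis", "A:2": "sacral canal", "A:3": "iliac crest"}
        )
        lex_b = single_name_lexicon(
            "B", {"B:1": "pubis", "B:2": "canalis sacralis", "B:3": "crista iliaca"}
        )
        return lex_a, lex_b

    def useful_bk(self, name="M1"):
        return bk_from_terms(
            name,
            {
                f"{name}:1": {"label": "sacral canal", "exact": ["canalis sacralis"]},
                f"{name}:2": {"label": "iliac crest", "exact": ["crista iliaca"]},
            },
        )

    def test_single_useful_candidate_selected(self):
        lex_a, lex_b = self.inputs()
        selected = select_bk([self.useful_bk()], lex_a, lex_b)
        assert [bk.name for bk in selected] == ["M1"]
        assert selected[0].individual_gain > 0

    def test_redundant_bk_rejected(self):
        # lexically identical to the inputs: zero gain
        lex_a, lex_b = self.inputs()
        bk = bk_from_terms("M0", {"M0:1": {"label": "pubis"}})
        assert select_bk([bk], lex_a, lex_b) == []

    def test_second_redundant_candidate_rejected(self):
        lex_a, lex_b = self.inputs()
        big = self.useful_bk("M1")
        # M2's novel mappings are a subset of M1's
        small = bk_from_terms(
            "M2",
            {"M2:1": {"label": "sacral canal", "exact": ["canalis sacralis"]}},
        )
        selected = select_bk([big, small], lex_a, lex_b)
        assert [bk.name for bk in selected] == ["M1"]

    def test_order_stability(self):
        lex_a, lex_b = self.inputs()
        candidates = [
            self.useful_bk("M1"),
            bk_from_terms("M0", {"M0:1": {"label": "pubis"}}),
            bk_from_terms(
                "M2",
                {"M2:1": {"label": "sacral canal", "exact": ["canalis sacralis"]}},
            ),
        ]
        results = set()
        for perm in itertools.permutations(candidates):
            selected = select_bk(list(perm), lex_a, lex_b)
            results.add(tuple(bk.name for bk in selected))
        assert len(results) == 1


class TestLogicalDefMatch:
    def phenotype_pair(self, filler_b="UBERON:0002228", bridge_terms=None):
        # "cleft" quality inhering in "rib" with "abnormal" modifier,
        # declared identically (or bridged) in two phenotype ontologies
        onto_a = make_ontology("HP", {"HP:0000892": {"label": "bifid ribs"}})
        onto_a.set_logical_def(
            "HP:0000892",
            LogicalDefinition(
                "PATO:0000403",
                frozenset(
                    {
                        ("inheres_in", "UBERON:0002228"),
                        ("has_modifier", "PATO:0000460"),
                    }
                ),
            ),
        )
        onto_b = make_ontology("MP", {"MP:0000153": {"label": "rib bifurcation"}})
        onto_b.set_logical_def(
            "MP:0000153",
            LogicalDefinition(
                "PATO:0000403",
                frozenset(
                    {("inheres_in", filler_b), ("has_modifier", "PATO:0000460")}
                ),
            ),
        )
        bridge = {}
        if bridge_terms:
            bridge = build_bridge(make_ontology("U", bridge_terms))
        return onto_a, onto_b, bridge

    def test_identical_definitions_mapped(self):
        onto_a, onto_b, _ = self.phenotype_pair()
        result = logicaldef_match(onto_a, onto_b)
        mapping = result.get("HP:0000892", "MP:0000153")
        assert mapping is not None
        assert mapping.similarity == pytest.approx(0.90)

    def test_one_filler_difference_not_mapped(self):
        onto_a, onto_b, _ = self.phenotype_pair(filler_b="UBERON:0000000")
        assert len(logicaldef_match(onto_a, onto_b)) == 0

    def test_bridged_fillers_mapped(self):
        # definitions differ in one filler, but a cross-reference bridges
        # the FMA-style identifier to the UBERON one
        onto_a, onto_b, bridge = self.phenotype_pair(
            filler_b="FMA:7574",
            bridge_terms={
                "U:1": {"xref": ["FMA:7574", "UBERON:0002228"]},
            },
        )
        assert len(logicaldef_match(onto_a, onto_b)) == 0  # without bridge
        result = logicaldef_match(onto_a, onto_b, bridge)
        assert result.get("HP:0000892", "MP:0000153") is not None


class TestInvariantMediationVsExpansion:
    @pytest.mark.parametrize("seed", range(5))
    def test_mediation_subset_of_expansion_matches(self, seed):
        from ontoalign import FixtureConfig, generate_pair

        cfg = FixtureConfig(
            n_classes=30,
            shared_fraction=0.8,
            variant_ops=("synonym_shuffle",),
            variant_rate=0.5,
            bk_mediator=True,
            seed=seed,
        )
        onto_a, onto_b, _, bk_onto = generate_pair(cfg)
        lex_a, lex_b = build_lexicon(onto_a), build_lexicon(onto_b)
        bk = BKSource("M", bk_onto, build_lexicon(bk_onto))
        mediated = mediating_match(lex_a, lex_b, bk)
        exp_a = lexical_expansion(lex_a, bk.lexicon, bk.anchors_a)
        exp_b = lexical_expansion(lex_b, bk.lexicon, bk.anchors_b)
        expanded = lexical_match(exp_a, exp_b)
        assert mediated.pairs() <= expanded.pairs()

    @pytest.mark.parametrize("seed", range(5))
    def test_mediator_never_lowers_recall(self, seed):
        from ontoalign import FixtureConfig, combine, evaluate, generate_pair

        cfg = FixtureConfig(
            n_classes=40,
            shared_fraction=0.8,
            variant_ops=("synonym_shuffle",),
            variant_rate=0.5,
            bk_mediator=True,
            seed=seed,
        )
        onto_a, onto_b, reference, bk_onto = generate_pair(cfg)
        lex_a, lex_b = build_lexicon(onto_a), build_lexicon(onto_b)
        bk = BKSource("M", bk_onto, build_lexicon(bk_onto))
        baseline = lexical_match(lex_a, lex_b)
        with_bk = combine(baseline, mediating_match(lex_a, lex_b, bk), "union")
        assert (
            evaluate(with_bk, reference).recall
            >= evaluate(baseline, reference).recall
        )
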