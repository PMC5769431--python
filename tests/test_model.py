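"""Normalization, lexicon construction and synonym derivation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoalign import (
    LexicalEntry,
    Lexicon,
    MatchConfig,
    Thesaurus,
    apply_thesaurus,
    build_lexicon,
    build_thesaurus,
    generate_reduced_synonyms,
    is_formula,
    normalize_name,
)
from ontoalign.model import EmptyNameError, canonical_name, is_alphanumeric_code

from .conftest import make_ontology


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("hasPart", "has part"),
            ("gingiva", "gingiva"),
            ("Mixed_mesodermal (Mullerian) Tumor!", "mixed mesodermal (mullerian) tumor"),
            ("nervous   system", "nervous system"),
            ("Heart", "heart"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    def test_empty_after_normalization_signalled(self):
        with pytest.raises(EmptyNameError):
            normalize_name("!!!")

    @given(st.text(min_size=1, max_size=40))
    @settings(max_examples=300, derandomize=True)
    def test_idempotent_on_own_outputs(self, raw):
        try:
            once = normalize_name(raw)
        except EmptyNameError:
            return
        assert normalize_name(once) == once


class TestIsFormula:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("nervous system", False),
            ("C20H25N3O", True),
            ("Fe(III)", True),
            ("mixed mesodermal (mullerian) tumor", False),
            ("gingiva", False),
        ],
    )
    def test_examples(self, raw, expected):
        assert is_formula(raw) is expected

    def test_formula_normalization_is_underscore_replacement_only(self):
        # formulas keep case and punctuation; only underscores become spaces
        assert canonical_name("Fe(III)_oxide") == "Fe(III) oxide"


class TestAlphanumericCodes:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("UBERON_0000948", True),
            ("0001275", True),
            ("NervousSystem", False),
            ("C68500", True),
        ],
    )
    def test_detection(self, name, expected):
        assert is_alphanumeric_code(name) is expected


class TestBuildLexicon:
    def test_label_and_exact_synonym_categories(self):
        onto = make_ontology(
            "UB", {"UB:0000948": {"label": "heart", "exact": ["vertebrate heart"]}}
        )
        lex = build_lexicon(onto)
        entries = {e.name: e for e in lex.entries_for_class("UB:0000948")}
        assert entries["heart"].category == "label"
        assert entries["vertebrate heart"].category == "exactSynonym"
        assert entries["heart"].weight > entries["vertebrate heart"].weight

    def test_code_local_names_excluded(self):
        onto = make_ontology("UBERON", {"UBERON:0000948": {"label": "heart"}})
        lex = build_lexicon(onto)
        assert all(e.category != "localName" for e in lex.entries())

    def test_word_like_local_names_included(self):
        onto = make_ontology("TB", {"TB:NervousSystem": {}})
        lex = build_lexicon(onto)
        (entry,) = lex.entries_for_class("TB:NervousSystem")
        assert entry.name == "nervous system"
        assert entry.category == "localName"

    def test_empty_annotations_empty_lexicon(self):
        onto = make_ontology("TA", {"TA:0000001": {}})
        assert len(build_lexicon(onto)) == 0

    def test_obsolete_classes_excluded(self):
        onto = make_ontology(
            "TA", {"TA:old": {"label": "former thing", "obsolete": True}}
        )
        assert len(build_lexicon(onto)) == 0

    def test_duplicate_name_keeps_highest_weight_category(self):
        onto = make_ontology(
            "TA", {"TA:0000007": {"label": "heart", "other": ["heart"]}}
        )
        lex = build_lexicon(onto)
        (entry,) = lex.entries_for_class("TA:0000007")
        assert entry.category == "label" and entry.weight == 1.0

    def test_unknown_properties_ignored(self):
        onto = make_ontology("TA", {"TA:0000008": {"label": "heart"}})
        onto.annotate("TA:0000008", "wibbleProperty", "whatever")
        lex = build_lexicon(onto)
        assert {e.name for e in lex.entries()} == {"heart"}

    def test_by_name_by_class_hold_same_entries(self):
        onto = make_ontology(
            "TA",
            {
                "TA:a": {"label": "heart", "exact": ["vertebrate heart"]},
                "TA:b": {"label": "lung", "other": ["pulmo"]},
            },
        )
        lex = build_lexicon(onto)
        via_names = sorted(lex.entries())
        via_classes = sorted(
            e for cid in lex.classes() for e in lex.entries_for_class(cid)
        )
        assert via_names == via_classes


class TestReducedSynonyms:
    def test_stopword_removal(self):
        lex = Lexicon([LexicalEntry("structure of nervous system", "S:1", "label", 1.0)])
        out = generate_reduced_synonyms(lex)
        names = {e.name for e in out.entries_for_class("S:1")}
        assert "nervous system" in names

    def test_parenthetical_removal(self):
        lex = Lexicon(
            [LexicalEntry("mixed mesodermal (mullerian) tumor", "N:1", "label", 1.0)]
        )
        out = generate_reduced_synonyms(lex)
        names = {e.name for e in out.entries_for_class("N:1")}
        assert "mixed mesodermal tumor" in names

    def test_nothing_to_remove_no_addition(self):
        lex = Lexicon([LexicalEntry("heart", "S:1", "label", 1.0)])
        assert len(generate_reduced_synonyms(lex)) == 1

    def test_derived_entries_penalized_and_tagged(self):
        lex = Lexicon([LexicalEntry("structure of heart", "S:1", "label", 1.0)])
        out = generate_reduced_synonyms(lex)
        derived = next(e for e in out.entries_for_class("S:1") if e.origin == "stopword")
        assert derived.weight == pytest.approx(0.9)

    def test_originals_untouched(self):
        entries = [
            LexicalEntry("structure of heart", "S:1", "label", 1.0),
            LexicalEntry("entire lung (left)", "S:2", "exactSynonym", 0.95),
        ]
        lex = Lexicon(entries)
        out = generate_reduced_synonyms(lex)
        for entry in entries:
            assert out.entries_for_name(entry.name)[0] == entry

    def test_leading_only_mode(self):
        lex = Lexicon([LexicalEntry("structure of wall of stomach", "S:1", "label", 1.0)])
        cfg = MatchConfig(leading_stopwords_only=True)
        out = generate_reduced_synonyms(lex, cfg)
        names = {e.name for e in out.entries_for_class("S:1")}
        assert "wall of stomach" in names
        assert "wall stomach" not in names

    def test_reduction_to_empty_skipped(self):
        lex = Lexicon([LexicalEntry("structure of the", "S:1", "label", 1.0)])
        out = generate_reduced_synonyms(lex)
        assert {e.name for e in out.entries()} == {"structure of the"}


class TestThesaurus:
    def test_single_word_difference_induces_pair(self):
        lex = Lexicon(
            [
                LexicalEntry("stomach serosa", "MA:1626", "label", 1.0),
                LexicalEntry("gastric serosa", "MA:1626", "exactSynonym", 0.95),
            ]
        )
        assert ("gastric", "stomach") in build_thesaurus(lex)

    def test_first_position_difference(self):
        lex = Lexicon(
            [
                LexicalEntry("hepatic artery", "X:1", "label", 1.0),
                LexicalEntry("liver artery", "X:1", "exactSynonym", 0.95),
            ]
        )
        assert ("hepatic", "liver") in build_thesaurus(lex)

    def test_single_name_contributes_nothing(self):
        lex = Lexicon([LexicalEntry("stomach serosa", "X:1", "label", 1.0)])
        assert len(build_thesaurus(lex)) == 0

    def test_different_lengths_excluded(self):
        lex = Lexicon(
            [
                LexicalEntry("serosa of stomach", "X:1", "label", 1.0),
                LexicalEntry("gastric serosa", "X:1", "exactSynonym", 0.95),
            ]
        )
        assert len(build_thesaurus(lex)) == 0

    def test_apply_substitutes_all_occurrences(self):
        lex = Lexicon([LexicalEntry("stomach wall", "X:1", "label", 1.0)])
        out = apply_thesaurus(lex, Thesaurus([("stomach", "gastric")]))
        derived = next(e for e in out.entries() if e.origin == "thesaurus")
        assert derived.name == "gastric wall"
        assert derived.weight == pytest.approx(0.9)

    def test_empty_thesaurus_identity(self):
        lex = Lexicon([LexicalEntry("stomach wall", "X:1", "label", 1.0)])
        assert sorted(apply_thesaurus(lex, Thesaurus()).entries()) == sorted(lex.entries())

    def test_word_absent_no_addition(self):
        lex = Lexicon([LexicalEntry("heart", "X:1", "label", 1.0)])
        out = apply_thesaurus(lex, Thesaurus([("stomach", "gastric")]))
        assert len(out) == 1

    def test_output_superset_of_input(self):
        lex = Lexicon(
            [
                LexicalEntry("stomach wall", "X:1", "label", 1.0),
                LexicalEntry("gastric mucosa", "X:2", "label", 1.0),
            ]
        )
        out = apply_thesaurus(lex, Thesaurus([("stomach", "gastric")]))
        assert set(lex.entries()) <= set(out.entries())
        assert {e.name for e in out.entries()} >= {"gastric wall", "stomach mucosa"}

    def test_identical_words_rejected(self):
        with pytest.raises(ValueError):
            Thesaurus([("stomach", "stomach")])
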