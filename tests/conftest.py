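"""Shared test fixtures: tiny hand-built ontologies and lexica."""

from __future__ import annotations

import pytest

from ontoalign import (
    Lexicon,
    LexicalEntry,
    MatchConfig,
    Ontology,
    build_lexicon,
)


@pytest.fixture()
def config() -> MatchConfig:
    return MatchConfig()


def make_ontology(prefix: str, terms: dict) -> Ontology:
    """Build an ontology from {class_id: {...}} term descriptions.

    Term keys: label, exact (list), other (list), is_a (list), part_of
    (list), xref (list), disjoint (list), obsolete (bool).
    """
    onto = Ontology(prefix=prefix)
    for cid in terms:
        onto.add_class(cid)
    for cid, spec in terms.items():
        if "label" in spec:
            onto.annotate(cid, "label", spec["label"])
        for text in spec.get("exact", ()):
            onto.annotate(cid, "hasExactSynonym", text)
        for text in spec.get("other", ()):
            onto.annotate(cid, "hasRelatedSynonym", text)
        for parent in spec.get("is_a", ()):
            onto.relationships.add_subclass(cid, parent)
        for whole in spec.get("part_of", ()):
            onto.relationships.add_property(cid, "part_of", whole)
        for curie in spec.get("xref", ()):
            onto.add_xref(cid, curie)
        for other in spec.get("disjoint", ()):
            onto.relationships.add_disjoint(cid, other)
        if spec.get("obsolete"):
            onto.mark_obsolete(cid)
    return onto


def single_name_lexicon(prefix: str, names: dict[str, str]) -> Lexicon:
    """Lexicon with one label entry per class: {class_id: name}."""
    return Lexicon(
        LexicalEntry(name, cid, "label", 1.0) for cid, name in names.items()
    )


@pytest.fixture()
def gum_case() -> tuple:
    """The gingiva/gum homonymy scenario: label-label beats label-synonym."""
    onto_a = make_ontology(
        "FMA", {"FMA:59762": {"label": "gingiva", "exact": ["gum"]}}
    )
    onto_b = make_ontology(
        "NCI",
        {
            "NCI:gingiva": {"label": "gingiva"},
            "NCI:gumdrug": {"label": "gum"},
        },
    )
    return build_lexicon(onto_a), build_lexicon(onto_b)
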