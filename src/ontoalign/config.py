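"""Configuration for lexicon weighting, synonym derivation and matching.

All tunables that the matching pipeline depends on live here so they can be
overridden from a YAML file or from the CLI.  The defaults encode the usual
practice for weighted lexical matching of biomedical ontologies: primary
names (labels and word-like local names) are fully trusted, exact synonyms
slightly less, and broad/narrow/related synonyms less still, so that
label-to-label mappings outscore mappings involving synonyms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping as TMapping

import yaml

#: Lexical categories, from most to least reliable.
CATEGORIES = ("localName", "label", "exactSynonym", "otherSynonym")

#: Default mapping from annotation property tags to lexical categories.
#: Tags not listed here are ignored (with a logged count) when building a
#: lexicon.  The table is deliberately wide: it covers the OBO flat-file
#: tags, the oboInOwl/SKOS properties and the NCI-style FULLSYN.
DEFAULT_PROPERTY_CATEGORIES: dict[str, str] = {
    "label": "label",
    "name": "label",
    "prefLabel": "label",
    "rdfs:label": "label",
    "skos:prefLabel": "label",
    "hasExactSynonym": "exactSynonym",
    "oboInOwl:hasExactSynonym": "exactSynonym",
    "exact_synonym": "exactSynonym",
    "FULLSYN": "exactSynonym",
    "skos:altLabel": "exactSynonym",
    "hasRelatedSynonym": "otherSynonym",
    "hasBroadSynonym": "otherSynonym",
    "hasNarrowSynonym": "otherSynonym",
    "oboInOwl:hasRelatedSynonym": "otherSynonym",
    "oboInOwl:hasBroadSynonym": "otherSynonym",
    "oboInOwl:hasNarrowSynonym": "otherSynonym",
    "synonym": "otherSynonym",
    "related_synonym": "otherSynonym",
}

#: Default stop words.  Small and editable on purpose; "structure" and "of"
#: cover the SNOMED-style "structure of X" naming convention.
DEFAULT_STOPWORDS = (
    "of",
    "the",
    "a",
    "an",
    "structure",
    "entire",
    "set",
    "region",
    "portion",
)

#: Formula detection: an intra-token letter/digit boundary ("C20H25N3O") or
#: an opening parenthesis glued to the preceding token ("Fe(III)").
DEFAULT_FORMULA_PATTERN = r"[A-Za-z][0-9]|[0-9][A-Za-z]|\S\("

#: Matcher provenance tags ordered from most to least precise; used for the
#: hierarchical combination order and for deterministic tie-breaking.
PROVENANCE_RANK: dict[str, int] = {
    "lexical": 0,
    "xref": 1,
    "mediating": 2,
    "logicaldef": 3,
    "thesaurus": 4,
    "word": 5,
    "string": 6,
    "string-local": 6,
    "unknown": 9,
}


def provenance_rank(tag: str) -> int:
    return PROVENANCE_RANK.get(tag, PROVENANCE_RANK["unknown"])


@dataclass(frozen=True)
class MatchConfig:
    """Bundle of all tunable parameters.

    Attributes
    ----------
    category_weights:
        Score in (0, 1] per lexical category.
    derivation_penalty:
        Multiplicative penalty applied to each synonym-derivation step
        (stop-word removal, parenthetical removal, thesaurus substitution,
        background-knowledge expansion).
    stopwords:
        Stop-word list used to mint reduced synonyms.
    leading_stopwords_only:
        If True, only leading stop words are stripped; by default internal
        stop words are removed as well.
    property_categories:
        Annotation property tag -> lexical category table.
    formula_pattern:
        Regular expression deciding whether a raw name is a formula.
    storage_threshold:
        Minimum similarity stored in an alignment (sparse-matrix cut-off).
    word_threshold / string_threshold:
        Acceptance thresholds of the word-overlap and string matchers.
    local_radius:
        Neighbourhood radius (hops over subclass and part-of edges, both
        directions) of the seed-local string matcher.
    xref_weight:
        Similarity assigned to cross-reference anchors.
    logicaldef_similarity:
        Similarity assigned to logical-definition mappings.
    xref_lexical_coverage_factor:
        Lexical anchors supplement cross-reference anchors for one input
        ontology only when they cover at least this multiple of the classes
        the cross-references cover.
    bk_preselect_threshold / bk_add_threshold:
        Mapping-gain thresholds of the two background-knowledge selection
        stages.
    gain_denominator:
        "baseline" (default) or "candidate": denominator of the mapping
        gain ratio.
    hybrid_threshold:
        Score above which the hybrid selector keeps conflicting mappings.
    """

    category_weights: TMapping[str, float] = field(
        default_factory=lambda: {
            "localName": 1.0,
            "label": 1.0,
            "exactSynonym": 0.95,
            "otherSynonym": 0.85,
        }
    )
    derivation_penalty: float = 0.9
    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS
    leading_stopwords_only: bool = False
    property_categories: TMapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_CATEGORIES)
    )
    formula_pattern: str = DEFAULT_FORMULA_PATTERN
    storage_threshold: float = 0.5
    word_threshold: float = 0.6
    string_threshold: float = 0.6
    local_radius: int = 2
    xref_weight: float = 0.99
    logicaldef_similarity: float = 0.90
    xref_lexical_coverage_factor: float = 2.0
    bk_preselect_threshold: float = 0.02
    bk_add_threshold: float = 0.02
    gain_denominator: str = "baseline"
    hybrid_threshold: float = 0.75

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            w = self.category_weights.get(cat)
            if w is None or not 0.0 < w <= 1.0:
                raise ValueError(f"weight for category {cat!r} must be in (0,1]")
        if not 0.0 < self.derivation_penalty <= 1.0:
            raise ValueError("derivation_penalty must be in (0,1]")
        if self.gain_denominator not in ("baseline", "candidate"):
            raise ValueError("gain_denominator must be 'baseline' or 'candidate'")

    def with_uniform_weights(self) -> "MatchConfig":
        """Variant with all category weights set to 1.0 (unweighted mode)."""
        return replace(
            self, category_weights={cat: 1.0 for cat in CATEGORIES}
        )

    @classmethod
    def from_yaml(cls, path: str) -> "MatchConfig":
        """Load overrides from a YAML key-value file.

        Keys mirror the dataclass fields; ``category_weights``,
        ``property_categories`` and ``stopwords`` replace the defaults
        wholesale when given.
        """
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        kwargs: dict = {}
        for key, value in data.items():
            if key == "stopwords":
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


DEFAULT_CONFIG = MatchConfig()
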