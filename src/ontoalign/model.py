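"""Ontology data model: normalization, weighted lexicon, structure, synonyms.

The matching strategy implemented by this package is hash-based: every
lexical annotation of every class is normalized once at load time and stored
in a bidirectional weighted index (the :class:`Lexicon`), whose name-keyed
side allows average constant-time search.  Matching two ontologies then
amounts to probing one lexicon with the names of the other instead of
comparing all class pairs.

Structural information (subclass taxonomy, the part-of partonomy and any
other object properties, plus disjointness axioms) is held in the
:class:`RelationshipMap`, which supports distance-bounded transitive
queries used for local matching and for coherence repair.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping as TMapping, Optional

from .config import CATEGORIES, DEFAULT_CONFIG, MatchConfig

logger = logging.getLogger(__name__)

ORIGINS = ("original", "stopword", "parenthetical", "thesaurus", "expansion")


class EmptyNameError(ValueError):
    """Raised when a raw name normalizes to the empty string."""


# ---------------------------------------------------------------------------
# Name normalization
# ---------------------------------------------------------------------------

_DISALLOWED = re.compile(r"[^0-9A-Za-z()\- ]")
_CAMEL_BOUNDARY = re.compile(r"(?<=[a-z])(?=[A-Z])")
_MULTISPACE = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Normalize a word-based name for hash-based matching.

    Rules, applied in order: underscores and all characters other than
    letters, digits, parentheses and dash become spaces; a space is inserted
    wherever capitalization occurs inside a word (``"hasPart"`` ->
    ``"has part"`` after lower-casing); everything is lower-cased and
    whitespace is collapsed.  The function is idempotent.

    Raises
    ------
    EmptyNameError
        If nothing is left after normalization.
    """
    s = raw.replace("_", " ")
    s = _DISALLOWED.sub(" ", s)
    s = _CAMEL_BOUNDARY.sub(" ", s)
    s = s.lower()
    s = _MULTISPACE.sub(" ", s).strip()
    if not s:
        raise EmptyNameError(f"name {raw!r} is empty after normalization")
    return s


def is_formula(raw: str, pattern: str | None = None) -> bool:
    """Decide whether a raw name is a formula rather than a word-based name.

    Chemical and other formulas must not be word-normalized (``"Fe(III)"``
    would be mangled), so for them the only normalization applied is the
    replacement of underscores with spaces.  The default pattern flags an
    intra-token letter/digit boundary or a parenthesis glued to the
    preceding token; it is configurable because formula conventions vary
    between ontologies.
    """
    pat = pattern if pattern is not None else DEFAULT_CONFIG.formula_pattern
    return re.search(pat, raw) is not None


def canonical_name(raw: str, pattern: str | None = None) -> str:
    """Normalize ``raw`` unless it is a formula (then only ``_`` -> space)."""
    stripped = raw.strip()
    if not stripped:
        raise EmptyNameError(f"name {raw!r} is empty")
    if is_formula(stripped, pattern):
        s = _MULTISPACE.sub(" ", stripped.replace("_", " ")).strip()
        if not s:
            raise EmptyNameError(f"name {raw!r} is empty after normalization")
        return s
    return normalize_name(stripped)


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class LexicalEntry:
    """One normalized name attached to one class.

    ``weight`` reflects the reliability of the annotation the name came
    from; ``origin`` distinguishes original annotations from derived
    synonyms (stop-word/parenthetical reductions, thesaurus substitutions,
    background-knowledge expansions).
    """

    name: str
    class_id: str
    category: str
    weight: float
    origin: str = "original"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside (0,1]")


class Lexicon:
    """Bidirectional weighted index between normalized names and classes.

    The name-keyed side is the inverted index that makes hash-based
    matching linear: probing it is an average O(1) dictionary lookup.
    Both sides always hold exactly the same entries.  For a given
    (name, class) pair only the best entry is kept (highest weight, ties
    broken toward the earlier origin in :data:`ORIGINS`).
    """

    def __init__(self, entries: Iterable[LexicalEntry] = ()) -> None:
        self._by_name: dict[str, dict[str, LexicalEntry]] = {}
        self._by_class: dict[str, dict[str, LexicalEntry]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexicalEntry) -> bool:
        """Insert ``entry``; returns True if it was added or upgraded."""
        current = self._by_name.get(entry.name, {}).get(entry.class_id)
        if current is not None:
            better = entry.weight > current.weight or (
                entry.weight == current.weight
                and ORIGINS.index(entry.origin) < ORIGINS.index(current.origin)
            )
            if not better:
                return False
        self._by_name.setdefault(entry.name, {})[entry.class_id] = entry
        self._by_class.setdefault(entry.class_id, {})[entry.name] = entry
        return True

    # -- views --------------------------------------------------------------

    def names(self) -> Iterator[str]:
        return iter(self._by_name)

    def classes(self) -> Iterator[str]:
        return iter(self._by_class)

    def entries(self) -> Iterator[LexicalEntry]:
        for per_class in self._by_name.values():
            yield from per_class.values()

    def entries_for_name(self, name: str) -> tuple[LexicalEntry, ...]:
        return tuple(self._by_name.get(name, {}).values())

    def entries_for_class(self, class_id: str) -> tuple[LexicalEntry, ...]:
        return tuple(self._by_class.get(class_id, {}).values())

    def has_name(self, name: str) -> bool:
        return name in self._by_name

    @property
    def name_count(self) -> int:
        return len(self._by_name)

    @property
    def class_count(self) -> int:
        return len(self._by_class)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_name.values())

    def copy(self) -> "Lexicon":
        return Lexicon(self.entries())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Lexicon({len(self)} entries, {self.name_count} names, "
            f"{self.class_count} classes)"
        )


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


class RelationshipMap:
    """Structural store: subclass edges, object-property edges, disjointness.

    Subclass edges form the taxonomic backbone; property edges (notably
    ``part_of``) form the partonomy, which in anatomical ontologies is a
    second hierarchical backbone.  Transitive queries are reflexive-free
    and accept a maximum-distance bound.
    """

    def __init__(self) -> None:
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        self._prop_out: dict[str, set[tuple[str, str]]] = {}
        self._prop_in: dict[str, set[tuple[str, str]]] = {}
        self._disjoint: set[frozenset[str]] = set()

    # -- construction -------------------------------------------------------

    def add_subclass(self, child: str, parent: str) -> None:
        self._parents.setdefault(child, set()).add(parent)
        self._children.setdefault(parent, set()).add(child)

    def add_property(self, subject: str, prop: str, obj: str) -> None:
        self._prop_out.setdefault(subject, set()).add((prop, obj))
        self._prop_in.setdefault(obj, set()).add((prop, subject))

    def add_disjoint(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("a class cannot be disjoint with itself")
        self._disjoint.add(frozenset((a, b)))

    # -- queries ------------------------------------------------------------

    def parents(self, class_id: str) -> set[str]:
        return set(self._parents.get(class_id, ()))

    def children(self, class_id: str) -> set[str]:
        return set(self._children.get(class_id, ()))

    def subclass_edges(self) -> Iterator[tuple[str, str]]:
        for child, parents in self._parents.items():
            for parent in parents:
                yield child, parent

    def property_edges(self) -> Iterator[tuple[str, str, str]]:
        for subject, pairs in self._prop_out.items():
            for prop, obj in pairs:
                yield subject, prop, obj

    def ancestors(self, class_id: str, max_distance: Optional[int] = None) -> set[str]:
        """Transitive superclasses of ``class_id`` (reflexive-free)."""
        return self._bfs(class_id, max_distance, lambda c: self._parents.get(c, ()))

    def descendants(self, class_id: str, max_distance: Optional[int] = None) -> set[str]:
        return self._bfs(class_id, max_distance, lambda c: self._children.get(c, ()))

    def neighborhood(
        self,
        class_id: str,
        radius: int,
        properties: tuple[str, ...] = ("part_of",),
    ) -> set[str]:
        """Classes within ``radius`` hops over subclass and the given
        property edges, traversed in both directions; includes the class
        itself."""

        def step(c: str) -> Iterator[str]:
            yield from self._parents.get(c, ())
            yield from self._children.get(c, ())
            for prop, other in self._prop_out.get(c, ()):
                if prop in properties:
                    yield other
            for prop, other in self._prop_in.get(c, ()):
                if prop in properties:
                    yield other

        result = self._bfs(class_id, radius, step)
        result.add(class_id)
        return result

    def disjoint_pairs(self) -> set[frozenset[str]]:
        return set(self._disjoint)

    def are_disjoint(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._disjoint

    @staticmethod
    def _bfs(start: str, max_distance: Optional[int], step) -> set[str]:
        seen: set[str] = set()
        frontier = deque([(start, 0)])
        while frontier:
            node, dist = frontier.popleft()
            if max_distance is not None and dist >= max_distance:
                continue
            for nxt in step(node):
                if nxt not in seen and nxt != start:
                    seen.add(nxt)
                    frontier.append((nxt, dist + 1))
                elif nxt == start:
                    # reflexive-free: never report the start itself
                    continue
        return seen


# ---------------------------------------------------------------------------
# Logical definitions and the ontology container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicalDefinition:
    """OBO-style cross-product: genus plus (property, filler) differentia.

    Fillers are CURIEs into external ontologies; matching two definitions
    may require rewriting fillers through a cross-reference bridge first.
    """

    genus: Optional[str]
    differentia: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.genus is None and not self.differentia:
            raise ValueError("logical definition needs a genus or differentia")


@dataclass
class Ontology:
    """In-memory ontology: classes, annotations, xrefs, defs, structure."""

    prefix: str
    classes: set[str] = field(default_factory=set)
    annotations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    xrefs: dict[str, set[str]] = field(default_factory=dict)
    logical_defs: dict[str, LogicalDefinition] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    relationships: RelationshipMap = field(default_factory=RelationshipMap)

    def add_class(self, class_id: str) -> None:
        self.classes.add(class_id)

    def annotate(self, class_id: str, prop: str, text: str) -> None:
        if class_id not in self.classes:
            raise KeyError(f"unknown class {class_id!r}")
        self.annotations.setdefault(class_id, []).append((prop, text))

    def add_xref(self, class_id: str, curie: str) -> None:
        if class_id not in self.classes:
            raise KeyError(f"unknown class {class_id!r}")
        self.xrefs.setdefault(class_id, set()).add(curie)

    def set_logical_def(self, class_id: str, definition: LogicalDefinition) -> None:
        if class_id not in self.classes:
            raise KeyError(f"unknown class {class_id!r}")
        self.logical_defs[class_id] = definition

    def mark_obsolete(self, class_id: str) -> None:
        if class_id not in self.classes:
            raise KeyError(f"unknown class {class_id!r}")
        self.obsolete.add(class_id)

    def validate(self) -> None:
        """Check the container invariants; raises ValueError on violation."""
        for store in (self.annotations, self.xrefs, self.logical_defs):
            unknown = set(store) - self.classes
            if unknown:
                raise ValueError(f"entries for unknown classes: {sorted(unknown)}")
        if not self.obsolete <= self.classes:
            raise ValueError("obsolete set contains unknown classes")

    def local_name(self, class_id: str) -> str:
        """Local part of a class identifier (after the last ':', '#' or '/')."""
        for sep in ("#", "/", ":"):
            if sep in class_id:
                return class_id.rsplit(sep, 1)[1]
        return class_id


_CODE_PATTERN = re.compile(r"^[A-Za-z]*[_:\-]?\d+$")


def is_alphanumeric_code(local_name: str) -> bool:
    """True for OBO-style codes (prefix+digits) or names without letters."""
    if not re.search(r"[A-Za-z]", local_name):
        return True
    return _CODE_PATTERN.match(local_name) is not None


# ---------------------------------------------------------------------------
# Lexicon construction and synonym derivation
# ---------------------------------------------------------------------------


def build_lexicon(
    ontology: Ontology,
    config: MatchConfig = DEFAULT_CONFIG,
    weights: TMapping[str, float] | None = None,
) -> Lexicon:
    """Build the weighted lexicon of an ontology.

    Local names are included only when they are word-like (alphanumeric
    codes such as ``UBERON_0000948`` carry no lexical signal); labels and
    synonym annotations are mapped to their lexical category through the
    configured property table; obsolete classes are skipped entirely.
    Unknown annotation properties are ignored with a logged count.
    """
    weights = dict(weights) if weights is not None else dict(config.category_weights)
    table = config.property_categories
    lexicon = Lexicon()
    unknown_props = 0
    skipped_empty = 0
    for class_id in sorted(ontology.classes):
        if class_id in ontology.obsolete:
            continue
        local = ontology.local_name(class_id)
        if not is_alphanumeric_code(local):
            try:
                name = canonical_name(local, config.formula_pattern)
            except EmptyNameError:
                skipped_empty += 1
            else:
                lexicon.add(
                    LexicalEntry(name, class_id, "localName", weights["localName"])
                )
        for prop, text in ontology.annotations.get(class_id, ()):
            category = table.get(prop)
            if category is None:
                unknown_props += 1
                continue
            try:
                name = canonical_name(text, config.formula_pattern)
            except EmptyNameError:
                skipped_empty += 1
                logger.warning(
                    "skipping empty-normalized annotation %r of %s", text, class_id
                )
                continue
            lexicon.add(LexicalEntry(name, class_id, category, weights[category]))
    if unknown_props:
        logger.info("ignored %d annotations with unknown properties", unknown_props)
    if skipped_empty:
        logger.info("skipped %d annotations that normalized to nothing", skipped_empty)
    return lexicon


def _strip_stopwords(words: list[str], stopwords: set[str], leading_only: bool) -> list[str]:
    if leading_only:
        i = 0
        while i < len(words) and words[i] in stopwords:
            i += 1
        return words[i:]
    return [w for w in words if w not in stopwords]


_PARENTHETICAL = re.compile(r"\([^()]*\)")


def generate_reduced_synonyms(
    lexicon: Lexicon,
    config: MatchConfig = DEFAULT_CONFIG,
    stopwords: Iterable[str] | None = None,
) -> Lexicon:
    """Mint reduced synonyms by stop-word and parenthetical removal.

    For every word-like entry this adds (when distinct and non-empty) the
    name with stop words removed and the name with parenthesized sections
    removed, at a penalized weight.  The input lexicon is not modified;
    the returned lexicon is a superset of it.
    """
    stops = set(stopwords) if stopwords is not None else set(config.stopwords)
    if not stops:
        raise ValueError("stop-word list must be non-empty")
    out = lexicon.copy()
    for entry in sorted(lexicon.entries()):
        if is_formula(entry.name, config.formula_pattern):
            continue
        derived: list[tuple[str, str]] = []
        words = entry.name.split()
        reduced = _strip_stopwords(words, stops, config.leading_stopwords_only)
        if reduced and reduced != words:
            derived.append((" ".join(reduced), "stopword"))
        without_parens = _MULTISPACE.sub(" ", _PARENTHETICAL.sub(" ", entry.name)).strip()
        if without_parens and without_parens != entry.name:
            derived.append((without_parens, "parenthetical"))
        for name, origin in derived:
            if name == entry.name:
                continue
            out.add(
                LexicalEntry(
                    name,
                    entry.class_id,
                    entry.category,
                    entry.weight * config.derivation_penalty,
                    origin,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Thesaurus
# ---------------------------------------------------------------------------


class Thesaurus:
    """Set of unordered pairs of synonymous words."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("a word is not its own thesaurus synonym")
        self._pairs.add(frozenset((a, b)))

    def pairs(self) -> list[tuple[str, str]]:
        """Pairs as sorted tuples, in deterministic order."""
        return sorted(tuple(sorted(p)) for p in self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __bool__(self) -> bool:
        return bool(self._pairs)


def build_thesaurus(lexicon: Lexicon) -> Thesaurus:
    """Induce synonymous word pairs from the names of each class.

    Two multi-word names of the same class with the same word count that
    differ in exactly one position contribute the differing word pair
    (e.g. "stomach serosa" / "gastric serosa" -> (stomach, gastric)).
    """
    thesaurus = Thesaurus()
    for class_id in lexicon.classes():
        names = sorted(
            e.name.split()
            for e in lexicon.entries_for_class(class_id)
            if " " in e.name
        )
        for wa, wb in itertools.combinations(names, 2):
            if len(wa) != len(wb):
                continue
            diff = [(x, y) for x, y in zip(wa, wb) if x != y]
            if len(diff) == 1:
                thesaurus.add(*diff[0])
    return thesaurus


def apply_thesaurus(
    lexicon: Lexicon,
    thesaurus: Thesaurus,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Lexicon:
    """Mint new synonyms by single-word thesaurus substitution.

    For each entry containing a thesaurus word, an entry with all
    occurrences of that word replaced by its partner is added at a
    penalized weight.  Substitutions use one pair at a time and are applied
    only to the entries of the input lexicon, so derived names never chain
    through multiple pairs.  The output is a superset of the input.
    """
    out = lexicon.copy()
    substitutions: dict[str, list[str]] = {}
    for a, b in thesaurus.pairs():
        substitutions.setdefault(a, []).append(b)
        substitutions.setdefault(b, []).append(a)
    for entry in sorted(lexicon.entries()):
        words = entry.name.split()
        present = [w for w in set(words) if w in substitutions]
        for word in sorted(present):
            for replacement in substitutions[word]:
                new_name = " ".join(
                    replacement if w == word else w for w in words
                )
                if new_name == entry.name:
                    continue
                out.add(
                    LexicalEntry(
                        new_name,
                        entry.class_id,
                        entry.category,
                        entry.weight * config.derivation_penalty,
                        "thesaurus",
                    )
                )
    return out
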