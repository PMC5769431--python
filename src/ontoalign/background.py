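"""Background knowledge exploitation: mediators, cross-references,
lexical expansion, logical definitions, and mapping-gain selection.

A third ontology can bridge two input ontologies in several ways.  As a
*mediator*, both inputs are aligned to it lexically and the two anchor
alignments are intersected.  When the background ontology carries curated
*cross-references* into the inputs, those are used as anchors instead
(they are essentially manually curated mappings), supplemented with
lexical anchors only when the latter cover substantially more of an input
ontology.  Alternatively, the background ontology's names can be imported
as new synonyms of anchored input classes (*lexical expansion*).  Finally,
OBO *logical definitions* (genus + differentia referencing external
ontologies) allow purely semantic matches between classes whose names
share nothing, optionally after rewriting definition fillers through a
cross-reference bridge.

Candidate background sources are ranked and selected by *mapping gain*:
the relative number of new mappings their alignment would add to the
current baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import Alignment, Mapping
from .config import DEFAULT_CONFIG, MatchConfig
from .matchers import combine, lexical_match
from .model import Lexicon, LogicalDefinition, Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "BKSource",
    "mediating_match",
    "xref_match",
    "lexical_expansion",
    "mapping_gain",
    "select_bk",
    "build_bridge",
    "logicaldef_match",
    "LogicalDefinition",
]


@dataclass
class BKSource:
    """A candidate background knowledge source and its anchor alignments."""

    name: str
    ontology: Ontology
    lexicon: Lexicon
    anchors_a: Alignment = field(default_factory=Alignment)
    anchors_b: Alignment = field(default_factory=Alignment)
    alignment: Alignment = field(default_factory=Alignment)
    individual_gain: float = 0.0


def _intersect_anchors(
    anchors_a: Alignment, anchors_b: Alignment, provenance: str
) -> Alignment:
    """Derive an input-input alignment from two input-BK anchor alignments.

    (a, b) is mapped iff some background class u anchors both a and b; the
    similarity is the minimum of the two anchor scores, maximised over all
    such u.
    """
    out = Alignment()
    best: dict[tuple[str, str], float] = {}
    bk_to_a: dict[str, list[Mapping]] = {}
    for m in anchors_a:
        bk_to_a.setdefault(m.target, []).append(m)
    for mb in anchors_b:
        for ma in bk_to_a.get(mb.target, ()):
            pair = (ma.source, mb.source)
            sim = min(ma.similarity, mb.similarity)
            if sim > best.get(pair, -1.0):
                best[pair] = sim
    for (a, b), sim in best.items():
        out.add(Mapping(a, b, sim, provenance=provenance))
    return out


def mediating_match(lexA: Lexicon, lexB: Lexicon, bk: BKSource) -> Alignment:
    """Match through a mediator: lexical anchors to the BK, intersected."""
    bk.anchors_a = lexical_match(lexA, bk.lexicon)
    bk.anchors_b = lexical_match(lexB, bk.lexicon)
    return _intersect_anchors(bk.anchors_a, bk.anchors_b, "mediating")


def _resolve_xref(curie: str, ontology: Ontology) -> str | None:
    """Resolve a cross-reference CURIE to a class of ``ontology``."""
    if curie in ontology.classes:
        return curie
    for alt in (curie.replace(":", "_"), curie.replace("_", ":")):
        if alt in ontology.classes:
            return alt
    return None


def _xref_anchors(
    bk: BKSource, onto: Ontology, weight: float
) -> tuple[Alignment, int]:
    """Anchors (input class -> BK class) from the BK's cross-references."""
    anchors = Alignment()
    unresolved = 0
    for bk_class in sorted(bk.ontology.xrefs):
        for curie in sorted(bk.ontology.xrefs[bk_class]):
            resolved = _resolve_xref(curie, onto)
            if resolved is None:
                unresolved += 1
                continue
            anchors.add(Mapping(resolved, bk_class, weight, provenance="xref"))
    return anchors, unresolved


def xref_match(
    ontoA: Ontology,
    ontoB: Ontology,
    bk: BKSource,
    lexA: Lexicon | None = None,
    lexB: Lexicon | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """Match through the BK's cross-references into the input ontologies.

    Anchor score is the configured xref weight.  For each input ontology,
    lexical anchors are added as a supplement only when they cover at
    least ``config.xref_lexical_coverage_factor`` times as many classes of
    that ontology as the cross-references do.
    """
    anchors_a, miss_a = _xref_anchors(bk, ontoA, config.xref_weight)
    anchors_b, miss_b = _xref_anchors(bk, ontoB, config.xref_weight)
    if miss_a or miss_b:
        logger.info(
            "ignored %d unresolvable cross-references", miss_a + miss_b
        )
    for anchors, lex, label in ((anchors_a, lexA, "A"), (anchors_b, lexB, "B")):
        if lex is None:
            continue
        lexical = lexical_match(lex, bk.lexicon)
        xref_cover = len(anchors.sources())
        lex_cover = len(lexical.sources())
        if lex_cover >= config.xref_lexical_coverage_factor * xref_cover:
            logger.info(
                "side %s: lexical anchors (%d classes) supplement xrefs (%d)",
                label, lex_cover, xref_cover,
            )
            for m in lexical.sorted_mappings():
                anchors.add(m)
    bk.anchors_a, bk.anchors_b = anchors_a, anchors_b
    return _intersect_anchors(anchors_a, anchors_b, "xref")


def lexical_expansion(
    lexicon: Lexicon,
    bk_lexicon: Lexicon,
    anchors: Alignment,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Lexicon:
    """Import BK names as new synonyms of anchored input classes.

    Every input class anchored to a background class gains all that
    class's lexical entries as ``expansion``-origin synonyms at a
    penalized weight.  The input lexicon is not modified.
    """
    out = lexicon.copy()
    for m in anchors.sorted_mappings():
        for entry in bk_lexicon.entries_for_class(m.target):
            out.add(
                entry.__class__(
                    entry.name,
                    m.source,
                    entry.category,
                    entry.weight * config.derivation_penalty,
                    "expansion",
                )
            )
    return out


def mapping_gain(
    candidate: Alignment,
    baseline: Alignment,
    denominator: str = "baseline",
) -> float:
    """Relative number of new mappings ``candidate`` adds to ``baseline``.

    A mapping counts as new when its source class is unmapped in the
    baseline.  With an empty baseline the gain degenerates to the raw
    candidate size (documented convention).  ``denominator="candidate"``
    switches the ratio's denominator to the candidate size.
    """
    new = sum(1 for m in candidate if not baseline.contains_source(m.source))
    if denominator == "candidate":
        return new / len(candidate) if len(candidate) else 0.0
    if len(baseline) == 0:
        return float(len(candidate))
    return new / len(baseline)


def select_bk(
    candidates: list[BKSource],
    lexA: Lexicon,
    lexB: Lexicon,
    preselect_threshold: float | None = None,
    add_threshold: float | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
    ontoA: Ontology | None = None,
    ontoB: Ontology | None = None,
    info: str = "lexical",
) -> list[BKSource]:
    """Two-stage greedy selection of background sources by mapping gain.

    Stage 1 computes each candidate's alignment and keeps those whose
    individual gain over the lexical baseline reaches the preselection
    threshold.  Stage 2 walks the survivors in descending order of
    individual gain, recomputes the gain over the running baseline, and
    adds a source (unioning its alignment into the baseline) only when the
    recomputed gain reaches the addition threshold.  Candidate input order
    never affects the result: ties are broken by source name.
    """
    if preselect_threshold is None:
        preselect_threshold = config.bk_preselect_threshold
    if add_threshold is None:
        add_threshold = config.bk_add_threshold
    baseline = lexical_match(lexA, lexB)
    preselected: list[BKSource] = []
    for bk in sorted(candidates, key=lambda s: s.name):
        if info == "xref":
            if ontoA is None or ontoB is None:
                raise ValueError("xref selection requires the input ontologies")
            bk.alignment = xref_match(ontoA, ontoB, bk, lexA, lexB, config)
        else:
            bk.alignment = mediating_match(lexA, lexB, bk)
        bk.individual_gain = mapping_gain(
            bk.alignment, baseline, config.gain_denominator
        )
        if bk.individual_gain >= preselect_threshold:
            preselected.append(bk)
    preselected.sort(key=lambda s: (-s.individual_gain, s.name))
    selected: list[BKSource] = []
    running = baseline
    for bk in preselected:
        gain = mapping_gain(bk.alignment, running, config.gain_denominator)
        if gain >= add_threshold:
            selected.append(bk)
            running = combine(running, bk.alignment, "union")
    return selected


# ---------------------------------------------------------------------------
# Logical definitions
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self._parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self._parent.setdefault(x, x)
        if parent != x:
            self._parent[x] = parent = self.find(parent)
        return parent

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographic minimum
            lo, hi = sorted((ra, rb))
            self._parent[hi] = lo


def build_bridge(*ontologies: Ontology) -> dict[str, str]:
    """Cross-reference bridge: CURIE -> canonical representative.

    Every class of the given ontologies is unified with all its
    cross-references (read symmetrically), so fillers referring to
    equivalent external classes rewrite to the same representative.
    """
    uf = _UnionFind()
    for onto in ontologies:
        for class_id in sorted(onto.xrefs):
            for curie in sorted(onto.xrefs[class_id]):
                uf.union(class_id, curie)
    return {x: uf.find(x) for x in sorted(uf._parent)}


def _canonical_def(
    definition: LogicalDefinition, bridge: dict[str, str]
) -> tuple:
    def canon(curie: str) -> str:
        return bridge.get(curie, curie)

    genus = canon(definition.genus) if definition.genus else None
    differentia = frozenset(
        (prop, canon(filler)) for prop, filler in definition.differentia
    )
    return (genus, differentia)


def logicaldef_match(
    ontoA: Ontology,
    ontoB: Ontology,
    bridge: dict[str, str] | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """Match classes with identical logical definitions.

    Definitions are compared as (genus, {(property, filler)}) after
    rewriting every filler through the cross-reference bridge, so
    definitions pointing at cross-referenced external classes still
    compare equal.  Mappings carry a fixed configured similarity.
    """
    bridge = bridge or {}
    by_def: dict[tuple, list[str]] = {}
    skipped = 0
    for class_id in sorted(ontoA.logical_defs):
        if class_id in ontoA.obsolete:
            continue
        try:
            key = _canonical_def(ontoA.logical_defs[class_id], bridge)
        except ValueError:
            skipped += 1
            continue
        by_def.setdefault(key, []).append(class_id)
    alignment = Alignment()
    for class_id in sorted(ontoB.logical_defs):
        if class_id in ontoB.obsolete:
            continue
        try:
            key = _canonical_def(ontoB.logical_defs[class_id], bridge)
        except ValueError:
            skipped += 1
            continue
        for a in by_def.get(key, ()):
            alignment.add(
                Mapping(
                    a,
                    class_id,
                    config.logicaldef_similarity,
                    provenance="logicaldef",
                )
            )
    if skipped:
        logger.info("skipped %d unusable logical definitions", skipped)
    return alignment
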