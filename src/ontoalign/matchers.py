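"""Matching algorithms producing scored candidate alignments.

The workhorses are hash-based: :func:`lexical_match` probes the name index
of the larger lexicon with each name of the smaller one, so its cost is
linear in the number of distinct names.  :func:`quadratic_lexical_match` is
a functionally identical oracle that performs all pairwise equality
comparisons instead; it exists to validate the hash-based matcher and to
expose the quadratic comparison count for scaling analyses.

String similarity (ISub) cannot be hash-indexed, so it is either applied
globally (small problems only) or locally, in the neighbourhood of seed
mappings found by the reliable hash-based matchers.

Every matcher records its work in ``alignment.stats`` (e.g.
``hash_searches``, ``pairwise_comparisons``, ``isub_comparisons``).
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np

from .alignment import Alignment, Mapping
from .config import DEFAULT_CONFIG, MatchConfig
from .isub import isub
from .model import Lexicon, Ontology, Thesaurus, apply_thesaurus

__all__ = [
    "lexical_match",
    "quadratic_lexical_match",
    "word_match",
    "string_match_global",
    "string_match_local",
    "thesaurus_match",
    "combine",
]


# ---------------------------------------------------------------------------
# Full-name matching
# ---------------------------------------------------------------------------


def lexical_match(
    lexA: Lexicon,
    lexB: Lexicon,
    threshold: float = 0.0,
    provenance: str = "lexical",
) -> Alignment:
    """Literal full-name matching through the inverted name index.

    A pair (a, b) is mapped iff some normalized name is shared by class a
    in A and class b in B; its similarity is the maximum over shared names
    of the product of the two entry weights.  Only the names of the smaller
    lexicon are iterated; each is a single hash probe into the other.
    """
    alignment = Alignment(threshold=threshold)
    searches = 0
    a_is_probe = lexA.name_count <= lexB.name_count
    probe, index = (lexA, lexB) if a_is_probe else (lexB, lexA)
    best: dict[tuple[str, str], float] = {}
    for name in probe.names():
        searches += 1
        hits = index.entries_for_name(name)
        if not hits:
            continue
        for pe in probe.entries_for_name(name):
            for ie in hits:
                if a_is_probe:
                    pair = (pe.class_id, ie.class_id)
                else:
                    pair = (ie.class_id, pe.class_id)
                sim = pe.weight * ie.weight
                if sim > best.get(pair, -1.0):
                    best[pair] = sim
    for (source, target), sim in best.items():
        alignment.add(Mapping(source, target, sim, provenance=provenance))
    alignment.stats["hash_searches"] = searches
    return alignment


def quadratic_lexical_match(
    lexA: Lexicon,
    lexB: Lexicon,
    threshold: float = 0.0,
    provenance: str = "lexical",
) -> Alignment:
    """Pairwise-comparison oracle for :func:`lexical_match`.

    Compares every entry of A with every entry of B for name equality and
    reports the comparison count (|entriesA| x |entriesB|).  The equality
    comparisons are carried out as vectorised integer-code comparisons, but
    no index is consulted: the output derives from pairwise equality alone.
    """
    alignment = Alignment(threshold=threshold)
    entriesA = sorted(lexA.entries())
    entriesB = sorted(lexB.entries())
    alignment.stats["pairwise_comparisons"] = len(entriesA) * len(entriesB)
    if not entriesA or not entriesB:
        return alignment
    vocab: dict[str, int] = {}
    def code(name: str) -> int:
        return vocab.setdefault(name, len(vocab))
    codesA = np.array([code(e.name) for e in entriesA])
    codesB = np.array([code(e.name) for e in entriesB])
    best: dict[tuple[str, str], float] = {}
    # block over A to bound the boolean matrix size
    block = max(1, 10_000_000 // max(1, len(entriesB)))
    for start in range(0, len(entriesA), block):
        eq = codesA[start : start + block, None] == codesB[None, :]
        for i, j in zip(*np.nonzero(eq)):
            ea = entriesA[start + int(i)]
            eb = entriesB[int(j)]
            pair = (ea.class_id, eb.class_id)
            sim = ea.weight * eb.weight
            if sim > best.get(pair, -1.0):
                best[pair] = sim
    for (source, target), sim in best.items():
        alignment.add(Mapping(source, target, sim, provenance=provenance))
    return alignment


# ---------------------------------------------------------------------------
# Word overlap
# ---------------------------------------------------------------------------


def _jaccard(wa: frozenset[str], wb: frozenset[str]) -> float:
    inter = len(wa & wb)
    if not inter:
        return 0.0
    return inter / len(wa | wb)


def word_match(
    lexA: Lexicon,
    lexB: Lexicon,
    threshold: float | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """Word-overlap matching through a word-keyed inverted index.

    Candidate pairs are found by sharing at least one word (no all-pairs
    scan); each candidate is scored by the best name pair under a weighted
    Jaccard overlap of the name word-sets, weighted by the entry weights.
    """
    if threshold is None:
        threshold = config.word_threshold
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    alignment = Alignment(threshold=threshold)
    # index B names by word
    by_word: dict[str, set[tuple[str, str]]] = {}
    b_words: dict[str, frozenset[str]] = {}
    for eb in lexB.entries():
        words = frozenset(eb.name.split())
        b_words[eb.name] = words
        for w in words:
            by_word.setdefault(w, set()).add((eb.class_id, eb.name))
    lookups = 0
    best: dict[tuple[str, str], float] = {}
    for ea in lexA.entries():
        wa = frozenset(ea.name.split())
        candidates: set[tuple[str, str]] = set()
        for w in wa:
            lookups += 1
            candidates |= by_word.get(w, set())
        for b_class, b_name in candidates:
            overlap = _jaccard(wa, b_words[b_name])
            if overlap <= 0.0:
                continue
            for eb in lexB.entries_for_name(b_name):
                if eb.class_id != b_class:
                    continue
                sim = overlap * ea.weight * eb.weight
                pair = (ea.class_id, b_class)
                if sim > best.get(pair, -1.0):
                    best[pair] = sim
    for (source, target), sim in best.items():
        alignment.add(Mapping(source, target, sim, provenance="word"))
    alignment.stats["word_lookups"] = lookups
    return alignment


# ---------------------------------------------------------------------------
# String matching
# ---------------------------------------------------------------------------


def _score_class_pair(
    entriesA: Iterable, entriesB: Iterable
) -> tuple[float, int]:
    """Best weighted ISub over the name pairs of two classes."""
    best = 0.0
    comparisons = 0
    for ea, eb in itertools.product(entriesA, entriesB):
        comparisons += 1
        sim = isub(ea.name, eb.name) * ea.weight * eb.weight
        if sim > best:
            best = sim
    return best, comparisons


def string_match_global(
    lexA: Lexicon,
    lexB: Lexicon,
    threshold: float | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """ISub string matching over all cross-ontology class pairs.

    Quadratic in the number of classes; intended for small problems and as
    the reference superset of :func:`string_match_local`.
    """
    if threshold is None:
        threshold = config.string_threshold
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    alignment = Alignment(threshold=threshold)
    comparisons = 0
    classesA = sorted(lexA.classes())
    classesB = sorted(lexB.classes())
    for a in classesA:
        ea = lexA.entries_for_class(a)
        for b in classesB:
            sim, n = _score_class_pair(ea, lexB.entries_for_class(b))
            comparisons += n
            if sim >= threshold:
                alignment.add(Mapping(a, b, sim, provenance="string"))
    alignment.stats["isub_comparisons"] = comparisons
    return alignment


def string_match_local(
    seed: Alignment,
    ontoA: Ontology,
    ontoB: Ontology,
    lexA: Lexicon,
    lexB: Lexicon,
    radius: int | None = None,
    threshold: float | None = None,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """ISub string matching restricted to the vicinity of seed mappings.

    Only pairs (a, b) with a within ``radius`` hops (subclass or part-of,
    either direction) of a seed source and b within ``radius`` hops of the
    corresponding seed target are scored; scoring is identical to
    :func:`string_match_global` on that restricted set, so the result is
    always a subset of the global alignment at the same threshold.
    """
    if radius is None:
        radius = config.local_radius
    if threshold is None:
        threshold = config.string_threshold
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    alignment = Alignment(threshold=threshold)
    candidate_pairs: set[tuple[str, str]] = set()
    for m in seed.sorted_mappings():
        neighA = ontoA.relationships.neighborhood(m.source, radius)
        neighB = ontoB.relationships.neighborhood(m.target, radius)
        neighA &= set(ontoA.classes) - ontoA.obsolete
        neighB &= set(ontoB.classes) - ontoB.obsolete
        candidate_pairs.update(itertools.product(neighA, neighB))
    comparisons = 0
    for a, b in sorted(candidate_pairs):
        sim, n = _score_class_pair(
            lexA.entries_for_class(a), lexB.entries_for_class(b)
        )
        comparisons += n
        if sim >= threshold:
            alignment.add(Mapping(a, b, sim, provenance="string-local"))
    alignment.stats["isub_comparisons"] = comparisons
    alignment.stats["candidate_pairs"] = len(candidate_pairs)
    return alignment


# ---------------------------------------------------------------------------
# Thesaurus matching
# ---------------------------------------------------------------------------


def thesaurus_match(
    lexA: Lexicon,
    lexB: Lexicon,
    thesA: Thesaurus,
    thesB: Thesaurus,
    threshold: float = 0.0,
    config: MatchConfig = DEFAULT_CONFIG,
) -> Alignment:
    """Full-name matching on thesaurus-augmented lexica.

    Equals :func:`lexical_match` on the augmented lexica, restricted to
    mappings that involve at least one thesaurus-origin entry through some
    shared name.
    """
    augA = apply_thesaurus(lexA, thesA, config)
    augB = apply_thesaurus(lexB, thesB, config)
    full = lexical_match(augA, augB, threshold=threshold, provenance="thesaurus")
    alignment = Alignment(threshold=threshold)
    for m in full:
        involved = False
        for ea in augA.entries_for_class(m.source):
            for eb in augB.entries_for_class(m.target):
                if ea.name == eb.name and (
                    ea.origin == "thesaurus" or eb.origin == "thesaurus"
                ):
                    involved = True
                    break
            if involved:
                break
        if involved:
            alignment.add(m)
    alignment.stats.update(full.stats)
    return alignment


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------


def combine(primary: Alignment, secondary: Alignment, mode: str = "union") -> Alignment:
    """Combine two preliminary alignments.

    ``union`` keeps the highest score per pair (with the provenance of the
    winning matcher); ``hierarchical`` adds a secondary mapping only when
    neither of its endpoints is already mapped in the primary alignment,
    so less precise matchers never conflict with more precise ones.
    """
    if mode not in ("union", "hierarchical"):
        raise ValueError(f"unknown combination mode {mode!r}")
    out = Alignment(threshold=min(primary.threshold, secondary.threshold))
    for m in primary.sorted_mappings():
        out.add(m)
    if mode == "union":
        for m in secondary.sorted_mappings():
            out.add(m)
    else:
        for m in secondary.sorted_mappings():
            if primary.contains_source(m.source) or primary.contains_target(m.target):
                continue
            out.add(m)
    for stats in (primary.stats, secondary.stats):
        for key, value in stats.items():
            out.stats[key] = out.stats.get(key, 0) + value
    return out
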