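"""Alignment filtering: cardinality selection and coherence repair.

Selection walks the candidate mappings in descending similarity (with a
deterministic total order) and resolves cardinality conflicts according to
one of three modes: ``strict`` enforces a 1:1 alignment, ``permissive``
keeps conflicting mappings only on exact score ties, and ``hybrid``
additionally keeps conflicting pairs when both scores exceed a high
threshold (0.75 by default).

Repair works on a propositional projection of the merged ontologies:
subclass edges and equivalence mappings become implications (the latter in
both directions) and disjointness axioms become mutual-exclusion clauses.
A class is unsatisfiable when it implies two disjoint classes.  Minimal
conflicting mapping sets are extracted per unsatisfiable class, and a
greedy weighted-vertex-cover heuristic repeatedly removes the mapping that
occurs in the most conflict sets (lowest score first on ties) until the
projection is coherent.  Only mappings are ever removed, never ontology
axioms.  Modularization restricts the satisfiability tests to the classes
that can actually influence the verdict: those with multiple parents
under the projection, mapped classes, and classes under a disjointness
clause.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .alignment import Alignment, Mapping
from .config import provenance_rank
from .model import Ontology

__all__ = [
    "select",
    "Projection",
    "project",
    "modularize",
    "ConflictSet",
    "find_conflicts",
    "is_coherent",
    "repair",
]


# ---------------------------------------------------------------------------
# Cardinality selection
# ---------------------------------------------------------------------------


def select(
    candidates: Alignment,
    mode: str = "permissive",
    hybrid_threshold: float = 0.75,
) -> Alignment:
    """Resolve cardinality conflicts by greedy descending-score selection.

    A strict 1:1 core is selected first by walking the candidates in the
    deterministic total order (score desc, provenance precision,
    lexicographic) and keeping every mapping whose endpoints are still
    free.  ``strict`` returns that core.  ``permissive`` additionally
    admits mappings all of whose conflicts with the core are exact score
    ties; ``hybrid`` also admits mappings whose every conflict with the
    core has both scores above the hybrid threshold.  The permissive and
    hybrid outputs are therefore supersets of the strict output, and the
    result is deterministic for identical inputs.
    """
    if mode not in ("strict", "permissive", "hybrid"):
        raise ValueError(f"unknown selection mode {mode!r}")
    ordered = candidates.sorted_mappings()
    core = Alignment(threshold=candidates.threshold)
    for m in ordered:
        if not core.contains_source(m.source) and not core.contains_target(m.target):
            core.add(m)
    if mode == "strict":
        return core
    out = core.copy()
    for m in ordered:
        if m.pair in core:
            continue
        conflicting = [
            core.get(m.source, t) for t in core.targets_of(m.source)
        ] + [core.get(s, m.target) for s in core.sources_of(m.target)]
        if all(c.similarity == m.similarity for c in conflicting):
            out.add(m)
        elif mode == "hybrid" and m.similarity > hybrid_threshold and all(
            c.similarity > hybrid_threshold for c in conflicting
        ):
            out.add(m)
    return out


# ---------------------------------------------------------------------------
# Propositional projection
# ---------------------------------------------------------------------------


@dataclass
class Projection:
    """Propositional model of the merged ontologies plus an alignment.

    ``implications`` holds the ontology-axiom edges only; mapping-derived
    implications are kept separately (``mapping_edges``) so that
    entailment can be queried under any subset of the mappings.
    """

    implications: dict[str, set[str]]
    disjoint: set[frozenset[str]]
    mappings: list[Mapping]
    classes: set[str]

    def mapping_adjacency(
        self, active: set[Mapping] | None = None
    ) -> dict[str, set[tuple[str, Mapping]]]:
        adj: dict[str, set[tuple[str, Mapping]]] = {}
        for m in self.mappings:
            if active is not None and m not in active:
                continue
            adj.setdefault(m.source, set()).add((m.target, m))
            adj.setdefault(m.target, set()).add((m.source, m))
        return adj

    def reachable(
        self, start: str, active: set[Mapping] | None = None
    ) -> set[str]:
        """Classes implied by ``start`` (reflexive), using ontology
        implications plus the active mappings (default: all)."""
        adj = self.mapping_adjacency(active)
        seen = {start}
        frontier = deque([start])
        while frontier:
            node = frontier.popleft()
            for nxt in self.implications.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
            for nxt, _m in adj.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        return seen

    def unsatisfiable(
        self, class_id: str, active: set[Mapping] | None = None
    ) -> bool:
        implied = self.reachable(class_id, active)
        return any(pair <= implied for pair in self.disjoint)


def project(ontoA: Ontology, ontoB: Ontology, alignment: Alignment) -> Projection:
    """Project the two ontologies and the alignment to propositional logic.

    Subclass edges become implications, each equivalence mapping becomes a
    bidirectional implication, and disjointness pairs become
    mutual-exclusion clauses.  Part-of and other object properties do not
    enter the coherence model.
    """
    implications: dict[str, set[str]] = {}
    disjoint: set[frozenset[str]] = set()
    classes: set[str] = set()
    for onto in (ontoA, ontoB):
        classes |= onto.classes
        for child, parent in onto.relationships.subclass_edges():
            implications.setdefault(child, set()).add(parent)
        disjoint |= onto.relationships.disjoint_pairs()
    return Projection(
        implications=implications,
        disjoint=disjoint,
        mappings=list(alignment.sorted_mappings()),
        classes=classes,
    )


def modularize(model: Projection) -> tuple[list[str], list[str]]:
    """Restrict coherence checking to the classes that can matter.

    Returns ``(check_list, search_list)``.  The search list contains the
    classes with more than one parent under the projection (counting
    mapping edges), the mapped classes, and the classes occurring in
    disjointness clauses; any unsatisfiable class entails an
    unsatisfiable class in the search list, so testing it suffices.  The
    check list is the union of the modules reachable from the search
    list.
    """
    out_degree: dict[str, int] = {}
    for child, parents in model.implications.items():
        out_degree[child] = out_degree.get(child, 0) + len(parents)
    search: set[str] = set()
    for m in model.mappings:
        search.add(m.source)
        search.add(m.target)
        out_degree[m.source] = out_degree.get(m.source, 0) + 1
        out_degree[m.target] = out_degree.get(m.target, 0) + 1
    for node, degree in out_degree.items():
        if degree > 1:
            search.add(node)
    for pair in model.disjoint:
        search |= pair
    check: set[str] = set()
    for node in search:
        check |= model.reachable(node)
    return sorted(check), sorted(search)


# ---------------------------------------------------------------------------
# Conflicts and repair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConflictSet:
    """A minimal set of mappings making ``unsat_class`` unsatisfiable.

    Minimality: removing any single mapping from the set breaks the
    entailment of the two disjoint superclasses.
    """

    unsat_class: str
    mappings: frozenset[Mapping]


def _shortest_path_mappings(
    model: Projection, start: str, goal: str
) -> frozenset[Mapping] | None:
    """Mappings used on a BFS shortest implication path start -> goal."""
    if start == goal:
        return frozenset()
    adj = model.mapping_adjacency()
    parent: dict[str, tuple[str, Mapping | None]] = {start: (start, None)}
    frontier = deque([start])
    while frontier:
        node = frontier.popleft()
        steps: list[tuple[str, Mapping | None]] = [
            (nxt, None) for nxt in sorted(model.implications.get(node, ()))
        ] + sorted(adj.get(node, ()), key=lambda t: (t[0], t[1].sort_key()))
        for nxt, used in steps:
            if nxt in parent:
                continue
            parent[nxt] = (node, used)
            if nxt == goal:
                mappings = set()
                cur = goal
                while cur != start:
                    prev, m = parent[cur]
                    if m is not None:
                        mappings.add(m)
                    cur = prev
                return frozenset(mappings)
            frontier.append(nxt)
    return None


def _entails(model: Projection, c: str, d1: str, d2: str, active: set[Mapping]) -> bool:
    implied = model.reachable(c, active)
    return d1 in implied and d2 in implied


def _minimize(
    model: Projection, c: str, d1: str, d2: str, candidate: frozenset[Mapping]
) -> frozenset[Mapping]:
    current = set(candidate)
    for m in sorted(candidate, key=Mapping.sort_key):
        trial = current - {m}
        if _entails(model, c, d1, d2, trial):
            current = trial
    return frozenset(current)


def find_conflicts(model: Projection, use_modules: bool = True) -> list[ConflictSet]:
    """Minimal conflict sets for every unsatisfiable class of the model.

    Conflicts that involve no mapping at all (the input ontologies are
    incoherent on their own) cannot be repaired by mapping removal and are
    not reported.
    """
    if use_modules:
        _, search = modularize(model)
    else:
        search = sorted(model.classes)
    conflicts: list[ConflictSet] = []
    seen: set[tuple[str, frozenset[Mapping]]] = set()
    for c in search:
        implied = model.reachable(c)
        for pair in sorted(model.disjoint, key=sorted):
            if not pair <= implied:
                continue
            d1, d2 = sorted(pair)
            path1 = _shortest_path_mappings(model, c, d1)
            path2 = _shortest_path_mappings(model, c, d2)
            if path1 is None or path2 is None:
                continue
            candidate = path1 | path2
            if not candidate:
                continue  # incoherence not caused by the alignment
            minimal = _minimize(model, c, d1, d2, candidate)
            if not minimal:
                continue
            key = (c, minimal)
            if key not in seen:
                seen.add(key)
                conflicts.append(ConflictSet(c, minimal))
    return conflicts


def is_coherent(model: Projection, use_modules: bool = False) -> bool:
    """Zero unsatisfiable classes?  Defaults to the full, unmodularized
    check so it can serve as the independent oracle."""
    if use_modules:
        _, search = modularize(model)
    else:
        search = sorted(model.classes)
    return not any(model.unsatisfiable(c) for c in search)


def repair(alignment: Alignment, ontoA: Ontology, ontoB: Ontology) -> Alignment:
    """Remove mappings until the propositional projection is coherent.

    Greedy heuristic: repeatedly drop the mapping occurring in the most
    conflict sets (lowest score first on ties, then provenance, then
    lexicographic), recomputing conflicts after each removal.  The result
    is a subset of the input; ontology axioms are never touched.
    """
    current = alignment.copy()
    while True:
        model = project(ontoA, ontoB, current)
        conflicts = find_conflicts(model)
        if not conflicts:
            return current
        counts: dict[Mapping, int] = {}
        for conflict in conflicts:
            for m in conflict.mappings:
                counts[m] = counts.get(m, 0) + 1
        victim = min(
            counts,
            key=lambda m: (
                -counts[m],
                m.similarity,
                -provenance_rank(m.provenance),
                m.source,
                m.target,
            ),
        )
        current.discard(victim)
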