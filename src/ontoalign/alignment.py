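"""Scored correspondences and the sparse alignment container.

An :class:`Alignment` is the sparse similarity matrix of the matching
problem: only scores above a storage threshold are kept, held both as a
mapping list (for sorting and selection) and as dual hash indices by
source and by target (for average constant-time lookup).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .config import provenance_rank


@dataclass(frozen=True)
class Mapping:
    """An equivalence correspondence between one class of each ontology."""

    source: str
    target: str
    similarity: float
    relation: str = "="
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [0,1]")
        if self.source == self.target:
            raise ValueError("source and target must be different classes")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)

    def sort_key(self) -> tuple:
        """Total order: score desc, provenance precision, lexicographic."""
        return (
            -self.similarity,
            provenance_rank(self.provenance),
            self.source,
            self.target,
        )


class Alignment:
    """Set of mappings with dual O(1) indices and a storage threshold.

    At most one mapping is kept per (source, target) pair: on duplicate
    insertion the higher-scored mapping wins (ties keep the more precise
    provenance, then the incumbent).
    """

    def __init__(
        self,
        mappings: Iterable[Mapping] = (),
        threshold: float = 0.0,
    ) -> None:
        self.threshold = threshold
        self._by_pair: dict[tuple[str, str], Mapping] = {}
        self._by_source: dict[str, set[str]] = {}
        self._by_target: dict[str, set[str]] = {}
        #: counters attached by matchers (hash searches, comparisons, ...)
        self.stats: dict[str, int] = {}
        for m in mappings:
            self.add(m)

    def add(self, mapping: Mapping) -> bool:
        """Insert ``mapping`` unless below threshold or beaten by the
        incumbent for the same pair; returns True if stored."""
        if mapping.similarity < self.threshold:
            return False
        current = self._by_pair.get(mapping.pair)
        if current is not None:
            if mapping.similarity < current.similarity:
                return False
            if mapping.similarity == current.similarity and provenance_rank(
                mapping.provenance
            ) >= provenance_rank(current.provenance):
                return False
        self._by_pair[mapping.pair] = mapping
        self._by_source.setdefault(mapping.source, set()).add(mapping.target)
        self._by_target.setdefault(mapping.target, set()).add(mapping.source)
        return True

    def discard(self, mapping: Mapping) -> None:
        current = self._by_pair.get(mapping.pair)
        if current is None:
            return
        del self._by_pair[mapping.pair]
        self._by_source[mapping.source].discard(mapping.target)
        if not self._by_source[mapping.source]:
            del self._by_source[mapping.source]
        self._by_target[mapping.target].discard(mapping.source)
        if not self._by_target[mapping.target]:
            del self._by_target[mapping.target]

    # -- lookup -------------------------------------------------------------

    def get(self, source: str, target: str) -> Optional[Mapping]:
        return self._by_pair.get((source, target))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._by_pair

    def contains_source(self, source: str) -> bool:
        return source in self._by_source

    def contains_target(self, target: str) -> bool:
        return target in self._by_target

    def targets_of(self, source: str) -> set[str]:
        return set(self._by_source.get(source, ()))

    def sources_of(self, target: str) -> set[str]:
        return set(self._by_target.get(target, ()))

    def sources(self) -> set[str]:
        return set(self._by_source)

    def targets(self) -> set[str]:
        return set(self._by_target)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)

    # -- iteration ----------------------------------------------------------

    def __iter__(self) -> Iterator[Mapping]:
        return iter(self._by_pair.values())

    def sorted_mappings(self) -> list[Mapping]:
        """Mappings in the deterministic total order."""
        return sorted(self._by_pair.values(), key=Mapping.sort_key)

    def __len__(self) -> int:
        return len(self._by_pair)

    def __bool__(self) -> bool:
        return bool(self._by_pair)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._by_pair == other._by_pair

    def copy(self) -> "Alignment":
        out = Alignment(threshold=self.threshold)
        for m in self:
            out.add(m)
        return out

    def scored_pairs(self) -> dict[tuple[str, str], float]:
        return {pair: m.similarity for pair, m in self._by_pair.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Alignment({len(self)} mappings)"
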