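"""Synthetic ontology pairs with known reference alignments.

A fixture is built from a shared concept backbone (a random subclass tree
plus part-of edges) rendered into two ontologies, A and B.  A fraction of
the concepts appears in both ontologies and constitutes the 1:1 reference
alignment; the remaining concepts are private to one side.  Name variants
applied to B's rendering emulate the lexical heterogeneity of real
biomedical ontologies, each designed to be recovered by one particular
matching strategy:

``stopword_prefix``
    B names the concept "structure of X" (SNOMED-style); recovered by
    stop-word synonym generation.
``parenthetical``
    B inserts a parenthesized qualifier; recovered by parenthetical
    removal.
``camel_case``
    B writes the name in CamelCase; recovered by name normalization.
``thesaurus_swap``
    B replaces one word through a planted synonymous word pair; a helper
    class carrying both spellings is added so the pair is inducible, and
    only the thesaurus matcher recovers the swapped concept.
``typo``
    B's name has one edited character; recovered by ISub string matching.
``synonym_shuffle``
    B's primary name is unrelated but B keeps the true name as an exact
    synonym, while an ambiguous related synonym of the A class matches a
    B-only distractor class; exercises synonym use and category weights.

Background-knowledge flags emit a mediator ontology whose classes carry
both sides' names, cross-references into both inputs, and OBO-style
logical definitions (with a cross-reference bridge between the external
namespaces the two sides' definitions point at).  ``incoherence_rate``
plants disjointness axioms in B (re-parenting the child so each input
ontology stays coherent on its own) that make pairs of reference mappings
jointly unsatisfiable.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .alignment import Alignment, Mapping
from .model import LogicalDefinition, Ontology

__all__ = ["FixtureConfig", "generate_pair", "render_obo", "VARIANT_OPS"]

VARIANT_OPS = (
    "stopword_prefix",
    "parenthetical",
    "camel_case",
    "thesaurus_swap",
    "typo",
    "synonym_shuffle",
)

#: Planted synonymous word pairs used by ``thesaurus_swap``.  These words
#: are deliberately absent from the name vocabulary below.
PLANTED_PAIRS = (
    ("stomach", "gastric"),
    ("hepatic", "liver"),
    ("renal", "kidney"),
    ("cardiac", "heart"),
)

_ADJECTIVES = (
    "anterior", "posterior", "dorsal", "ventral", "lateral", "medial",
    "proximal", "distal", "superior", "inferior", "cranial", "caudal",
    "left", "right", "upper", "lower", "deep", "superficial", "internal",
    "external", "central", "peripheral", "primary", "secondary", "basal",
    "apical", "axial", "radial", "oblique", "transverse", "longitudinal",
    "circular", "smooth", "striated", "compact", "spongy", "fibrous",
    "elastic", "mucous", "serous", "squamous", "cuboidal", "columnar",
    "ciliated", "glandular", "vascular", "neural", "epithelial", "muscular",
    "skeletal", "dermal", "cortical", "medullary", "pelvic", "thoracic",
    "cervical", "lumbar", "sacral", "frontal", "parietal", "temporal",
    "occipital", "nasal", "oral",
)

_NOUNS = (
    "artery", "vein", "capillary", "nerve", "ganglion", "plexus", "muscle",
    "tendon", "ligament", "bone", "cartilage", "joint", "membrane", "gland",
    "duct", "lobe", "lobule", "segment", "septum", "sinus", "fossa",
    "foramen", "canal", "tract", "fasciculus", "nucleus", "cortex",
    "medulla", "capsule", "sheath", "follicle", "papilla", "villus",
    "crypt", "ridge", "groove", "process", "tubercle", "tuberosity",
    "condyle", "epicondyle", "spine", "arch", "body", "head", "neck",
    "shaft", "base", "apex", "margin", "border", "surface", "wall",
    "chamber", "valve", "node",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic ontology pair."""

    n_classes: int
    shared_fraction: float = 1.0
    variant_ops: tuple[str, ...] = ()
    variant_rate: float = 0.0
    bk_mediator: bool = False
    bk_xrefs: bool = False
    bk_logical_defs: bool = False
    incoherence_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        for name, rate in (
            ("shared_fraction", self.shared_fraction),
            ("variant_rate", self.variant_rate),
            ("incoherence_rate", self.incoherence_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        unknown = set(self.variant_ops) - set(VARIANT_OPS)
        if unknown:
            raise ValueError(f"unknown variant ops: {sorted(unknown)}")
        if self.incoherence_rate > 0 and self.n_classes < 4:
            raise ValueError("incoherence planting needs n_classes >= 4")


@dataclass
class _Concept:
    index: int
    name: str
    parent: int | None
    part_of: int | None
    side: str  # "both" | "A" | "B"
    op: str | None = None
    b_name: str | None = None
    a_extra_synonyms: list[tuple[str, str]] = field(default_factory=list)
    b_extra_synonyms: list[tuple[str, str]] = field(default_factory=list)
    logical_def: tuple[LogicalDefinition, LogicalDefinition] | None = None


def _camel(name: str) -> str:
    return "".join(w.capitalize() for w in name.split())


def _typo(name: str, rng: random.Random) -> str:
    letters = [i for i, ch in enumerate(name) if ch.isalpha()]
    # avoid the first character so the shared prefix survives for ISub
    pos = rng.choice(letters[1:] if len(letters) > 1 else letters)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    replacement = rng.choice([c for c in alphabet if c != name[pos]])
    return name[:pos] + replacement + name[pos + 1:]


def generate_pair(
    config: FixtureConfig,
) -> tuple[Ontology, Ontology, Alignment, Ontology | None]:
    """Generate (ontology A, ontology B, reference alignment, optional BK)."""
    rng = random.Random(config.seed)
    combos = [f"{a} {n}" for a, n in itertools.product(_ADJECTIVES, _NOUNS)]
    rng.shuffle(combos)
    if config.n_classes + 64 > len(combos):
        raise ValueError("n_classes exceeds the name vocabulary")
    name_pool = iter(combos)

    concepts: list[_Concept] = []
    for i in range(config.n_classes):
        if i == 0:
            side = "both"  # keep both ontologies rooted
            parent = None
        else:
            side = "both" if rng.random() < config.shared_fraction else (
                "A" if rng.random() < 0.5 else "B"
            )
            parent = rng.randrange(0, i)
        part_of = None
        if i >= 2 and rng.random() < 0.15:
            target = rng.randrange(0, i)
            if target != parent:
                part_of = target
        concepts.append(_Concept(i, next(name_pool), parent, part_of, side))

    shared = [c for c in concepts if c.side == "both"]

    # --- variant ops on B's rendering -------------------------------------
    ops = tuple(sorted(config.variant_ops))
    used_pairs: list[tuple[str, str]] = []
    if ops and config.variant_rate > 0:
        for concept in shared[1:]:  # keep the root stable
            if rng.random() >= config.variant_rate:
                continue
            concept.op = ops[rng.randrange(len(ops))]
    pair_cycle = itertools.cycle(PLANTED_PAIRS)
    for concept in [c for c in shared if c.op == "thesaurus_swap"]:
        pair = next(pair_cycle)
        if pair not in used_pairs:
            used_pairs.append(pair)
        concept.name = f"{pair[0]} {concept.name}"
        concept.b_name = f"{pair[1]} {concept.name.split(' ', 1)[1]}"
    for concept in shared:
        if concept.op == "stopword_prefix":
            concept.b_name = f"structure of {concept.name}"
        elif concept.op == "parenthetical":
            qualifier = next(name_pool).split()[0]
            words = concept.name.split(" ", 1)
            concept.b_name = f"{words[0]} ({qualifier}) {words[1]}"
        elif concept.op == "camel_case":
            concept.b_name = _camel(concept.name)
        elif concept.op == "typo":
            concept.b_name = _typo(concept.name, rng)
        elif concept.op == "synonym_shuffle":
            alt = next(name_pool)
            amb = next(name_pool)
            concept.b_name = alt
            concept.b_extra_synonyms.append(("hasExactSynonym", concept.name))
            concept.a_extra_synonyms.append(("hasRelatedSynonym", amb))
            distractor = _Concept(
                len(concepts), amb, 0, None, "B", op="distractor"
            )
            concepts.append(distractor)

    # helper classes that make the planted word pairs inducible
    for pair in used_pairs:
        helper_base = next(name_pool)
        helper = _Concept(
            len(concepts), f"{pair[0]} {helper_base}", 0, None, "both"
        )
        helper.a_extra_synonyms.append(
            ("hasExactSynonym", f"{pair[1]} {helper_base}")
        )
        concepts.append(helper)
        shared.append(helper)

    # --- logical definitions ----------------------------------------------
    if config.bk_logical_defs:
        candidates = [c for c in shared if c.op is None and c.index != 0]
        n_defs = max(1, len(candidates) // 4) if candidates else 0
        for k, concept in enumerate(candidates[:n_defs]):
            concept.op = "logicaldef"
            concept.b_name = next(name_pool)  # lexically unmatchable
            genus = f"XG:{k:05d}"
            if k % 2 == 0:
                filler_a = filler_b = f"XC:{k:05d}"
            else:  # bridged through the BK's cross-references
                filler_a = f"XA:{k:05d}"
                filler_b = f"XB:{k:05d}"
            concept.logical_def = (
                LogicalDefinition(genus, frozenset({("inheres_in", filler_a)})),
                LogicalDefinition(genus, frozenset({("inheres_in", filler_b)})),
            )

    # --- incoherence planting ----------------------------------------------
    planted_conflicts: list[tuple[int, int]] = []
    if config.incoherence_rate > 0:
        shared_idx = {c.index for c in shared}
        plain = {
            c.index for c in shared if c.op is None and c.b_name is None
        }
        child_pairs = [
            (c.index, c.parent)
            for c in concepts
            if c.parent is not None
            and c.index in plain
            and c.parent in plain
            and c.parent in shared_idx
        ]
        n_conflicts = max(1, int(round(config.incoherence_rate * len(child_pairs))))
        planted_conflicts = child_pairs[:n_conflicts]

    # --- rendering ----------------------------------------------------------
    def class_id(prefix: str, index: int) -> str:
        return f"{prefix}:{index:07d}"

    by_index = {c.index: c for c in concepts}

    def nearest_present(index: int | None, present: set[int]) -> int | None:
        while index is not None:
            if index in present:
                return index
            index = by_index[index].parent
        return None

    reparented = {child for child, _parent in planted_conflicts}

    def build(prefix: str, side: str) -> Ontology:
        onto = Ontology(prefix=prefix)
        present = {
            c.index for c in concepts if c.side in ("both", side)
        }
        for index in sorted(present):
            onto.add_class(class_id(prefix, index))
        for index in sorted(present):
            concept = by_index[index]
            cid = class_id(prefix, index)
            if side == "B":
                label = concept.b_name or concept.name
                extra = concept.b_extra_synonyms
            else:
                label = concept.name
                extra = concept.a_extra_synonyms
            onto.annotate(cid, "label", label)
            for prop, text in extra:
                onto.annotate(cid, prop, text)
            parent_index = concept.parent
            if side == "B" and index in reparented:
                parent_index = by_index[parent_index].parent
            parent = nearest_present(parent_index, present - {index})
            if parent is not None:
                onto.relationships.add_subclass(cid, class_id(prefix, parent))
            whole = nearest_present(concept.part_of, present - {index})
            if whole is not None:
                onto.relationships.add_property(
                    cid, "part_of", class_id(prefix, whole)
                )
            if concept.logical_def is not None:
                definition = concept.logical_def[0 if side == "A" else 1]
                onto.set_logical_def(cid, definition)
        if side == "B":
            for child, parent in planted_conflicts:
                onto.relationships.add_disjoint(
                    class_id(prefix, parent), class_id(prefix, child)
                )
        return onto

    onto_a = build("TA", "A")
    onto_b = build("TB", "B")

    reference = Alignment()
    for concept in concepts:
        if concept.side == "both":
            reference.add(
                Mapping(
                    class_id("TA", concept.index),
                    class_id("TB", concept.index),
                    1.0,
                    provenance="reference",
                )
            )

    bk = None
    if config.bk_mediator or config.bk_xrefs or config.bk_logical_defs:
        bk = Ontology(prefix="TM")
        for concept in concepts:
            if concept.side != "both":
                continue
            cid = f"TM:{concept.index:07d}"
            bk.add_class(cid)
            bk.annotate(cid, "label", concept.name)
            if concept.b_name is not None and concept.op != "logicaldef":
                bk.annotate(cid, "hasExactSynonym", concept.b_name)
            if config.bk_xrefs:
                bk.add_xref(cid, class_id("TA", concept.index))
                bk.add_xref(cid, class_id("TB", concept.index))
            parent = nearest_present(
                concept.parent, {c.index for c in concepts if c.side == "both"}
            )
            if parent is not None:
                bk.relationships.add_subclass(cid, f"TM:{parent:07d}")
        if config.bk_logical_defs:
            bridged = sorted(
                k
                for k, concept in enumerate(
                    c for c in concepts if c.op == "logicaldef"
                )
                if k % 2 == 1
            )
            for k in bridged:
                cid = f"TM:X{k:06d}"
                bk.add_class(cid)
                bk.annotate(cid, "label", next(name_pool))
                bk.add_xref(cid, f"XA:{k:05d}")
                bk.add_xref(cid, f"XB:{k:05d}")
    return onto_a, onto_b, reference, bk


# ---------------------------------------------------------------------------
# OBO rendering
# ---------------------------------------------------------------------------

_SYNONYM_SCOPES = {
    "hasExactSynonym": "EXACT",
    "hasRelatedSynonym": "RELATED",
    "hasBroadSynonym": "BROAD",
    "hasNarrowSynonym": "NARROW",
}


def render_obo(ontology: Ontology, path: str) -> None:
    """Write an ontology as a deterministic OBO 1.4 flat file.

    The output round-trips through the OBO reader: classes, names,
    synonym scopes, cross-references, logical definitions, relationships
    and disjointness are preserved.
    """
    lines = [
        "format-version: 1.4",
        f"ontology: {ontology.prefix.lower()}",
        "",
    ]
    disjoint_by_class: dict[str, list[str]] = {}
    for pair in sorted(ontology.relationships.disjoint_pairs(), key=sorted):
        first, second = sorted(pair)
        disjoint_by_class.setdefault(first, []).append(second)
    for cid in sorted(ontology.classes):
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        annotations = ontology.annotations.get(cid, [])
        labels = [t for p, t in annotations if p in ("label", "name")]
        if labels:
            lines.append(f"name: {labels[0]}")
        for prop, text in sorted(annotations):
            scope = _SYNONYM_SCOPES.get(prop)
            if scope is not None:
                escaped = text.replace('"', '\\"')
                lines.append(f'synonym: "{escaped}" {scope} []')
        for curie in sorted(ontology.xrefs.get(cid, ())):
            lines.append(f"xref: {curie}")
        for parent in sorted(ontology.relationships.parents(cid)):
            lines.append(f"is_a: {parent}")
        for subject, prop, obj in sorted(ontology.relationships.property_edges()):
            if subject == cid:
                lines.append(f"relationship: {prop} {obj}")
        definition = ontology.logical_defs.get(cid)
        if definition is not None:
            if definition.genus is not None:
                lines.append(f"intersection_of: {definition.genus}")
            for prop, filler in sorted(definition.differentia):
                lines.append(f"intersection_of: {prop} {filler}")
        for other in sorted(disjoint_by_class.get(cid, ())):
            lines.append(f"disjoint_from: {other}")
        if cid in ontology.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
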