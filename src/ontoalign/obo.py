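"""Ontology ingestion: OBO 1.2/1.4 flat files and RDF/XML OWL.

Both readers produce the same :class:`~ontoalign.model.Ontology`
container, so the rest of the pipeline is format-agnostic.  OBO parsing
is delegated to :mod:`obonet`; synonym scope tags (EXACT, RELATED, BROAD,
NARROW) are mapped onto the corresponding oboInOwl-style annotation
properties, and ``intersection_of`` stanzas become
:class:`~ontoalign.model.LogicalDefinition` objects (a bare CURIE line is
the genus, ``property CURIE`` lines are the differentia).

The OWL reader covers the subset of RDF/XML OWL needed for lexical
matching: named classes with rdfs:label and oboInOwl synonym properties,
rdfs:subClassOf between named classes, owl:disjointWith, and
oboInOwl:hasDbXref cross-references.
"""

from __future__ import annotations

import logging
import re

import obonet
import rdflib
from rdflib.namespace import OWL, RDF, RDFS

from .model import LogicalDefinition, Ontology

logger = logging.getLogger(__name__)

__all__ = ["read_obo", "read_owl", "load_ontology"]

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')

_SCOPE_PROPERTY = {
    "EXACT": "hasExactSynonym",
    "RELATED": "hasRelatedSynonym",
    "BROAD": "hasBroadSynonym",
    "NARROW": "hasNarrowSynonym",
    "": "hasRelatedSynonym",
}


def _parse_synonym(raw: str) -> tuple[str, str] | None:
    """(property tag, text) from an OBO synonym value, or None."""
    match = _SYNONYM_RE.match(raw.strip())
    if not match:
        return None
    text = match.group("text").replace('\\"', '"')
    prop = _SCOPE_PROPERTY.get(match.group("scope"), "hasRelatedSynonym")
    return prop, text


def _strip_comment(value: str) -> str:
    return value.split(" ! ")[0].strip()


def _parse_intersection(lines: list[str]) -> LogicalDefinition | None:
    genus: str | None = None
    differentia: list[tuple[str, str]] = []
    for raw in lines:
        value = _strip_comment(raw)
        parts = value.split()
        if len(parts) == 1:
            genus = parts[0]
        elif len(parts) == 2:
            differentia.append((parts[0], parts[1]))
        else:
            logger.warning("unparseable intersection_of line %r", raw)
            return None
    if genus is None and not differentia:
        return None
    return LogicalDefinition(genus, frozenset(differentia))


def _prefix_of(class_id: str) -> str:
    for sep in (":", "_"):
        if sep in class_id:
            return class_id.split(sep, 1)[0]
    return class_id


def read_obo(path: str, prefix: str | None = None) -> Ontology:
    """Read an OBO flat file into an :class:`Ontology`.

    Obsolete terms are kept (flagged obsolete) so the lexicon builder can
    exclude them explicitly.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    node_ids = sorted(graph.nodes)
    if prefix is None:
        prefix = _prefix_of(node_ids[0]) if node_ids else "UNKNOWN"
    onto = Ontology(prefix=prefix)
    for node in node_ids:
        onto.add_class(node)
    for node in node_ids:
        data = graph.nodes[node]
        if "name" in data:
            onto.annotate(node, "label", data["name"])
        for raw in data.get("synonym", ()):
            parsed = _parse_synonym(raw)
            if parsed is None:
                logger.warning("unparseable synonym line %r on %s", raw, node)
                continue
            onto.annotate(node, *parsed)
        for curie in data.get("xref", ()):
            onto.add_xref(node, _strip_comment(curie))
        for parent in data.get("is_a", ()):
            onto.relationships.add_subclass(node, _strip_comment(parent))
        for rel in data.get("relationship", ()):
            parts = _strip_comment(rel).split()
            if len(parts) == 2:
                onto.relationships.add_property(node, parts[0], parts[1])
        for other in data.get("disjoint_from", ()):
            onto.relationships.add_disjoint(node, _strip_comment(other))
        definition = _parse_intersection(list(data.get("intersection_of", ())))
        if definition is not None:
            onto.set_logical_def(node, definition)
        if str(data.get("is_obsolete", "")).lower() == "true":
            onto.mark_obsolete(node)
    return onto


_OBOINOWL = rdflib.Namespace("http://www.geneontology.org/formats/oboInOwl#")
_OBO_BASE = "http://purl.obolibrary.org/obo/"

_OWL_SYNONYM_PROPS = {
    _OBOINOWL.hasExactSynonym: "hasExactSynonym",
    _OBOINOWL.hasRelatedSynonym: "hasRelatedSynonym",
    _OBOINOWL.hasBroadSynonym: "hasBroadSynonym",
    _OBOINOWL.hasNarrowSynonym: "hasNarrowSynonym",
}


def _uri_to_id(uri: str) -> str:
    if uri.startswith(_OBO_BASE):
        return uri[len(_OBO_BASE):].replace("_", ":", 1)
    return uri


def read_owl(path: str, prefix: str | None = None) -> Ontology:
    """Read an RDF/XML OWL file through the same ingestion contract."""
    graph = rdflib.Graph()
    graph.parse(path, format="xml")
    class_uris = sorted(
        u for u in graph.subjects(RDF.type, OWL.Class)
        if isinstance(u, rdflib.URIRef)
    )
    ids = {u: _uri_to_id(str(u)) for u in class_uris}
    if prefix is None:
        prefix = _prefix_of(next(iter(ids.values()))) if ids else "UNKNOWN"
    onto = Ontology(prefix=prefix)
    for uri in class_uris:
        onto.add_class(ids[uri])
    for uri in class_uris:
        node = ids[uri]
        for label in sorted(graph.objects(uri, RDFS.label)):
            onto.annotate(node, "label", str(label))
        for prop, tag in _OWL_SYNONYM_PROPS.items():
            for value in sorted(graph.objects(uri, prop)):
                onto.annotate(node, tag, str(value))
        for value in sorted(graph.objects(uri, _OBOINOWL.hasDbXref)):
            onto.add_xref(node, str(value))
        for parent in sorted(graph.objects(uri, RDFS.subClassOf)):
            if isinstance(parent, rdflib.URIRef) and parent in ids:
                onto.relationships.add_subclass(node, ids[parent])
        for other in sorted(graph.objects(uri, OWL.disjointWith)):
            if isinstance(other, rdflib.URIRef) and other in ids:
                onto.relationships.add_disjoint(node, ids[other])
        deprecated = graph.value(uri, OWL.deprecated)
        if deprecated is not None and str(deprecated).lower() == "true":
            onto.mark_obsolete(node)
    return onto


def load_ontology(path: str, prefix: str | None = None) -> Ontology:
    """Dispatch on file extension: .obo -> OBO reader, .owl/.rdf -> OWL."""
    lowered = path.lower()
    if lowered.endswith(".obo"):
        return read_obo(path, prefix)
    if lowered.endswith((".owl", ".rdf", ".xml")):
        return read_owl(path, prefix)
    raise ValueError(f"cannot infer ontology format of {path!r}")
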