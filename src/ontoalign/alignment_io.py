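"""Reading, writing and evaluating alignments.

Two serializations are supported: a TSV dialect (source, target, score,
relation, provenance) and the de-facto alignment exchange RDF/XML dialect
in which each correspondence is a ``Cell`` with ``entity1``, ``entity2``,
``relation`` and ``measure``.  Writing is deterministic (rows follow the
selection total order, scores carry four decimals) so outputs are
byte-reproducible; reading is the inverse of writing on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape, quoteattr

import rdflib

from .alignment import Alignment, Mapping

__all__ = [
    "write_alignment",
    "read_alignment",
    "evaluate",
    "EvaluationResult",
    "EmptyReferenceError",
]

_ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment#"
_OBO_BASE = "http://purl.obolibrary.org/obo/"


def _curie_to_uri(class_id: str) -> str:
    if ":" in class_id and "//" not in class_id:
        return _OBO_BASE + class_id.replace(":", "_", 1)
    return class_id


def _uri_to_curie(uri: str) -> str:
    if uri.startswith(_OBO_BASE):
        return uri[len(_OBO_BASE):].replace("_", ":", 1)
    return uri


def _format_score(score: float) -> str:
    """Four decimals, trailing zeros trimmed: 0.95, 0.585, 1.0."""
    text = f"{score:.4f}".rstrip("0")
    return text + "0" if text.endswith(".") else text


def write_alignment(alignment: Alignment, path: str, format: str = "tsv") -> None:
    """Serialize ``alignment`` to ``path`` in TSV or alignment-RDF format."""
    rows = alignment.sorted_mappings()
    if format == "tsv":
        lines = ["source\ttarget\tscore\trelation\tprovenance"]
        for m in rows:
            lines.append(
                f"{m.source}\t{m.target}\t{_format_score(m.similarity)}"
                f"\t{m.relation}\t{m.provenance}"
            )
        text = "\n".join(lines) + "\n"
    elif format == "alignment-rdf":
        cells = []
        for m in rows:
            cells.append(
                "    <map>\n"
                "      <Cell>\n"
                f"        <entity1 rdf:resource={quoteattr(_curie_to_uri(m.source))}/>\n"
                f"        <entity2 rdf:resource={quoteattr(_curie_to_uri(m.target))}/>\n"
                f"        <relation>{escape(m.relation)}</relation>\n"
                '        <measure rdf:datatype='
                '"http://www.w3.org/2001/XMLSchema#float">'
                f"{_format_score(m.similarity)}</measure>\n"
                f"        <provenance>{escape(m.provenance)}</provenance>\n"
                "      </Cell>\n"
                "    </map>\n"
            )
        text = (
            "<?xml version='1.0' encoding='utf-8'?>\n"
            f"<rdf:RDF xmlns={quoteattr(_ALIGN_NS)}\n"
            '         xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#">\n'
            "  <Alignment>\n"
            "    <xml>yes</xml>\n"
            "    <level>0</level>\n"
            "    <type>11</type>\n"
            + "".join(cells)
            + "  </Alignment>\n"
            "</rdf:RDF>\n"
        )
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def _read_tsv(path: str) -> Alignment:
    alignment = Alignment()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source\ttarget"):
            raise ValueError(f"{path}: not an alignment TSV (bad header)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            source, target, score, relation, provenance = fields
            alignment.add(
                Mapping(source, target, float(score), relation, provenance)
            )
    return alignment


def _read_rdf(path: str) -> Alignment:
    graph = rdflib.Graph()
    graph.parse(path, format="xml")
    ns = rdflib.Namespace(_ALIGN_NS)
    alignment = Alignment()
    for cell in graph.subjects(rdflib.RDF.type, ns.Cell):
        _add_cell(graph, ns, cell, alignment)
    if not len(alignment):
        # some serializers omit the rdf:type of cells; fall back on shape
        for cell in set(graph.subjects(ns.entity1, None)):
            _add_cell(graph, ns, cell, alignment)
    return alignment


def _add_cell(graph, ns, cell, alignment: Alignment) -> None:
    entity1 = graph.value(cell, ns.entity1)
    entity2 = graph.value(cell, ns.entity2)
    measure = graph.value(cell, ns.measure)
    relation = graph.value(cell, ns.relation)
    provenance = graph.value(cell, ns.provenance)
    if entity1 is None or entity2 is None or measure is None:
        raise ValueError(f"malformed alignment cell {cell}")
    alignment.add(
        Mapping(
            _uri_to_curie(str(entity1)),
            _uri_to_curie(str(entity2)),
            float(measure),
            str(relation) if relation is not None else "=",
            str(provenance) if provenance is not None else "unknown",
        )
    )


def read_alignment(path: str, format: str | None = None) -> Alignment:
    """Parse an alignment file; the format is sniffed when not given."""
    if format is None:
        with open(path, "r", encoding="utf-8") as fh:
            head = fh.read(200)
        format = "alignment-rdf" if head.lstrip().startswith("<?xml") else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "alignment-rdf":
        return _read_rdf(path)
    raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class EmptyReferenceError(ValueError):
    """Recall against an empty reference alignment is undefined."""


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall/F-measure of a predicted alignment vs a reference."""

    precision: float
    recall: float
    f_measure: float
    true_positives: int
    false_positives: int
    false_negatives: int


def evaluate(predicted: Alignment, reference: Alignment) -> EvaluationResult:
    """Score ``predicted`` against ``reference``.

    The intersection is taken on (source, target) pairs; similarity scores
    are ignored.  Precision is |P∩R|/|P|, recall |P∩R|/|R|, F their
    harmonic mean.
    """
    if len(reference) == 0:
        raise EmptyReferenceError("reference alignment is empty")
    p_pairs = predicted.pairs()
    r_pairs = reference.pairs()
    tp = len(p_pairs & r_pairs)
    fp = len(p_pairs) - tp
    fn = len(r_pairs) - tp
    precision = tp / len(p_pairs) if p_pairs else 0.0
    recall = tp / len(r_pairs)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationResult(precision, recall, f, tp, fp, fn)
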