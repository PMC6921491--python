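"""Reading, filtering and summarizing RDF background knowledge graphs.

The interaction-prediction pipeline treats a biomedical knowledge graph
(drugs, targets, enzymes, pathways, ... connected by typed predicates) as
background knowledge from which entity features are learned.  This module
parses the N-Triples serialization, strips known interaction edges so the
learned features cannot leak the label being predicted, and builds the
adjacency structure used by the random-walk and translational-embedding
trainers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import Literal as _RDFLiteral
from rdflib.plugins.parsers.ntriples import (
    ParseError as _RDFParseError,
    W3CNTriplesParser as _NTParser,
)

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "GraphSummary",
    "NTriplesParseError",
    "read_ntriples",
    "write_ntriples",
    "remove_interaction_edges",
    "build_graph",
    "graph_summary",
]


class NTriplesParseError(ValueError):
    """Raised when an N-Triples line cannot be parsed; carries the line number."""

    def __init__(self, path: str, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: malformed N-Triples line: {message}")


@dataclass(frozen=True)
class Triple:
    """A single RDF statement (subject, predicate, object).

    ``object_is_literal`` flags literal objects, which are kept as terminal
    tokens for walks but never act as graph entities.
    """

    subject: str
    predicate: str
    object: str
    object_is_literal: bool = False

    def __post_init__(self) -> None:
        if not self.subject or not self.predicate or not self.object:
            raise ValueError(f"triple components must be non-empty: {self!r}")


@dataclass
class KnowledgeGraph:
    """Typed directed multigraph with outgoing-edge adjacency.

    ``entities`` holds URI nodes only.  Literal objects appear as edge
    targets (terminal walk tokens) but are excluded from ``entities`` so
    they are never used as walk roots or corruption candidates.
    """

    entities: set[str] = field(default_factory=set)
    relation_types: set[str] = field(default_factory=set)
    out_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    literals: set[str] = field(default_factory=set)

    @property
    def n_triples(self) -> int:
        return sum(len(v) for v in self.out_edges.values())


@dataclass(frozen=True)
class GraphSummary:
    n_triples: int
    n_entities: int
    n_relation_types: int


class _Sink:
    def __init__(self) -> None:
        self.triple_: tuple | None = None

    def triple(self, s, p, o) -> None:
        self.triple_ = (s, p, o)


def read_ntriples(path: str | Path) -> list[Triple]:
    """Parse an N-Triples file into a list of :class:`Triple`.

    Blank lines and ``#`` comment lines are skipped.  Duplicate statements
    are preserved (deduplication happens in :func:`build_graph`).  A
    malformed line raises :class:`NTriplesParseError` naming the line.
    """
    path = Path(path)
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            sink = _Sink()
            parser = _NTParser(sink)
            try:
                parser.parsestring(line)
            except _RDFParseError as exc:
                raise NTriplesParseError(str(path), lineno, str(exc)) from exc
            if sink.triple_ is None:
                raise NTriplesParseError(str(path), lineno, "no statement found")
            s, p, o = sink.triple_
            triples.append(
                Triple(str(s), str(p), str(o), isinstance(o, _RDFLiteral))
            )
    return triples


def _escape_literal(value: str) -> str:
    out = value.replace("\\", "\\\\").replace('"', '\\"')
    out = out.replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")
    return out


def write_ntriples(triples: Iterable[Triple], path: str | Path) -> int:
    """Serialize triples to N-Triples; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            if t.object_is_literal:
                obj = f'"{_escape_literal(t.object)}"'
            else:
                obj = f"<{t.object}>"
            fh.write(f"<{t.subject}> <{t.predicate}> {obj} .\n")
            n += 1
    return n


def remove_interaction_edges(
    triples: Sequence[Triple], interaction_predicates: Iterable[str]
) -> list[Triple]:
    """Drop every triple whose predicate encodes a known drug interaction.

    Removing these edges before feature learning prevents the embedding
    from memorizing the very links the classifier is asked to predict.
    Order is preserved; an empty predicate set is the identity.
    """
    banned = set(interaction_predicates)
    if not banned:
        return list(triples)
    return [t for t in triples if t.predicate not in banned]


def build_graph(triples: Iterable[Triple]) -> KnowledgeGraph:
    """Build the outgoing-edge adjacency used by walks and embeddings.

    Duplicate triples are deduplicated so the adjacency is deterministic.
    Edge lists preserve first-occurrence order.
    """
    g = KnowledgeGraph()
    seen: set[tuple[str, str, str, bool]] = set()
    for t in triples:
        key = (t.subject, t.predicate, t.object, t.object_is_literal)
        if key in seen:
            continue
        seen.add(key)
        g.entities.add(t.subject)
        g.relation_types.add(t.predicate)
        if t.object_is_literal:
            g.literals.add(t.object)
        else:
            g.entities.add(t.object)
        g.out_edges.setdefault(t.subject, []).append((t.predicate, t.object))
    return g


def graph_summary(graph: KnowledgeGraph) -> GraphSummary:
    """Triple/entity/relation-type counts of a knowledge graph."""
    return GraphSummary(
        n_triples=graph.n_triples,
        n_entities=len(graph.entities),
        n_relation_types=len(graph.relation_types),
    )
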