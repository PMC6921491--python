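"""Random graph walks producing the sentence corpus for embedding training.

Each walk starts at a root entity and repeatedly follows a uniformly random
outgoing edge, emitting alternating entity and predicate tokens, so a
depth-``d`` walk contains at most ``2 d + 1`` tokens.  Walks that reach a
node without outgoing edges are truncated there.  The union of all walks is
the corpus fed to skip-gram / CBOW training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kg_io import KnowledgeGraph

__all__ = [
    "WalkConfig",
    "WalkCorpus",
    "CorpusStats",
    "random_walks",
    "corpus_stats",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class WalkConfig:
    """Walk-generation parameters.

    depth
        Number of edge traversals per walk (1-4 are typical for
        biomedical graphs; deeper walks mostly revisit hub nodes).
    walks_per_entity
        Number of walks emitted per root entity; duplicates are kept and
        act as frequency weighting.
    """

    depth: int = 4
    walks_per_entity: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.walks_per_entity < 1:
            raise ValueError("walks_per_entity must be >= 1")


@dataclass
class WalkCorpus:
    walks: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def vocabulary(self) -> set[str]:
        return {tok for walk in self.walks for tok in walk}


@dataclass(frozen=True)
class CorpusStats:
    n_walks: int
    n_tokens: int
    vocab_size: int


def random_walks(
    graph: KnowledgeGraph,
    roots: Iterable[str] | None = None,
    config: WalkConfig = WalkConfig(),
) -> WalkCorpus:
    """Generate ``walks_per_entity`` random walks from each root.

    Roots default to every entity in the graph.  At each step the next
    (predicate, target) pair is drawn uniformly among the current node's
    outgoing edges; dead ends truncate the walk.  Deterministic under
    ``config.seed`` (roots are visited in sorted order).
    """
    if roots is None:
        root_list = sorted(graph.entities)
    else:
        root_list = sorted(set(roots))
        unknown = [r for r in root_list if r not in graph.entities]
        if unknown:
            raise KeyError(f"walk root not in graph: {unknown[0]!r}")
    rng = np.random.default_rng(config.seed)
    out = graph.out_edges
    walks: list[tuple[str, ...]] = []
    for root in root_list:
        for _ in range(config.walks_per_entity):
            tokens = [root]
            node = root
            for _ in range(config.depth):
                edges = out.get(node)
                if not edges:
                    break
                pred, target = edges[rng.integers(len(edges))]
                tokens.append(pred)
                tokens.append(target)
                node = target
            walks.append(tuple(tokens))
    return WalkCorpus(walks=walks)


def corpus_stats(corpus: WalkCorpus) -> CorpusStats:
    n_tokens = sum(len(w) for w in corpus.walks)
    return CorpusStats(
        n_walks=len(corpus.walks),
        n_tokens=n_tokens,
        vocab_size=len(corpus.vocabulary),
    )


def write_corpus(corpus: WalkCorpus, path: str | Path) -> None:
    """One walk per line, tokens space-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for walk in corpus.walks:
            fh.write(" ".join(walk) + "\n")


def read_corpus(path: str | Path) -> WalkCorpus:
    walks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                walks.append(tuple(line.split(" ")))
    return WalkCorpus(walks=walks)
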