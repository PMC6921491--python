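"""Balanced, split-aware labeled pair datasets with concatenated embedding features.

Classifiers see a drug pair as the concatenation of the two drugs' embedding
vectors (2 x dim features).  Positives are known interactions; negatives are
unknown pairs sampled in equal number, drawn from the pair-space block that
matches the pair's fold role (existing x existing for training,
existing x cold-start for the drug-wise test, cold-start x cold-start for the
pairwise test) so that negative sampling cannot re-introduce the leakage the
disjoint split removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cv_split import FoldSplit, Pair, ReferenceDDISet, canonical_pair, classify_pair
from .embed_models import EmbeddingTable

__all__ = [
    "LabeledPairDataset",
    "enumerate_unknown_pairs",
    "count_unknown_pairs",
    "sample_negatives",
    "sample_negatives_global",
    "pair_features",
    "filter_drugs_with_embeddings",
    "FilterReport",
    "build_dataset",
]


@dataclass
class LabeledPairDataset:
    """Aligned (pairs, labels, features) rows for one subset of one fold."""

    pairs: list[Pair]
    labels: np.ndarray  # 1 = known DDI
    features: np.ndarray  # (n_pairs, 2*dim)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels) or len(self.pairs) != len(self.features):
            raise ValueError("pairs, labels and features must align")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in dataset")


def enumerate_unknown_pairs(drugs: set[str], known: set[Pair]) -> tuple[set[Pair], int]:
    """All canonical unordered pairs over ``drugs`` that are not known DDIs.

    The count is ``n(n-1)/2 - |known|`` when every known pair lies within
    the universe.  Returns (pair set, count).
    """
    ordered = sorted(drugs)
    unknown = {
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
        if (ordered[i], ordered[j]) not in known
    }
    return unknown, len(unknown)


def count_unknown_pairs(n_drugs: int, n_known: int) -> int:
    """Closed-form unknown-pair count: n(n-1)/2 - known."""
    return n_drugs * (n_drugs - 1) // 2 - n_known


def _sample_block(
    side_a: Sequence[str],
    side_b: Sequence[str] | None,
    n: int,
    known: set[Pair],
    rng: np.random.Generator,
    block_name: str,
) -> list[Pair]:
    """Draw n distinct unknown pairs from a pair-space block by rejection.

    ``side_b=None`` means the within-block case (unordered pairs inside
    ``side_a``).  Falls back to exhaustive enumeration when the block is
    small or rejection stalls, and errors if the block cannot supply n
    pairs.
    """
    if n == 0:
        return []
    picked: set[Pair] = set()
    a = list(side_a)
    b = list(side_b) if side_b is not None else None
    # expected candidate count; exhaustive fallback keeps correctness when dense
    max_pairs = (len(a) * (len(a) - 1) // 2) if b is None else len(a) * len(b)
    attempts = 0
    limit = 50 * max(n, 1) + 1000
    while len(picked) < n and attempts < limit:
        attempts += 1
        if b is None:
            if len(a) < 2:
                break
            i, j = rng.choice(len(a), size=2, replace=False)
            p = canonical_pair(a[i], a[j])
        else:
            if not a or not b:
                break
            d1 = a[rng.integers(len(a))]
            d2 = b[rng.integers(len(b))]
            if d1 == d2:
                continue
            p = canonical_pair(d1, d2)
        if p not in known and p not in picked:
            picked.add(p)
    if len(picked) < n:
        # exhaustive fallback: enumerate the whole block
        if b is None:
            candidates = {
                canonical_pair(a[i], a[j])
                for i in range(len(a))
                for j in range(i + 1, len(a))
            }
        else:
            candidates = {canonical_pair(x, y) for x in a for y in b if x != y}
        candidates = sorted(candidates - known - picked)
        need = n - len(picked)
        if len(candidates) < need:
            raise ValueError(
                f"block {block_name!r} has only {max_pairs} pairs, "
                f"not enough unknown pairs to draw {n} negatives"
            )
        idx = rng.choice(len(candidates), size=need, replace=False)
        picked.update(candidates[i] for i in np.atleast_1d(idx))
    return sorted(picked)


def sample_negatives(
    ref: ReferenceDDISet, fold: FoldSplit, seed: int = 0
) -> dict[str, list[Pair]]:
    """Per-subset negatives matching each subset's positive count and block.

    Train negatives come from existing x existing, drug-wise negatives from
    existing x cold-start, pairwise negatives from cold-start x cold-start.
    No sampled pair is a known DDI anywhere in the full reference set.
    """
    rng = np.random.default_rng(seed)
    existing = sorted(fold.existing)
    cold = sorted(fold.coldstart)
    out = {
        "train": _sample_block(
            existing, None, len(fold.train_pairs), ref.known_pairs, rng, "train"
        ),
        "drugwise": _sample_block(
            existing, cold, len(fold.drugwise_pairs), ref.known_pairs, rng, "drugwise"
        ),
        "pairwise": _sample_block(
            cold, None, len(fold.pairwise_pairs), ref.known_pairs, rng, "pairwise"
        ),
    }
    for subset, negs in out.items():
        for p in negs:
            expected = {"train": "train", "drugwise": "drugwise", "pairwise": "pairwise"}[subset]
            assert classify_pair(p, fold.coldstart) == expected
    return out


def sample_negatives_global(
    ref: ReferenceDDISet, n: int, seed: int = 0
) -> list[Pair]:
    """Draw n unknown pairs uniformly from the whole pair space (traditional CV)."""
    rng = np.random.default_rng(seed)
    return _sample_block(sorted(ref.drugs), None, n, ref.known_pairs, rng, "global")


def pair_features(emb: EmbeddingTable, pairs: Sequence[Pair]) -> np.ndarray:
    """Row i = concat(vector(d1), vector(d2)) in canonical pair order."""
    out = np.empty((len(pairs), 2 * emb.dim))
    for i, (d1, d2) in enumerate(pairs):
        if d1 not in emb:
            raise KeyError(f"drug without embedding vector: {d1!r}")
        if d2 not in emb:
            raise KeyError(f"drug without embedding vector: {d2!r}")
        out[i, : emb.dim] = emb[d1]
        out[i, emb.dim :] = emb[d2]
    return out


@dataclass(frozen=True)
class FilterReport:
    n_drugs_removed: int
    n_pairs_removed: int
    removed_drugs: tuple[str, ...]


def filter_drugs_with_embeddings(
    ref: ReferenceDDISet, emb: EmbeddingTable
) -> tuple[ReferenceDDISet, FilterReport]:
    """Restrict the reference set to drugs that have an embedding vector."""
    keep = {d for d in ref.drugs if d in emb}
    removed = ref.drugs - keep
    pairs = {p for p in ref.known_pairs if p[0] in keep and p[1] in keep}
    labels = None
    if ref.type_labels is not None:
        labels = {p: t for p, t in ref.type_labels.items() if p in pairs}
    report = FilterReport(
        n_drugs_removed=len(removed),
        n_pairs_removed=len(ref.known_pairs) - len(pairs),
        removed_drugs=tuple(sorted(removed)),
    )
    return ReferenceDDISet(keep, pairs, labels), report


def build_dataset(
    emb: EmbeddingTable, positives: Iterable[Pair], negatives: Iterable[Pair]
) -> LabeledPairDataset:
    """Stack positives and negatives into one aligned labeled dataset."""
    pos = sorted(set(positives))
    neg = sorted(set(negatives))
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:3]}")
    pairs = pos + neg
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return LabeledPairDataset(pairs, labels, pair_features(emb, pairs))
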