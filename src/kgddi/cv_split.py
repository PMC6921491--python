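"""Cross-validation schemes for paired drug data.

Traditional k-fold CV partitions drug *pairs*, so the same drug appears in
both training and test pairs and performance estimates are optimistic for
drugs without any known interactions.  The disjoint schemes here instead
partition *drugs* into k groups; the group held out in a fold is the
cold-start set, and the known interactions split into three disjoint blocks:

* ``train``    — both drugs existing,
* ``drugwise`` — exactly one drug cold-start (one-sided cold start),
* ``pairwise`` — both drugs cold-start (fully unseen pairs).

A single training set serves both test blocks in each fold.  A time-slice
scheme (train on an early snapshot, test on interactions added later) is
also provided, together with a helper contrasting the round counts of the
within/between-group alternative ("CV2") scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pair",
    "canonical_pair",
    "ReferenceDDISet",
    "FoldSplit",
    "SnapshotPair",
    "classify_pair",
    "disjoint_folds",
    "coldstart_split",
    "traditional_folds",
    "timeslice_split",
    "cv2_round_counts",
    "write_fold_manifest",
    "read_fold_manifest",
]

Pair = tuple[str, str]


def canonical_pair(d1: str, d2: str) -> Pair:
    """Unordered pair in lexicographic (min, max) order; self-pairs rejected."""
    if d1 == d2:
        raise ValueError(f"self-pair is not a valid drug pair: {d1!r}")
    return (d1, d2) if d1 < d2 else (d2, d1)


@dataclass
class ReferenceDDISet:
    """Drug universe plus canonical known-interaction pairs (optional types)."""

    drugs: set[str]
    known_pairs: set[Pair]
    type_labels: dict[Pair, str] | None = None

    def __post_init__(self) -> None:
        for d1, d2 in self.known_pairs:
            if d1 >= d2:
                raise ValueError(f"pair not canonical: {(d1, d2)!r}")
            if d1 not in self.drugs or d2 not in self.drugs:
                raise ValueError(f"pair {(d1, d2)!r} references a drug outside the universe")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str] | tuple[str, str, str]],
        drugs: Iterable[str] | None = None,
    ) -> "ReferenceDDISet":
        """Build from (drug1, drug2[, type]) rows; pairs are canonicalized."""
        known: set[Pair] = set()
        labels: dict[Pair, str] = {}
        universe: set[str] = set(drugs) if drugs is not None else set()
        typed = False
        for row in pairs:
            p = canonical_pair(row[0], row[1])
            known.add(p)
            universe.update(p)
            if len(row) > 2:
                typed = True
                labels[p] = str(row[2])
        return cls(universe, known, labels if typed else None)

    @classmethod
    def read_table(cls, path: str | Path, sep: str = "\t") -> "ReferenceDDISet":
        """Read a two- or three-column delimited (drug1, drug2[, type]) table."""
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("DDI table needs at least two columns")
        return cls.from_pairs(df.itertuples(index=False, name=None))


@dataclass
class FoldSplit:
    """One fold of the disjoint scheme: drug partition and the three pair blocks."""

    fold_index: int
    existing: set[str]
    coldstart: set[str]
    train_pairs: set[Pair]
    drugwise_pairs: set[Pair]
    pairwise_pairs: set[Pair]


@dataclass
class SnapshotPair:
    """Two DDI snapshots of the same universe taken at different times."""

    early: ReferenceDDISet
    late: ReferenceDDISet

    def missing_from_late(self) -> set[Pair]:
        """Early pairs absent from the late snapshot (should be empty)."""
        return self.early.known_pairs - self.late.known_pairs


def classify_pair(pair: Pair, coldstart: set[str]) -> str:
    """Assign a canonical pair to train / drugwise / pairwise for a cold-start set."""
    n_cold = (pair[0] in coldstart) + (pair[1] in coldstart)
    return ("train", "drugwise", "pairwise")[n_cold]


def _partition_groups(items: Sequence[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    """Shuffle once, then split into k contiguous near-equal blocks."""
    order = list(items)
    perm = rng.permutation(len(order))
    shuffled = [order[i] for i in perm]
    sizes = np.full(k, len(order) // k)
    sizes[: len(order) % k] += 1
    groups, start = [], 0
    for s in sizes:
        groups.append(shuffled[start : start + int(s)])
        start += int(s)
    return groups


def disjoint_folds(ref: ReferenceDDISet, k: int, seed: int = 0) -> list[FoldSplit]:
    """Drug-wise/pairwise disjoint k-fold CV.

    Drugs (including those with no known interaction — they matter for
    negative sampling blocks) are partitioned uniformly at random into k
    near-equal groups.  Fold i treats group i as cold-start drugs; every
    known pair falls into exactly one of the three blocks via
    :func:`classify_pair`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ref.drugs):
        raise ValueError(f"k={k} exceeds the number of drugs ({len(ref.drugs)})")
    rng = np.random.default_rng(seed)
    groups = _partition_groups(sorted(ref.drugs), k, rng)
    folds = []
    for i, group in enumerate(groups):
        cold = set(group)
        existing = ref.drugs - cold
        blocks: dict[str, set[Pair]] = {"train": set(), "drugwise": set(), "pairwise": set()}
        for pair in ref.known_pairs:
            blocks[classify_pair(pair, cold)].add(pair)
        folds.append(
            FoldSplit(i, existing, cold, blocks["train"], blocks["drugwise"], blocks["pairwise"])
        )
    return folds


def coldstart_split(
    ref: ReferenceDDISet, coldstart_fraction: float, seed: int = 0
) -> FoldSplit:
    """Single random split holding out a fraction of drugs as cold-start.

    Used outside k-fold CV, e.g. a 10%-cold-start bias-check experiment.
    """
    if not 0 < coldstart_fraction < 1:
        raise ValueError("coldstart_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    drugs = sorted(ref.drugs)
    n_cold = max(1, int(round(coldstart_fraction * len(drugs))))
    perm = rng.permutation(len(drugs))
    cold = {drugs[i] for i in perm[:n_cold]}
    blocks: dict[str, set[Pair]] = {"train": set(), "drugwise": set(), "pairwise": set()}
    for pair in ref.known_pairs:
        blocks[classify_pair(pair, cold)].add(pair)
    return FoldSplit(0, ref.drugs - cold, cold, blocks["train"], blocks["drugwise"], blocks["pairwise"])


def traditional_folds(
    ref: ReferenceDDISet, k: int, seed: int = 0
) -> list[tuple[set[Pair], set[Pair]]]:
    """Classic k-fold CV on pairs: partition known pairs into k test groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ref.known_pairs):
        raise ValueError(f"k={k} exceeds the number of known pairs ({len(ref.known_pairs)})")
    rng = np.random.default_rng(seed)
    groups = _partition_groups(sorted(ref.known_pairs), k, rng)
    folds = []
    for i in range(k):
        test = set(groups[i])
        train = ref.known_pairs - test
        folds.append((train, test))
    return folds


def timeslice_split(
    snap: SnapshotPair, n_groups: int = 10, seed: int = 0
) -> tuple[set[Pair], list[set[Pair]]]:
    """Train on the early snapshot; test on interactions added by the late one.

    The novel-interaction pool ``late - early`` is split randomly into
    ``n_groups`` near-equal subsets so scores can be averaged over groups.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    pool = snap.late.known_pairs - snap.early.known_pairs
    if not pool:
        raise ValueError("no novel interactions: the late snapshot adds no pairs")
    rng = np.random.default_rng(seed)
    n_groups = min(n_groups, len(pool))
    groups = _partition_groups(sorted(pool), n_groups, rng)
    return set(snap.early.known_pairs), [set(g) for g in groups]


def cv2_round_counts(k: int) -> tuple[int, int]:
    """Round counts of the within/between-group alternative at k folds.

    Within-group sampling yields one round per group (k); between-group
    sampling yields one per unordered group pair (k(k-1)/2).  The disparity
    is why averaging the two samplings can bias the estimate.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return k, k * (k - 1) // 2


def write_fold_manifest(folds: Sequence[FoldSplit], path: str | Path, sep: str = "\t") -> None:
    """One row per known pair per fold: (fold, subset, drug1, drug2)."""
    rows = []
    for f in folds:
        for subset, pairs in (
            ("train", f.train_pairs),
            ("drugwise", f.drugwise_pairs),
            ("pairwise", f.pairwise_pairs),
        ):
            for d1, d2 in sorted(pairs):
                rows.append((f.fold_index, subset, d1, d2))
    pd.DataFrame(rows, columns=["fold", "subset", "drug1", "drug2"]).to_csv(
        path, sep=sep, index=False
    )


def read_fold_manifest(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"fold": int, "subset": str, "drug1": str, "drug2": str})
    expected = {"fold", "subset", "drug1", "drug2"}
    if not expected.issubset(df.columns):
        raise ValueError(f"fold manifest must have columns {sorted(expected)}")
    return df
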