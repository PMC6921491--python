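"""Chi-square diagnostic: does a disjoint split distort DDI-type composition?

A realistic split should hold out drugs, not mechanisms.  This module
tallies the categorical DDI-type distribution of a pair set and tests, per
fold, whether the test-set distribution is consistent with the training-set
distribution using a Pearson goodness-of-fit statistic (rare types pooled so
every expected count reaches a minimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cv_split import FoldSplit, Pair, ReferenceDDISet

__all__ = [
    "TypeDistribution",
    "ChiSquareResult",
    "type_distribution",
    "chi_square_consistency",
    "fold_type_consistency",
]


@dataclass
class TypeDistribution:
    """Counts per DDI-type ID over a pair set."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")

    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {t: c / self.total for t, c in self.counts.items()}


def type_distribution(
    pairs: Iterable[Pair],
    type_labels: Mapping[Pair, str],
    *,
    exclude_unlabeled: bool = False,
) -> TypeDistribution:
    """Tally DDI types over a pair set.

    A pair without a label raises unless ``exclude_unlabeled`` is set, in
    which case it is dropped from the tally.
    """
    counts: dict[str, int] = {}
    total = 0
    for p in pairs:
        if p not in type_labels:
            if exclude_unlabeled:
                continue
            raise KeyError(f"pair {p!r} has no DDI-type label")
        t = type_labels[p]
        counts[t] = counts.get(t, 0) + 1
        total += 1
    return TypeDistribution(counts, total)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    n_cells: int


def chi_square_consistency(
    train: TypeDistribution,
    test: TypeDistribution,
    min_expected: float = 5.0,
    *,
    train_as_sample: bool = True,
) -> ChiSquareResult:
    """Pearson chi-square consistency of test type counts with the train set.

    Expected counts are ``test.total x train proportion`` per type and the
    raw statistic is the Pearson sum ``(O - E)^2 / E``.  Because the train
    composition is itself estimated from a finite sample, the difference
    ``O/n_test - p_train`` has variance inflated by ``1 + n_test/n_train``;
    with ``train_as_sample=True`` (default) the statistic is divided by
    that factor, which keeps the test calibrated for any train/test size
    ratio.  Set ``train_as_sample=False`` when the train side is a known
    reference composition rather than a sample.

    Types whose expected test count falls below ``min_expected`` are
    pooled into a single residual cell before computing the statistic;
    degrees of freedom are (cells after pooling) - 1.
    """
    if train.total <= 0 or test.total <= 0:
        raise ValueError("both distributions must be non-empty")
    types = sorted(set(train.counts) | set(test.counts))
    train_p = train.proportions()
    expected = np.array([test.total * train_p.get(t, 0.0) for t in types])
    observed = np.array([test.counts.get(t, 0) for t in types], dtype=float)

    keep = expected >= min_expected

    def pooled(values: np.ndarray) -> np.ndarray:
        cells = list(values[keep])
        if (~keep).any():
            cells.append(values[~keep].sum())
        return np.array(cells)

    obs = pooled(observed)
    exp = pooled(expected)
    if len(obs) < 2:
        raise ValueError("fewer than 2 cells after pooling; cannot run the test")
    if np.any(exp <= 0):
        raise ValueError("a cell has zero expected count after pooling")
    dof = len(obs) - 1
    statistic = float(((obs - exp) ** 2 / exp).sum())
    if train_as_sample:
        statistic /= 1.0 + test.total / train.total
    p = float(stats.chi2.sf(statistic, dof))
    return ChiSquareResult(statistic, dof, p, len(obs))


def fold_type_consistency(
    ref: ReferenceDDISet,
    folds: Sequence[FoldSplit],
    min_expected: float = 5.0,
    *,
    per_subset: bool = False,
    exclude_unlabeled: bool = False,
    train_as_sample: bool = True,
) -> pd.DataFrame:
    """Per-fold chi-square table comparing test against train type composition.

    By default the test distribution is the union of the drug-wise and
    pairwise test sets; ``per_subset`` reports each test block separately.
    Both sides are finite samples of the same reference set, so the
    calibrated two-sample form of :func:`chi_square_consistency` is used
    unless ``train_as_sample`` is disabled.  Returns a table with columns
    (fold, subset, statistic, dof, p_value).
    """
    if ref.type_labels is None:
        raise ValueError("reference set carries no DDI-type labels")
    rows = []
    for fold in folds:
        train_dist = type_distribution(
            fold.train_pairs, ref.type_labels, exclude_unlabeled=exclude_unlabeled
        )
        if per_subset:
            blocks = {"drugwise": fold.drugwise_pairs, "pairwise": fold.pairwise_pairs}
        else:
            blocks = {"combined": fold.drugwise_pairs | fold.pairwise_pairs}
        for subset, pairs in blocks.items():
            test_dist = type_distribution(
                pairs, ref.type_labels, exclude_unlabeled=exclude_unlabeled
            )
            res = chi_square_consistency(
                train_dist, test_dist, min_expected, train_as_sample=train_as_sample
            )
            rows.append((fold.fold_index, subset, res.statistic, res.dof, res.p_value))
    return pd.DataFrame(rows, columns=["fold", "subset", "statistic", "dof", "p_value"])
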