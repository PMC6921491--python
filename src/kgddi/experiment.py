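"""Classifier training and CV-scheme evaluation over embedding pair features.

The classifiers follow the common DDI-prediction setting: logistic
regression (C = 0.01), Gaussian naive Bayes, and a random forest with 200
estimators of maximum depth 8.  Metrics are AUC, AUPR (step-interpolated
precision-recall area) and F1 at a fixed probability threshold.  Scores are
averaged over folds and over independently seeded runs; every run re-draws
the fold assignment and the negative samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB

from .cv_split import (
    Pair,
    ReferenceDDISet,
    SnapshotPair,
    _partition_groups,
    disjoint_folds,
    timeslice_split,
    traditional_folds,
)
from .embed_models import EmbeddingTable
from .pair_dataset import (
    _sample_block,
    build_dataset,
    sample_negatives,
    sample_negatives_global,
)

__all__ = [
    "ClassifierSpec",
    "Metrics",
    "EvalReport",
    "train_classifier",
    "evaluate_scores",
    "run_cv_experiment",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus the hyperparameters that matter for it."""

    family: str = "random_forest"
    C: float = 0.01  # logistic regression regularization
    n_estimators: int = 200  # random forest
    max_depth: int | None = 8  # random forest
    seed: int = 0

    def build(self):
        if self.family == "logistic_regression":
            return LogisticRegression(C=self.C, max_iter=2000)
        if self.family == "naive_bayes_gaussian":
            return GaussianNB()
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=self.seed,
                n_jobs=1,
            )
        raise ValueError(f"unknown classifier family {self.family!r}")


def train_classifier(features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec):
    """Fit the specified classifier; returns an estimator with predict_proba."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    est = spec.build()
    est.fit(features, labels)
    return est


def _scores(est, features: np.ndarray) -> np.ndarray:
    return est.predict_proba(features)[:, 1]


@dataclass(frozen=True)
class Metrics:
    auc: float
    aupr: float
    f1: float


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> Metrics:
    """AUC, step-interpolated AUPR, and F1 at a probability threshold.

    AUC is the probability that a random positive outranks a random
    negative, with ties counted one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("labels and scores must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute ranking metrics")
    return Metrics(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, (scores >= threshold).astype(int))),
    )


@dataclass
class EvalReport:
    """Per-fold metric rows and their per-subset means."""

    scheme: str
    n_runs: int
    records: pd.DataFrame  # columns: run, fold, subset, auc, aupr, f1, n_test

    def summary(self) -> pd.DataFrame:
        """Mean AUC/AUPR/F1 per subset across folds and runs."""
        return self.records.groupby("subset")[["auc", "aupr", "f1"]].mean()

    def mean(self, subset: str, metric: str = "auc") -> float:
        sel = self.records[self.records["subset"] == subset]
        if sel.empty:
            raise KeyError(f"no records for subset {subset!r}")
        return float(sel[metric].mean())

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_runs": self.n_runs,
            "records": self.records.to_dict(orient="records"),
            "summary": {
                subset: row.to_dict() for subset, row in self.summary().iterrows()
            },
        }


def _audit_no_leakage(train_pairs: set[Pair], test_pairs: Sequence[Pair]) -> None:
    leaked = train_pairs.intersection(test_pairs)
    if leaked:
        raise AssertionError(f"test pairs leaked into training: {sorted(leaked)[:3]}")


def _fit_and_eval(emb, train_pos, train_neg, tests, spec, rng, permute_labels, threshold):
    """Train once, evaluate on each named test set; returns metric rows."""
    train_ds = build_dataset(emb, train_pos, train_neg)
    labels = train_ds.labels
    if permute_labels:
        labels = labels[rng.permutation(len(labels))]
    est = train_classifier(train_ds.features, labels, spec)
    train_set = set(train_ds.pairs)
    rows = []
    for subset, (pos, neg) in tests.items():
        if not pos or not neg:
            continue
        test_ds = build_dataset(emb, pos, neg)
        _audit_no_leakage(train_set, test_ds.pairs)
        m = evaluate_scores(test_ds.labels, _scores(est, test_ds.features), threshold)
        rows.append((subset, m, len(test_ds.pairs)))
    return est, train_ds, rows


def run_cv_experiment(
    emb: EmbeddingTable,
    ref: ReferenceDDISet,
    scheme: str = "disjoint",
    spec: ClassifierSpec | None = None,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    snapshots: SnapshotPair | None = None,
    permute_labels: bool = False,
    include_train: bool = False,
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate a classifier on embedding features under one CV scheme.

    Each run re-seeds the fold assignment and negative sampling.  For the
    disjoint scheme a single training set per fold serves both the
    drug-wise and the pairwise test sets; ``include_train`` additionally
    reports in-sample training metrics.  ``permute_labels`` shuffles
    training labels as a null-calibration control.
    """
    spec = spec or ClassifierSpec()
    if scheme not in ("disjoint", "traditional", "timeslice"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "timeslice" and snapshots is None:
        raise ValueError("timeslice scheme requires a SnapshotPair")
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    for run, run_seed in enumerate(map(int, seeds)):
        rng = np.random.default_rng(run_seed)
        if scheme == "disjoint":
            for fold in disjoint_folds(ref, k, seed=run_seed):
                negs = sample_negatives(ref, fold, seed=run_seed + fold.fold_index)
                tests = {
                    "drugwise": (fold.drugwise_pairs, negs["drugwise"]),
                    "pairwise": (fold.pairwise_pairs, negs["pairwise"]),
                }
                est, train_ds, evals = _fit_and_eval(
                    emb, fold.train_pairs, negs["train"], tests, spec, rng,
                    permute_labels, threshold,
                )
                if include_train and len(np.unique(train_ds.labels)) == 2:
                    m = evaluate_scores(
                        train_ds.labels, _scores(est, train_ds.features), threshold
                    )
                    evals.append(("train", m, len(train_ds.pairs)))
                for subset, m, n in evals:
                    rows.append((run, fold.fold_index, subset, m.auc, m.aupr, m.f1, n))
        elif scheme == "traditional":
            pos_folds = traditional_folds(ref, k, seed=run_seed)
            negatives = sample_negatives_global(ref, len(ref.known_pairs), seed=run_seed)
            neg_groups = _partition_groups(sorted(negatives), k, rng)
            for i, (train_pos, test_pos) in enumerate(pos_folds):
                test_neg = set(neg_groups[i])
                train_neg = set(negatives) - test_neg
                _, _, evals = _fit_and_eval(
                    emb, train_pos, train_neg, {"test": (test_pos, test_neg)},
                    spec, rng, permute_labels, threshold,
                )
                for subset, m, n in evals:
                    rows.append((run, i, subset, m.auc, m.aupr, m.f1, n))
        else:  # timeslice
            train_pos, test_groups = timeslice_split(snapshots, n_groups=k, seed=run_seed)
            universe = snapshots.late
            train_neg = sample_negatives_global(universe, len(train_pos), seed=run_seed)
            used: set[Pair] = set(train_neg)
            drug_list = sorted(universe.drugs)
            for i, test_pos in enumerate(test_groups):
                test_neg = set(
                    _sample_block(
                        drug_list, None, len(test_pos),
                        universe.known_pairs | used, rng, "timeslice-test",
                    )
                )
                used |= test_neg
                _, _, evals = _fit_and_eval(
                    emb, train_pos, train_neg, {"test": (test_pos, test_neg)},
                    spec, rng, permute_labels, threshold,
                )
                for subset, m, n in evals:
                    rows.append((run, i, subset, m.auc, m.aupr, m.f1, n))
    records = pd.DataFrame(
        rows, columns=["run", "fold", "subset", "auc", "aupr", "f1", "n_test"]
    )
    return EvalReport(scheme=scheme, n_runs=n_runs, records=records)
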