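"""Disjoint / traditional / time-slice CV schemes and their partition invariants."""

import itertools

import numpy as np
import pytest

from kgddi.cv_split import (
    ReferenceDDISet,
    SnapshotPair,
    canonical_pair,
    classify_pair,
    coldstart_split,
    cv2_round_counts,
    disjoint_folds,
    read_fold_manifest,
    timeslice_split,
    traditional_folds,
    write_fold_manifest,
)


def random_ref(rng, n_drugs=20, density=0.2):
    drugs = [f"d{i:02d}" for i in range(n_drugs)]
    pairs = {
        canonical_pair(a, b)
        for a, b in itertools.combinations(drugs, 2)
        if rng.random() < density
    }
    return ReferenceDDISet(set(drugs), pairs)


def test_canonical_pair_orders_and_rejects_self():
    assert canonical_pair("b", "a") == ("a", "b")
    with pytest.raises(ValueError):
        canonical_pair("a", "a")


@pytest.mark.parametrize(
    "coldstart,expected",
    [(set(), "train"), ({"A"}, "drugwise"), ({"A", "B"}, "pairwise"), ({"Z"}, "train")],
)
def test_classify_pair(coldstart, expected):
    assert classify_pair(("A", "B"), coldstart) == expected


class TestDisjointFolds:
    def test_toy_ten_drugs_fourteen_ddis_two_folds(self, rng):
        """2-fold partitioning of a 10-drug / 14-interaction toy reference:
        each fold's three blocks exactly partition the 14 pairs."""
        ref = None
        while ref is None or len(ref.known_pairs) != 14:
            ref = random_ref(rng, n_drugs=10, density=0.31)
        folds = disjoint_folds(ref, k=2, seed=1)
        assert len(folds) == 2
        for f in folds:
            blocks = [f.train_pairs, f.drugwise_pairs, f.pairwise_pairs]
            assert set().union(*blocks) == ref.known_pairs
            assert sum(len(b) for b in blocks) == 14  # mutually disjoint
            assert len(f.coldstart) == 5 and len(f.existing) == 5

    def test_k_equals_n_drugs_has_no_pairwise_pairs(self, rng):
        ref = random_ref(rng, n_drugs=8, density=0.4)
        folds = disjoint_folds(ref, k=8, seed=0)
        for f in folds:
            assert len(f.coldstart) == 1
            assert f.pairwise_pairs == set()

    def test_random_instances_match_exhaustive_labeling(self, rng):
        for trial in range(100):
            n = int(rng.integers(5, 31))
            k = int(rng.integers(2, min(n, 8) + 1))
            ref = random_ref(rng, n_drugs=n, density=float(rng.uniform(0.1, 0.5)))
            folds = disjoint_folds(ref, k, seed=trial)
            cold_union = set()
            for f in folds:
                expected = {"train": set(), "drugwise": set(), "pairwise": set()}
                for p in ref.known_pairs:
                    expected[classify_pair(p, f.coldstart)].add(p)
                assert f.train_pairs == expected["train"]
                assert f.drugwise_pairs == expected["drugwise"]
                assert f.pairwise_pairs == expected["pairwise"]
                # cold-start isolation
                train_drugs = {d for p in f.train_pairs for d in p}
                assert not train_drugs & f.coldstart
                for p in f.pairwise_pairs:
                    assert p[0] in f.coldstart and p[1] in f.coldstart
                for p in f.drugwise_pairs:
                    assert len({p[0], p[1]} & f.coldstart) == 1
                assert f.existing | f.coldstart == ref.drugs
                assert not f.existing & f.coldstart
                cold_union |= f.coldstart
            # every drug cold-start in exactly one fold; near-equal groups
            assert cold_union == ref.drugs
            sizes = [len(f.coldstart) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, rng):
        ref = random_ref(rng)
        a = disjoint_folds(ref, 4, seed=9)
        b = disjoint_folds(ref, 4, seed=9)
        for fa, fb in zip(a, b):
            assert fa.coldstart == fb.coldstart

    def test_invalid_k(self, rng):
        ref = random_ref(rng, n_drugs=5)
        with pytest.raises(ValueError):
            disjoint_folds(ref, 1)
        with pytest.raises(ValueError):
            disjoint_folds(ref, 6)


def test_coldstart_split_fraction(rng):
    ref = random_ref(rng, n_drugs=30)
    split = coldstart_split(ref, 0.1, seed=0)
    assert len(split.coldstart) == 3
    for p in ref.known_pairs:
        assert p in {
            "train": split.train_pairs,
            "drugwise": split.drugwise_pairs,
            "pairwise": split.pairwise_pairs,
        }[classify_pair(p, split.coldstart)]


class TestTraditionalFolds:
    def test_fourteen_pairs_two_folds(self, rng):
        ref = None
        while ref is None or len(ref.known_pairs) != 14:
            ref = random_ref(rng, n_drugs=10, density=0.31)
        folds = traditional_folds(ref, 2, seed=0)
        assert sorted(len(test) for _, test in folds) == [7, 7]

    def test_test_sets_partition_known_pairs(self, rng):
        ref = random_ref(rng)
        folds = traditional_folds(ref, 5, seed=3)
        tests = [test for _, test in folds]
        assert set().union(*tests) == ref.known_pairs
        assert sum(len(t) for t in tests) == len(ref.known_pairs)
        for train, test in folds:
            assert train == ref.known_pairs - test


class TestTimeslice:
    def test_identical_snapshots_error(self, rng):
        ref = random_ref(rng)
        snap = SnapshotPair(early=ref, late=ref)
        with pytest.raises(ValueError, match="novel"):
            timeslice_split(snap, 5, seed=0)

    def test_novel_pool_split_into_groups(self, rng):
        ref = random_ref(rng, n_drugs=30, density=0.15)
        pairs = sorted(ref.known_pairs)
        assert len(pairs) > 30
        early = ReferenceDDISet(set(ref.drugs), set(pairs[:10]))
        late = ReferenceDDISet(set(ref.drugs), set(pairs[:30]))
        train, groups = timeslice_split(SnapshotPair(early, late), 10, seed=0)
        assert train == early.known_pairs
        assert len(groups) == 10 and all(len(g) == 2 for g in groups)
        assert set().union(*groups) == late.known_pairs - early.known_pairs

    def test_pool_matches_set_difference(self, rng):
        for _ in range(10):
            ref = random_ref(rng, n_drugs=15, density=0.3)
            pairs = sorted(ref.known_pairs)
            cut = len(pairs) // 2
            early = ReferenceDDISet(set(ref.drugs), set(pairs[:cut]))
            snap = SnapshotPair(early, ref)
            _, groups = timeslice_split(snap, 3, seed=1)
            assert set().union(*groups) == ref.known_pairs - early.known_pairs

    def test_missing_from_late_reported(self, rng):
        ref = random_ref(rng)
        pairs = sorted(ref.known_pairs)
        early = ReferenceDDISet(set(ref.drugs), set(pairs))
        late = ReferenceDDISet(set(ref.drugs), set(pairs[1:]))
        snap = SnapshotPair(early, late)
        assert snap.missing_from_late() == {pairs[0]}


class TestCv2RoundCounts:
    def test_reference_values(self):
        assert cv2_round_counts(10) == (10, 45)
        assert cv2_round_counts(2) == (2, 1)

    def test_matches_enumeration(self):
        k = 7
        within, between = cv2_round_counts(k)
        assert within == k
        assert between == len(list(itertools.combinations(range(k), 2)))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            cv2_round_counts(1)


def test_fold_manifest_roundtrip(tmp_path, rng):
    ref = random_ref(rng)
    folds = disjoint_folds(ref, 3, seed=0)
    path = tmp_path / "folds.tsv"
    write_fold_manifest(folds, path)
    df = read_fold_manifest(path)
    assert len(df) == 3 * len(ref.known_pairs)
    for f in folds:
        sub = df[(df["fold"] == f.fold_index) & (df["subset"] == "pairwise")]
        assert {tuple(x) for x in sub[["drug1", "drug2"]].values} == f.pairwise_pairs
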