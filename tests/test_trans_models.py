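"""Translational embeddings: scoring, corruption, projection, training, gradients."""

import numpy as np
import pytest

from kgddi.kg_io import Triple
from kgddi.embed_models import (
    EmbeddingTable,
    TransConfig,
    TransDModel,
    TransEModel,
    corrupt_triple,
    train_transd,
    train_transe,
    transd_pair_loss_grad,
    transd_project,
    transd_score,
    transe_pair_loss_grad,
    transe_score,
)


def toy_triples(rng, n_entities=12, n_relations=2, n=30):
    ents = [f"e{i}" for i in range(n_entities)]
    out = []
    for _ in range(n):
        h, t = rng.choice(n_entities, 2, replace=False)
        out.append(Triple(ents[h], f"r{rng.integers(n_relations)}", ents[t]))
    return ents, out


class TestCorruptTriple:
    def test_forced_head_replacement(self):
        # pool {A,B}: whichever slot is corrupted, the replacement is forced
        t = Triple("A", "r", "B")
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = corrupt_triple(t, {"A", "B"}, rng)
            assert c in (Triple("B", "r", "B"), Triple("A", "r", "A"))
            assert c.predicate == "r"

    def test_branch_frequencies_balanced(self):
        t = Triple("A", "r", "B")
        pool = {"A", "B", "C", "D"}
        rng = np.random.default_rng(1)
        n = 10_000
        head = sum(corrupt_triple(t, pool, rng).subject != "A" for _ in range(n))
        # binomial(n, 0.5): 4 sigma band
        assert abs(head - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_never_equals_original(self):
        t = Triple("A", "r", "B")
        rng = np.random.default_rng(2)
        assert all(corrupt_triple(t, {"A", "B", "C"}, rng) != t for _ in range(10_000))

    def test_degenerate_pool_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            # whichever branch is drawn, the only candidate equals the original
            corrupt_triple(Triple("A", "r", "A"), {"A"}, rng)


class TestTransEScore:
    def model(self, vectors, relations):
        return TransEModel(
            EmbeddingTable(list(vectors), np.array(list(vectors.values()), float)),
            EmbeddingTable(list(relations), np.array(list(relations.values()), float)),
        )

    def test_exact_translation_scores_zero(self):
        m = self.model({"h": [1, 0], "t": [1, 1]}, {"r": [0, 1]})
        assert transe_score(m, "h", "r", "t") == pytest.approx(0.0)

    def test_all_zero_vectors_score_zero(self):
        m = self.model({"h": [0, 0], "t": [0, 0]}, {"r": [0, 0]})
        assert transe_score(m, "h", "r", "t") == 0.0

    def test_matches_hand_computed_norms(self, rng):
        h, r, t = rng.normal(size=(3, 5))
        m = TransEModel(
            EmbeddingTable(["h", "t"], np.stack([h, t])),
            EmbeddingTable(["r"], r[None]),
            norm="L2",
        )
        expected = float(np.sqrt(((h + r - t) ** 2).sum()))
        assert transe_score(m, "h", "r", "t") == pytest.approx(expected)
        m.norm = "L1"
        assert transe_score(m, "h", "r", "t") == pytest.approx(float(np.abs(h + r - t).sum()))


class TestTransDProject:
    def model(self, rng, m=4, n=4):
        ents = ["a", "b"]
        return TransDModel(
            EmbeddingTable(ents, rng.normal(size=(2, m))),
            EmbeddingTable(ents, rng.normal(size=(2, m))),
            EmbeddingTable(["r"], rng.normal(size=(1, n))),
            EmbeddingTable(["r"], rng.normal(size=(1, n))),
        )

    def test_zero_relation_projection_is_identity(self, rng):
        md = self.model(rng)
        md.relation_projections.matrix[:] = 0.0
        np.testing.assert_allclose(
            transd_project(md, "a", "r"), md.entity_vectors["a"]
        )

    def test_orthogonal_projection_vector_reduces_to_resize(self, rng):
        md = self.model(rng, m=4, n=3)
        e = md.entity_vectors["a"]
        # build e_p orthogonal to e
        ep = rng.normal(size=4)
        ep -= (ep @ e) / (e @ e) * e
        md.entity_projections.matrix[0] = ep
        np.testing.assert_allclose(transd_project(md, "a", "r"), e[:3], atol=1e-12)

    @pytest.mark.parametrize("m,n", [(4, 4), (5, 3), (3, 6)])
    def test_matches_dense_mapping_matrix(self, rng, m, n):
        md = self.model(rng, m=m, n=n)
        e = md.entity_vectors["a"]
        ep = md.entity_projections["a"]
        rp = md.relation_projections["r"]
        eye = np.zeros((n, m))
        eye[: min(m, n), : min(m, n)] = np.eye(min(m, n))
        M = np.outer(rp, ep) + eye
        np.testing.assert_allclose(transd_project(md, "a", "r"), M @ e)


def test_hinge_inactive_gives_zero_loss():
    # true triple is an exact translation, corruption is far: margin satisfied
    h, r, t = np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0])
    hc, tc = np.array([5.0, 5.0]), np.array([-5.0, -5.0])
    loss, grads = transe_pair_loss_grad(h, r, t, hc, tc, margin=1.0)
    assert loss == 0.0
    assert all(np.all(g == 0) for g in grads.values())


def central_difference(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


def test_transe_gradient_matches_central_difference(rng):
    vs = {k: rng.normal(size=8) for k in ("h", "r", "t", "hc", "tc")}
    loss, grads = transe_pair_loss_grad(**vs, margin=5.0)
    assert loss > 0  # hinge active so the gradient is informative
    for name in vs:
        def f(x, name=name):
            d = dict(vs)
            d[name] = x
            return transe_pair_loss_grad(**d, margin=5.0)[0]
        num = central_difference(f, vs[name])
        rel = np.abs(grads[name] - num).max() / np.abs(num).max()
        assert rel < 1e-4


def test_transd_gradient_matches_central_difference(rng):
    params = {k: rng.normal(size=7) for k in ("h", "h_p", "t", "t_p", "hc", "hc_p", "tc", "tc_p")}
    params["r"] = rng.normal(size=5)
    params["r_p"] = rng.normal(size=5)
    loss, grads = transd_pair_loss_grad(params, margin=30.0)
    assert loss > 0
    for name in params:
        def f(x, name=name):
            d = {k: v.copy() for k, v in params.items()}
            d[name] = x
            return transd_pair_loss_grad(d, margin=30.0)[0]
        num = central_difference(f, params[name])
        rel = np.abs(grads[name] - num).max() / np.abs(num).max()
        assert rel < 1e-4


def test_transd_with_zero_projections_reduces_to_transe(rng):
    """With all projection vectors zero and m = n the TransD hinge and its
    entity/relation gradients coincide with the TransE ones."""
    vs = {k: rng.normal(size=6) for k in ("h", "r", "t", "hc", "tc")}
    params = {
        "h": vs["h"], "t": vs["t"], "hc": vs["hc"], "tc": vs["tc"], "r": vs["r"],
        "h_p": np.zeros(6), "t_p": np.zeros(6), "hc_p": np.zeros(6),
        "tc_p": np.zeros(6), "r_p": np.zeros(6),
    }
    le, ge = transe_pair_loss_grad(**vs, margin=4.0)
    ld, gd = transd_pair_loss_grad(params, margin=4.0)
    assert ld == pytest.approx(le)
    for name in ("h", "r", "t", "hc", "tc"):
        np.testing.assert_allclose(gd[name], ge[name])


class TestTraining:
    def test_transe_separates_true_from_corrupted(self, rng):
        ents, triples = toy_triples(rng)
        cfg = TransConfig(dim=16, epochs=120, seed=0)
        m = train_transe(triples, cfg)
        rng2 = np.random.default_rng(50)
        true = np.mean([transe_score(m, t.subject, t.predicate, t.object) for t in triples])
        corr = [corrupt_triple(t, ents, rng2) for t in triples]
        fake = np.mean([transe_score(m, c.subject, c.predicate, c.object) for c in corr])
        assert true < fake

    def test_transe_entity_vectors_unit_norm(self, rng):
        _, triples = toy_triples(rng)
        m = train_transe(triples, TransConfig(dim=8, epochs=10, seed=1))
        norms = np.linalg.norm(m.entity_vectors.matrix, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_transd_separates_and_loss_shrinks(self, rng):
        ents, triples = toy_triples(rng, n=50)
        m = train_transd(triples, TransConfig(dim=12, rel_dim=10, epochs=120, seed=0))
        assert np.mean(m.epoch_losses[-10:]) < m.epoch_losses[0]
        rng2 = np.random.default_rng(51)
        true = np.mean([transd_score(m, t.subject, t.predicate, t.object) for t in triples])
        corr = [corrupt_triple(t, ents, rng2) for t in triples]
        fake = np.mean([transd_score(m, c.subject, c.predicate, c.object) for c in corr])
        assert true < fake

    def test_seed_determinism(self, rng):
        _, triples = toy_triples(rng)
        cfg = TransConfig(dim=8, epochs=5, seed=3)
        m1, m2 = train_transe(triples, cfg), train_transe(triples, cfg)
        np.testing.assert_array_equal(m1.entity_vectors.matrix, m2.entity_vectors.matrix)

    def test_empty_triples_raise(self):
        with pytest.raises(ValueError):
            train_transe([], TransConfig(dim=4))

    def test_planted_translation_improves_mean_rank(self, rng):
        """On a graph with exact translation structure, the trained model
        ranks the true tail above the random-init baseline."""
        # bipartite: a_i --r--> b_i, two relations with disjoint tail groups
        triples = [Triple(f"a{i}", "r0", f"b{i}") for i in range(8)]
        triples += [Triple(f"a{i}", "r1", f"c{i}") for i in range(8)]
        ents = sorted({t.subject for t in triples} | {t.object for t in triples})

        def mean_rank(model):
            ranks = []
            for t in triples:
                s_true = transe_score(model, t.subject, t.predicate, t.object)
                scores = [transe_score(model, t.subject, t.predicate, e) for e in ents]
                ranks.append(1 + sum(s < s_true for s in scores))
            return np.mean(ranks)

        base = train_transe(triples, TransConfig(dim=12, epochs=0, seed=2))
        trained = train_transe(triples, TransConfig(dim=12, epochs=200, seed=2))
        assert mean_rank(trained) < mean_rank(base)
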