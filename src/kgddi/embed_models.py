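"""Entity embedding learners: skip-gram / CBOW on walk corpora, TransE / TransD on triples.

Two families of representation learners are provided:

* word2vec-style models trained on the random-walk corpus.  Training uses
  negative sampling (the standard approximation to the full softmax); the
  exact softmax is kept in :func:`skipgram_probability` /
  :func:`cbow_probability` so the normalized model can be checked directly.
* translational models trained on the triples themselves.  TransE scores a
  triple by ``||h + r - t||``; TransD additionally projects entities into
  the relation space through per-entity/per-relation projection vectors,
  using vector operations only (no explicit projection matrices are built).

All trainers are plain-numpy minibatch SGD and are bit-reproducible under a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .graph_walks import WalkCorpus
from .kg_io import Triple

__all__ = [
    "EmbeddingTable",
    "Word2VecConfig",
    "Word2VecModel",
    "train_skipgram",
    "train_cbow",
    "skipgram_probability",
    "cbow_probability",
    "cbow_context_vector",
    "TransConfig",
    "TransEModel",
    "TransDModel",
    "corrupt_triple",
    "transe_score",
    "transd_project",
    "transd_score",
    "train_transe",
    "train_transd",
    "transe_pair_loss_grad",
    "transd_pair_loss_grad",
]


# ---------------------------------------------------------------------------
# Embedding container


class EmbeddingTable:
    """Token -> fixed-dimension vector lookup backed by a dense matrix."""

    def __init__(self, tokens: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError("matrix must be (n_tokens, dim)")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("embedding vectors must be finite")
        self.tokens: list[str] = list(tokens)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in embedding table")
        self.matrix = matrix

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.matrix[self.index[token]]
        except KeyError:
            raise KeyError(f"token not in embedding table: {token!r}") from None

    def save_word2vec(self, path: str | Path) -> None:
        """Write the word2vec text format: header ``count dim``, then rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self)} {self.dim}\n")
            for tok, row in zip(self.tokens, self.matrix):
                fh.write(tok + " " + " ".join(f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(tokens) != n:
            raise ValueError(f"header declares {n} rows, found {len(tokens)}")
        return cls(tokens, np.asarray(rows))


# ---------------------------------------------------------------------------
# word2vec on walk corpora


@dataclass(frozen=True)
class Word2VecConfig:
    """Skip-gram / CBOW hyperparameters.

    Defaults are the common biomedical-KG embedding setting: context window
    5, 5 epochs, 25 negative samples and dimension 100.
    """

    architecture: Literal["SG", "CBOW"] = "SG"
    window: int = 5
    dim: int = 100
    negative: int = 25
    epochs: int = 5
    subsample: float = 1e-3  # frequent-token subsampling threshold (0 disables)
    # step size of the per-token mean-gradient update; larger than classic
    # per-example SGD rates because duplicates in a batch are averaged
    learning_rate: float = 0.4
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negative < 0 or self.subsample < 0:
            raise ValueError("invalid word2vec configuration")
        if self.architecture not in ("SG", "CBOW"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # stable log(sigmoid(x)) = -log1p(exp(-x)) with clipping
    return -np.log1p(np.exp(-np.clip(x, -30, 30)))


class Word2VecModel:
    """A trained two-layer embedding model (input and output vectors).

    ``input_vectors`` (one per vocabulary token) are the embeddings used
    downstream; ``output_vectors`` parameterize the softmax and are kept so
    the model's conditional probabilities can be evaluated exactly.
    """

    def __init__(
        self,
        tokens: Sequence[str],
        input_matrix: np.ndarray,
        output_matrix: np.ndarray,
        architecture: str,
        epoch_losses: list[float] | None = None,
    ):
        self.input_vectors = EmbeddingTable(tokens, input_matrix)
        self.output_vectors = EmbeddingTable(tokens, output_matrix)
        self.architecture = architecture
        self.epoch_losses = epoch_losses or []

    @property
    def embeddings(self) -> EmbeddingTable:
        return self.input_vectors

    @property
    def tokens(self) -> list[str]:
        return self.input_vectors.tokens


def _build_vocab(corpus: WalkCorpus) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for walk in corpus.walks:
        for tok in walk:
            counts[tok] = counts.get(tok, 0) + 1
    # frequency order, lexicographic tie-break, for deterministic indexing
    tokens = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(tokens)}
    freq = np.array([counts[t] for t in tokens], dtype=np.float64)
    return tokens, index, freq

def _keep_probs(freq: np.ndarray, subsample: float) -> np.ndarray:
    """word2vec frequent-token subsampling: keep prob (sqrt(f/t)+1) t/f."""
    if subsample <= 0:
        return np.ones(len(freq))
    f = freq / freq.sum()
    kp = (np.sqrt(f / subsample) + 1.0) * (subsample / f)
    return np.minimum(kp, 1.0)


def _epoch_sequences(
    walk_ids: list[list[int]], keep: np.ndarray, rng: np.random.Generator
) -> list[list[int]]:
    """Random per-occurrence downsampling of frequent tokens, per epoch."""
    if np.all(keep >= 1.0):
        return walk_ids
    out = []
    for ids in walk_ids:
        u = rng.random(len(ids))
        filtered = [t for t, x in zip(ids, u) if x < keep[t]]
        if filtered:
            out.append(filtered)
    return out


def _sg_pairs(sequences: list[list[int]], window: int):
    """(center, context) index pairs within the fixed window."""
    centers, contexts = [], []
    for ids in sequences:
        L = len(ids)
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def _neg_sampler(freq: np.ndarray):
    """Unigram^(3/4) negative-sampling distribution as an inverse-CDF lookup."""
    p = freq**0.75
    cdf = np.cumsum(p / p.sum())

    def draw(rng: np.random.Generator, shape) -> np.ndarray:
        return np.searchsorted(cdf, rng.random(shape), side="right")

    return draw


def _mean_update(W: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """Subtract the mean gradient per referenced row of W."""
    acc = np.zeros_like(W)
    np.add.at(acc, idx, grads)
    counts = np.bincount(idx, minlength=W.shape[0])
    touched = counts > 0
    W[touched] -= acc[touched] / counts[touched, None]


def _train_word2vec(corpus: WalkCorpus, config: Word2VecConfig) -> Word2VecModel:
    if not corpus.walks:
        raise ValueError("cannot train on an empty corpus")
    tokens, index, freq = _build_vocab(corpus)
    V, d = len(tokens), config.dim
    rng = np.random.default_rng(config.seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))
    draw_neg = _neg_sampler(freq)
    lr0 = config.learning_rate
    sg = config.architecture == "SG"

    walk_ids = [[index[t] for t in walk] for walk in corpus.walks]
    keep = _keep_probs(freq, config.subsample)

    losses: list[float] = []
    labels_template = None
    trained_any = False
    for epoch in range(config.epochs):
        # word2vec-style linear learning-rate decay, per epoch
        lr = lr0 * max(1e-4, 1.0 - epoch / config.epochs)
        sequences = _epoch_sequences(walk_ids, keep, rng)
        if sg:
            centers, contexts = _sg_pairs(sequences, config.window)
            n_pairs = len(centers)
        else:
            examples = _cbow_examples(sequences, config.window)
            if examples is None:
                losses.append(float("nan"))
                continue
            ctx_pad, ctx_mask, targets = examples
            n_pairs = len(targets)
        if n_pairs == 0:  # e.g. corpus of single-token walks
            losses.append(float("nan"))
            continue
        trained_any = True
        order = rng.permutation(n_pairs)
        epoch_loss, epoch_n = 0.0, 0
        for start in range(0, n_pairs, config.batch_size):
            sel = order[start : start + config.batch_size]
            if sg:
                c, o = centers[sel], contexts[sel]
                v = W_in[c]  # (B, d)
            else:
                cp, cm, o = ctx_pad[sel], ctx_mask[sel], targets[sel]
                nctx = cm.sum(axis=1, keepdims=True)  # (B, 1) >= 1 guaranteed
                v = (W_in[cp] * cm[:, :, None]).sum(axis=1) / nctx  # mean context
            B = len(o)
            neg = draw_neg(rng, (B, config.negative))
            T = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+k)
            u = W_out[T]  # (B, 1+k, d)
            scores = np.einsum("bd,bkd->bk", v, u)
            if labels_template is None or labels_template.shape[0] < B:
                labels_template = np.zeros((B, 1 + config.negative))
                labels_template[:, 0] = 1.0
            y = labels_template[:B]
            p = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
            epoch_loss += -(
                _log_sigmoid(scores[:, 0]).sum()
                + _log_sigmoid(-scores[:, 1:]).sum()
            )
            epoch_n += B
            g = (p - y) * lr  # (B, 1+k)
            grad_v = np.einsum("bk,bkd->bd", g, u)
            grad_u = g[:, :, None] * v[:, None, :]
            # frequent tokens recur many times per batch (hub entities,
            # negative draws); applying the per-token MEAN gradient keeps
            # each row's step bounded by lr and the training stable
            _mean_update(W_out, T.reshape(-1), grad_u.reshape(-1, d))
            if sg:
                _mean_update(W_in, c, grad_v)
            else:
                # distribute the context gradient equally over context words
                gv = (grad_v / nctx)[:, None, :] * cm[:, :, None]
                flat = cp.reshape(-1)
                live = cm.reshape(-1) > 0
                _mean_update(W_in, flat[live], gv.reshape(-1, d)[live])
        losses.append(epoch_loss / max(1, epoch_n))
    if not trained_any:
        losses = []
    return Word2VecModel(tokens, W_in, W_out, config.architecture, losses)


def _cbow_examples(sequences: list[list[int]], window: int):
    """Padded context matrix, mask and target indices for CBOW training."""
    ctx_rows, targets = [], []
    width = 2 * window
    for ids in sequences:
        L = len(ids)
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            ctx = [ids[j] for j in range(lo, hi) if j != i]
            if ctx:
                ctx_rows.append(ctx)
                targets.append(c)
    if not targets:
        return None
    ctx_pad = np.zeros((len(targets), width), dtype=np.int64)
    ctx_mask = np.zeros((len(targets), width))
    for r, ctx in enumerate(ctx_rows):
        ctx_pad[r, : len(ctx)] = ctx
        ctx_mask[r, : len(ctx)] = 1.0
    return ctx_pad, ctx_mask, np.asarray(targets, dtype=np.int64)


def train_skipgram(
    corpus: WalkCorpus, config: Word2VecConfig | None = None, *, return_model: bool = False
):
    """Train skip-gram with negative sampling on the walk corpus.

    Returns the input-vector :class:`EmbeddingTable`, or the full
    :class:`Word2VecModel` (input + output vectors, per-epoch losses) when
    ``return_model`` is set.
    """
    config = config or Word2VecConfig(architecture="SG")
    if config.architecture != "SG":
        config = Word2VecConfig(**{**config.__dict__, "architecture": "SG"})
    model = _train_word2vec(corpus, config)
    return model if return_model else model.embeddings


def train_cbow(
    corpus: WalkCorpus, config: Word2VecConfig | None = None, *, return_model: bool = False
):
    """Train CBOW with negative sampling: averaged context predicts the target."""
    config = config or Word2VecConfig(architecture="CBOW")
    if config.architecture != "CBOW":
        config = Word2VecConfig(**{**config.__dict__, "architecture": "CBOW"})
    model = _train_word2vec(corpus, config)
    return model if return_model else model.embeddings


def _softmax_over_vocab(model: Word2VecModel, query: np.ndarray) -> np.ndarray:
    scores = model.output_vectors.matrix @ query
    scores -= scores.max()
    e = np.exp(scores)
    return e / e.sum()


def skipgram_probability(model: Word2VecModel, center: str, context: str) -> float:
    """Exact softmax probability p(context | center) over the full vocabulary."""
    v = model.input_vectors[center]
    p = _softmax_over_vocab(model, v)
    return float(p[model.output_vectors.index[context]])


def cbow_context_vector(model: Word2VecModel, context: Iterable[str]) -> np.ndarray:
    """Averaged input vector of the context words (the CBOW hidden layer)."""
    rows = [model.input_vectors[t] for t in context]
    if not rows:
        raise ValueError("context must be non-empty")
    return np.mean(rows, axis=0)


def cbow_probability(model: Word2VecModel, context: Iterable[str], target: str) -> float:
    """Exact softmax probability p(target | averaged context)."""
    p = _softmax_over_vocab(model, cbow_context_vector(model, context))
    return float(p[model.output_vectors.index[target]])


# ---------------------------------------------------------------------------
# Translational models


@dataclass(frozen=True)
class TransConfig:
    """TransE / TransD hyperparameters (margin-ranking loss, SGD)."""

    dim: int = 100
    rel_dim: int | None = None  # TransD relation-space dim; defaults to dim
    margin: float = 1.0
    norm: Literal["L1", "L2"] = "L2"
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.norm not in ("L1", "L2"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class TransEModel:
    entity_vectors: EmbeddingTable
    relation_vectors: EmbeddingTable
    norm: str = "L2"
    epoch_losses: list[float] = field(default_factory=list)


@dataclass
class TransDModel:
    entity_vectors: EmbeddingTable
    entity_projections: EmbeddingTable
    relation_vectors: EmbeddingTable
    relation_projections: EmbeddingTable
    norm: str = "L2"
    epoch_losses: list[float] = field(default_factory=list)


def corrupt_triple(
    triple: Triple, entity_pool: Iterable[str], rng: np.random.Generator
) -> Triple:
    """Replace the head or the tail (chosen uniformly) by another pool entity.

    The relation is never changed and the corrupted triple always differs
    from the input in the replaced slot.
    """
    pool = sorted(set(entity_pool))
    corrupt_head = rng.random() < 0.5
    original = triple.subject if corrupt_head else triple.object
    candidates = [e for e in pool if e != original]
    if not candidates:
        raise ValueError("entity pool must contain an entity differing from the original")
    repl = candidates[rng.integers(len(candidates))]
    if corrupt_head:
        return Triple(repl, triple.predicate, triple.object)
    return Triple(triple.subject, triple.predicate, repl)


def _dissimilarity(u: np.ndarray, norm: str) -> float:
    return float(np.abs(u).sum() if norm == "L1" else np.linalg.norm(u))


def transe_score(model: TransEModel, h: str, r: str, t: str) -> float:
    """Translation energy ``||h + r - t||`` in the model's norm."""
    u = model.entity_vectors[h] + model.relation_vectors[r] - model.entity_vectors[t]
    return _dissimilarity(u, model.norm)


def _resize(vec: np.ndarray, n: int) -> np.ndarray:
    """Zero-pad or truncate a vector to length n."""
    m = len(vec)
    if m == n:
        return vec.copy()
    if m > n:
        return vec[:n].copy()
    out = np.zeros(n)
    out[:m] = vec
    return out


def transd_project(
    model: TransDModel, entity: str, relation: str, role: str = "head"
) -> np.ndarray:
    """Project an entity into the relation space: ``r_p (e_p . e) + resize(e)``.

    Equivalent to applying the mapping matrix ``M = r_p e_p^T + I`` without
    materializing it.  ``role`` is accepted for interface symmetry; head and
    tail use the same construction with their own projection vectors.
    """
    if role not in ("head", "tail"):
        raise ValueError("role must be 'head' or 'tail'")
    e = model.entity_vectors[entity]
    e_p = model.entity_projections[entity]
    r_p = model.relation_projections[relation]
    return r_p * float(e_p @ e) + _resize(e, len(r_p))


def transd_score(model: TransDModel, h: str, r: str, t: str) -> float:
    u = (
        transd_project(model, h, r, "head")
        + model.relation_vectors[r]
        - transd_project(model, t, r, "tail")
    )
    return _dissimilarity(u, model.norm)


def _norm_grad(u: np.ndarray, norm: str) -> np.ndarray:
    """d||u||/du, batched over the first axis; safe at the origin."""
    if norm == "L1":
        return np.sign(u)
    nrm = np.linalg.norm(u, axis=-1, keepdims=True)
    return u / np.maximum(nrm, 1e-12)


def _index_triples(triples: Sequence[Triple]):
    uri_triples = [t for t in triples if not t.object_is_literal]
    if not uri_triples:
        raise ValueError("no entity-to-entity triples to train on")
    entities = sorted({t.subject for t in uri_triples} | {t.object for t in uri_triples})
    relations = sorted({t.predicate for t in uri_triples})
    e_idx = {e: i for i, e in enumerate(entities)}
    r_idx = {r: i for i, r in enumerate(relations)}
    H = np.array([e_idx[t.subject] for t in uri_triples], dtype=np.int64)
    R = np.array([r_idx[t.predicate] for t in uri_triples], dtype=np.int64)
    T = np.array([e_idx[t.object] for t in uri_triples], dtype=np.int64)
    return entities, relations, H, R, T


def _corrupt_batch(H, T, n_entities, rng):
    """Bernoulli(0.5) head/tail corruption with uniform replacement entities."""
    B = len(H)
    head_mask = rng.random(B) < 0.5
    repl = rng.integers(n_entities, size=B)
    Hc, Tc = H.copy(), T.copy()
    Hc[head_mask] = repl[head_mask]
    Tc[~head_mask] = repl[~head_mask]
    # redraw replacements that collide with the original entity
    for _ in range(100):
        bad = (head_mask & (Hc == H)) | (~head_mask & (Tc == T))
        if not bad.any():
            break
        redraw = rng.integers(n_entities, size=int(bad.sum()))
        bh = bad & head_mask
        bt = bad & ~head_mask
        Hc[bh] = redraw[: int(bh.sum())]
        Tc[bt] = redraw[int(bh.sum()) :]
    return Hc, Tc


def _unit_rows(M: np.ndarray) -> np.ndarray:
    return M / np.maximum(np.linalg.norm(M, axis=1, keepdims=True), 1e-12)


def train_transe(triples: Sequence[Triple], config: TransConfig | None = None) -> TransEModel:
    """Train TransE by SGD on the margin-ranking loss with corrupted triples.

    Entity vectors are renormalized to unit L2 norm at the end of every
    epoch.  Literal-object triples are excluded (literals are not
    embeddable entities).
    """
    config = config or TransConfig()
    entities, relations, H, R, T = _index_triples(triples)
    rng = np.random.default_rng(config.seed)
    d = config.dim
    bound = 6.0 / np.sqrt(d)
    E = rng.uniform(-bound, bound, (len(entities), d))
    Rm = _unit_rows(rng.uniform(-bound, bound, (len(relations), d)))
    losses = []
    n = len(H)
    for _epoch in range(config.epochs):
        E = _unit_rows(E)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            h, r, t = H[sel], R[sel], T[sel]
            hc, tc = _corrupt_batch(h, t, len(entities), rng)
            u_pos = E[h] + Rm[r] - E[t]
            u_neg = E[hc] + Rm[r] - E[tc]
            if config.norm == "L1":
                d_pos, d_neg = np.abs(u_pos).sum(1), np.abs(u_neg).sum(1)
            else:
                d_pos, d_neg = np.linalg.norm(u_pos, axis=1), np.linalg.norm(u_neg, axis=1)
            viol = config.margin + d_pos - d_neg
            active = viol > 0
            epoch_loss += float(viol[active].sum())
            if not active.any():
                continue
            lr = config.learning_rate
            gp = _norm_grad(u_pos[active], config.norm) * lr
            gn = _norm_grad(u_neg[active], config.norm) * lr
            ha, ra, ta = h[active], r[active], t[active]
            hca, tca = hc[active], tc[active]
            np.add.at(E, ha, -gp)
            np.add.at(E, ta, gp)
            np.add.at(Rm, ra, -gp + gn)
            np.add.at(E, hca, gn)
            np.add.at(E, tca, -gn)
        losses.append(epoch_loss / n)
    E = _unit_rows(E)
    return TransEModel(
        EmbeddingTable(entities, E), EmbeddingTable(relations, Rm), config.norm, losses
    )


def train_transd(triples: Sequence[Triple], config: TransConfig | None = None) -> TransDModel:
    """Train TransD: per-entity/per-relation projection vectors, vector ops only.

    Projection vectors are initialized randomly (all-zero projections are a
    saddle point: each projection gradient is a product with the other,
    zero, projection vector); they pick up gradient where a shared entity
    space is insufficient (one-to-many and many-to-many relations).
    """
    config = config or TransConfig()
    entities, relations, H, R, T = _index_triples(triples)
    rng = np.random.default_rng(config.seed)
    m = config.dim
    nrel = config.rel_dim or config.dim
    bound = 6.0 / np.sqrt(m)
    E = rng.uniform(-bound, bound, (len(entities), m))
    Rm = _unit_rows(rng.uniform(-bound, bound, (len(relations), nrel)))
    Ep = rng.uniform(-bound, bound, (len(entities), m))
    Rp = rng.uniform(-bound, bound, (len(relations), nrel))
    k = min(m, nrel)  # overlap used by the identity part of the mapping
    losses = []
    n = len(H)
    for _epoch in range(config.epochs):
        E = _unit_rows(E)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            h, r, t = H[sel], R[sel], T[sel]
            hc, tc = _corrupt_batch(h, t, len(entities), rng)

            def project(eidx, ridx):
                e, ep, rp = E[eidx], Ep[eidx], Rp[ridx]
                s = np.einsum("bd,bd->b", ep, e)  # (B,)
                out = rp * s[:, None]
                out[:, :k] += e[:, :k]
                return out, s

            hp, sh = project(h, r)
            tp, st = project(t, r)
            hcp, shc = project(hc, r)
            tcp, stc = project(tc, r)
            u_pos = hp + Rm[r] - tp
            u_neg = hcp + Rm[r] - tcp
            if config.norm == "L1":
                d_pos, d_neg = np.abs(u_pos).sum(1), np.abs(u_neg).sum(1)
            else:
                d_pos, d_neg = np.linalg.norm(u_pos, axis=1), np.linalg.norm(u_neg, axis=1)
            viol = config.margin + d_pos - d_neg
            active = viol > 0
            epoch_loss += float(viol[active].sum())
            if not active.any():
                continue
            lr = config.learning_rate
            gp = _norm_grad(u_pos[active], config.norm) * lr  # dL/du_pos
            gn = -_norm_grad(u_neg[active], config.norm) * lr  # dL/du_neg

            def backprop(g, eidx, ridx, s, sign):
                """Accumulate -gradients for e_perp = rp*s + resize(e)."""
                e, ep, rp = E[eidx], Ep[eidx], Rp[ridx]
                gs = np.einsum("bd,bd->b", g, rp)  # dL/ds
                ge = ep * gs[:, None]
                ge[:, :k] += g[:, :k]
                np.add.at(E, eidx, -sign * ge)
                np.add.at(Ep, eidx, -sign * e * gs[:, None])
                np.add.at(Rp, ridx, -sign * g * s[:, None])

            ha, ra, ta = h[active], r[active], t[active]
            hca, tca = hc[active], tc[active]
            backprop(gp, ha, ra, sh[active], 1.0)
            backprop(-gp, ta, ra, st[active], 1.0)
            np.add.at(Rm, ra, -gp)
            backprop(gn, hca, ra, shc[active], 1.0)
            backprop(-gn, tca, ra, stc[active], 1.0)
            np.add.at(Rm, ra, -gn)
        losses.append(epoch_loss / n)
    E = _unit_rows(E)
    return TransDModel(
        EmbeddingTable(entities, E),
        EmbeddingTable(entities, Ep),
        EmbeddingTable(relations, Rm),
        EmbeddingTable(relations, Rp),
        config.norm,
        losses,
    )


# ---------------------------------------------------------------------------
# Analytic gradients of the per-pair hinge loss (for verification)


def transe_pair_loss_grad(
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    hc: np.ndarray,
    tc: np.ndarray,
    margin: float = 1.0,
    norm: str = "L2",
) -> tuple[float, dict[str, np.ndarray]]:
    """Hinge loss ``[margin + d(h+r,t) - d(hc+r,tc)]_+`` and its gradients.

    The five vectors are treated as independent parameters; the gradient
    with respect to ``r`` combines the positive and negative branches.
    """
    u_pos = h + r - t
    u_neg = hc + r - tc
    d_pos = _dissimilarity(u_pos, norm)
    d_neg = _dissimilarity(u_neg, norm)
    loss = margin + d_pos - d_neg
    zeros = {k: np.zeros_like(h) for k in ("h", "r", "t", "hc", "tc")}
    if loss <= 0:
        return 0.0, zeros
    gp = _norm_grad(u_pos, norm)
    gn = _norm_grad(u_neg, norm)
    return loss, {"h": gp, "r": gp - gn, "t": -gp, "hc": -gn, "tc": gn}


def _transd_perp(e, ep, rp, k):
    s = float(ep @ e)
    out = rp * s
    out[:k] += e[:k]
    return out, s


def transd_pair_loss_grad(
    params: dict[str, np.ndarray], margin: float = 1.0, norm: str = "L2"
) -> tuple[float, dict[str, np.ndarray]]:
    """TransD hinge loss and gradients for one (true, corrupted) pair.

    ``params`` holds h, h_p, t, t_p, hc, hc_p, tc, tc_p (entity space) and
    r, r_p (relation space).  Gradients are returned under the same keys.
    """
    r, rp = params["r"], params["r_p"]
    nrel = len(r)
    m = len(params["h"])
    k = min(m, nrel)
    hp, sh = _transd_perp(params["h"], params["h_p"], rp, k)
    tp, st = _transd_perp(params["t"], params["t_p"], rp, k)
    hcp, shc = _transd_perp(params["hc"], params["hc_p"], rp, k)
    tcp, stc = _transd_perp(params["tc"], params["tc_p"], rp, k)
    u_pos = hp + r - tp
    u_neg = hcp + r - tcp
    loss = margin + _dissimilarity(u_pos, norm) - _dissimilarity(u_neg, norm)
    grads = {key: np.zeros_like(val) for key, val in params.items()}
    if loss <= 0:
        return 0.0, grads
    gp = _norm_grad(u_pos, norm)
    gn = _norm_grad(u_neg, norm)

    def accum(g, ekey, pkey, s):
        e, ep = params[ekey], params[pkey]
        gs = float(g @ rp)
        ge = ep * gs
        ge[:k] += g[:k]
        grads[ekey] += ge
        grads[pkey] += e * gs
        grads["r_p"] += g * s

    accum(gp, "h", "h_p", sh)
    accum(-gp, "t", "t_p", st)
    accum(-gn, "hc", "hc_p", shc)
    accum(gn, "tc", "tc_p", stc)
    grads["r"] = gp - gn
    return loss, grads
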