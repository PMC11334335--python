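"""Sentence and token vector spaces.

Two kinds of representation are used downstream:

* *contextual* sentence vectors, used for clustering seed-matched
  utterances and for nearest-neighbour label propagation.  The encoder
  is pluggable (any ``str -> vector`` function); the default is a
  deterministic feature-hashing encoder over token n-grams, which needs
  no trained weights and is bitwise reproducible.
* *static* token embeddings averaged over an utterance's tokens, used as
  classifier features.  Two training algorithms are provided (skip-gram
  with negative sampling, and a PPMI + truncated-SVD factorization), plus
  a corpus-independent hash-derived table that assigns every token a
  fixed pseudo-random vector (a synthetic stand-in playing the role of a
  large general-purpose embedding table).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

SentenceEncoder = Callable[[str], np.ndarray]

_WORD_RE = re.compile(r"[a-z0-9']+")


def _hash_seed(*parts: str) -> int:
    digest = hashlib.md5("|".join(parts).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def hash_token_vector(token: str, dim: int, salt: str = "") -> np.ndarray:
    """Deterministic pseudo-random unit vector for one token."""
    rng = np.random.default_rng(_hash_seed("tok", salt, token))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


class HashSentenceEncoder:
    """Seeded feature-hashing sentence encoder.

    Sums deterministic token (and optionally bigram) vectors and
    L2-normalizes.  Same string, same vector, in any process.
    """

    def __init__(self, dim: int = 64, salt: str = "contextual", use_bigrams: bool = True):
        self.dim = dim
        self.salt = salt
        self.use_bigrams = use_bigrams
        self._cache: dict[str, np.ndarray] = {}

    def _token_vec(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            v = hash_token_vector(token, self.dim, self.salt)
            self._cache[token] = v
        return v

    def __call__(self, text: str) -> np.ndarray:
        tokens = _WORD_RE.findall(text.lower().replace("’", "'"))
        if not tokens:
            return hash_token_vector("<empty>", self.dim, self.salt)
        v = np.zeros(self.dim)
        for tok in tokens:
            v += self._token_vec(tok)
        if self.use_bigrams:
            for a, b in zip(tokens, tokens[1:]):
                v += 0.5 * self._token_vec(a + "_" + b)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else hash_token_vector("<empty>", self.dim, self.salt)


@dataclass
class SentenceVectors:
    """A batch of sentence vectors sharing one space."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n, dim)
    space_tag: str  # contextual | contextual_reduced | static_pretrained | static_corpus

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("ids/values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite sentence vector")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: Sequence[str]) -> "SentenceVectors":
        index = {u: i for i, u in enumerate(self.ids)}
        rows = [index[u] for u in ids]
        return SentenceVectors(tuple(ids), self.values[rows], self.space_tag)


def encode_contextual(
    texts_by_id: Sequence[tuple[str, str]],
    encoder: SentenceEncoder,
) -> SentenceVectors:
    """Encode (utterance_id, text) pairs with a pluggable encoder."""
    ids, rows = [], []
    for uid, text in texts_by_id:
        try:
            v = np.asarray(encoder(text), dtype=float)
        except Exception as err:  # pragma: no cover - encoder contract
            raise RuntimeError(f"encoder failed on utterance {uid!r}: {err}") from err
        if not np.all(np.isfinite(v)):
            raise RuntimeError(f"encoder produced non-finite vector for {uid!r}")
        ids.append(uid)
        rows.append(v)
    values = np.vstack(rows) if rows else np.zeros((0, 0))
    return SentenceVectors(tuple(ids), values, "contextual")


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class ReducedSpace:
    """A fitted PCA projection keeping a target fraction of variance."""

    components: np.ndarray  # (target_dim, source_dim)
    mean: np.ndarray
    explained_variance_ratio: float
    source_dim: int
    target_dim: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, np.vstack([self.mean, self.components]))
        meta = {
            "explained_variance_ratio": self.explained_variance_ratio,
            "source_dim": self.source_dim,
            "target_dim": self.target_dim,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def reduce(
    vectors: SentenceVectors, variance_target: float = 0.95
) -> tuple[ReducedSpace, SentenceVectors]:
    """PCA to the minimal dimension reaching the variance target.

    ``variance_target`` of 1.0 keeps every component carrying variance
    (the rank of the centred data).
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    n, d = vectors.values.shape
    if n < 2:
        raise ValueError("need at least 2 vectors to fit a reduction")
    pca = PCA(svd_solver="full")
    pca.fit(vectors.values)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    # tolerate fp round-off at the top of the spectrum
    eps = 1e-12
    nonzero = int(np.sum(pca.explained_variance_ > eps))
    if variance_target >= 1.0 - eps:
        target_dim = max(nonzero, 1)
    else:
        target_dim = int(np.searchsorted(cum, variance_target - eps) + 1)
        target_dim = min(target_dim, len(evr))
    space = ReducedSpace(
        components=pca.components_[:target_dim].copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=float(cum[target_dim - 1]),
        source_dim=d,
        target_dim=target_dim,
    )
    reduced = SentenceVectors(
        vectors.ids, space.transform(vectors.values), "contextual_reduced"
    )
    return space, reduced


# ---------------------------------------------------------------------------
# Static token embeddings
# ---------------------------------------------------------------------------

class EmbeddingTable:
    """Token -> vector lookup; ``lookup`` returns None when out of vocabulary."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int):
        self.vectors = vectors
        self.dim = dim

    def lookup(self, token: str) -> Optional[np.ndarray]:
        return self.vectors.get(token)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def save_word2vec(self, path: str | Path) -> None:
        """Serialize in the word2vec text format."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for tok, vec in self.vectors.items():
                fh.write(tok + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            vectors = {}
            for line in fh:
                fields = line.rstrip("\n").split(" ")
                vectors[fields[0]] = np.array([float(x) for x in fields[1:]])
        if len(vectors) != n:
            raise ValueError(f"{path}: header count {n} != {len(vectors)} rows")
        return cls(vectors, dim)


class HashEmbeddingTable(EmbeddingTable):
    """Hash-derived token embeddings with unlimited vocabulary.

    Every token deterministically maps to a fixed pseudo-random unit
    vector, so any test-set token is in vocabulary.  This synthetic table
    plays the structural role of a large general-purpose pretrained
    embedding table in the model grid.
    """

    def __init__(self, dim: int = 32, salt: str = "static"):
        super().__init__({}, dim)
        self.salt = salt

    def lookup(self, token: str) -> np.ndarray:
        v = self.vectors.get(token)
        if v is None:
            v = hash_token_vector(token, self.dim, self.salt)
            self.vectors[token] = v
        return v

    def __contains__(self, token: str) -> bool:
        return True


def _build_vocab(sentences: Sequence[Sequence[str]], min_count: int) -> list[str]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    return sorted(tok for tok, c in counts.items() if c >= min_count)


def _cooccurrence(
    sentences: Sequence[Sequence[str]], vocab_index: dict[str, int], window: int
) -> np.ndarray:
    V = len(vocab_index)
    C = np.zeros((V, V))
    for sent in sentences:
        idx = [vocab_index[t] for t in sent if t in vocab_index]
        for i, wi in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    C[wi, idx[j]] += 1.0
    return C


def _train_ppmi_svd(
    sentences: Sequence[Sequence[str]],
    vocab: list[str],
    dim: int,
    window: int,
) -> dict[str, np.ndarray]:
    index = {t: i for i, t in enumerate(vocab)}
    C = _cooccurrence(sentences, index, window)
    total = C.sum()
    if total == 0:
        return {t: np.zeros(dim) for t in vocab}
    row = C.sum(axis=1, keepdims=True)
    col = C.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((C * total) / (row @ col))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(dim, len(vocab))
    U, S, _ = np.linalg.svd(ppmi, full_matrices=False)
    emb = U[:, :k] * np.sqrt(S[:k])
    if k < dim:
        emb = np.pad(emb, ((0, 0), (0, dim - k)))
    return {t: emb[i].copy() for t, i in index.items()}


def _train_sgns(
    sentences: Sequence[Sequence[str]],
    vocab: list[str],
    dim: int,
    window: int,
    seed: int,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.05,
) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling, plain numpy SGD."""
    rng = np.random.default_rng(seed)
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    W = (rng.random((V, dim)) - 0.5) / dim  # input vectors
    Wc = np.zeros((V, dim))  # context vectors

    pairs: list[tuple[int, int]] = []
    counts = np.zeros(V)
    for sent in sentences:
        idx = [index[t] for t in sent if t in index]
        for t in idx:
            counts[t] += 1
        for i, wi in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((wi, idx[j]))
    if not pairs:
        return {t: W[i].copy() for t, i in index.items()}
    pair_arr = np.array(pairs)
    noise = counts**0.75
    noise /= noise.sum()

    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        centers = pair_arr[order, 0]
        contexts = pair_arr[order, 1]
        negs = rng.choice(V, size=(len(order), negative), p=noise)
        for c, ctx, neg in zip(centers, contexts, negs):
            vc = W[c]
            # positive update
            vo = Wc[ctx]
            g = 1.0 / (1.0 + np.exp(-vc @ vo)) - 1.0
            grad_c = g * vo
            Wc[ctx] -= lr * g * vc
            # negative updates
            vn = Wc[neg]
            gn = 1.0 / (1.0 + np.exp(-(vn @ vc)))
            grad_c = grad_c + gn @ vn
            Wc[neg] -= lr * gn[:, None] * vc
            W[c] -= lr * grad_c
    return {t: W[i].copy() for t, i in index.items()}


def train_static(
    sentences: Sequence[Sequence[str]],
    algorithm: str = "skipgram",
    dim: int = 32,
    seed: int = 0,
    window: int = 2,
    min_count: int = 1,
    epochs: int = 5,
) -> EmbeddingTable:
    """Train token embeddings on a tokenized corpus.

    ``algorithm`` is ``"skipgram"`` (negative sampling) or
    ``"glove_style"`` (PPMI matrix + truncated SVD, a count-based
    factorization in the same family as GloVe).  Reproducible for a
    fixed seed.
    """
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("empty corpus")
    vocab = _build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError("no token meets min_count")
    if algorithm == "skipgram":
        vecs = _train_sgns(sentences, vocab, dim, window, seed, epochs)
    elif algorithm == "glove_style":
        vecs = _train_ppmi_svd(sentences, vocab, dim, window)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return EmbeddingTable(vecs, dim)


def mean_embedding(
    tokens: Iterable[str], table: EmbeddingTable
) -> tuple[np.ndarray, int]:
    """Mean of in-vocabulary token vectors.

    Returns ``(vector, n_in_vocab)``; an all-out-of-vocabulary sentence
    yields the zero vector with ``n_in_vocab == 0`` so callers can flag
    or exclude it.
    """
    vecs = []
    for tok in tokens:
        v = table.lookup(tok)
        if v is not None:
            vecs.append(v)
    if not vecs:
        return np.zeros(table.dim), 0
    return np.mean(vecs, axis=0), len(vecs)
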