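"""Moral word-sense disambiguation by per-cell mixture clustering.

Seed-matched utterances are grouped per *cell* -- one (foundation,
polarity, speaker role) combination -- encoded, PCA-reduced, and
clustered with a Gaussian mixture.  The number of clusters k is chosen
by grid search over 2..10 to maximize the silhouette score (ties go to
the smaller k).  With 5 foundations x 2 polarities x 2 roles a fully
populated corpus yields 20 fitted models.

A cluster's representative sentences for human annotation are the
*prototypes* (highest proximity to the cluster mean) and *peripherals*
(lowest proximity), where

    proximity(s, C) = cos(v_s, mean of member vectors of C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .embeddings import (
    ReducedSpace,
    SentenceEncoder,
    SentenceVectors,
    encode_contextual,
    reduce,
)
from .types import SpeakerRole, Utterance, split_category

logger = logging.getLogger(__name__)

#: (category, role) keys for the full clustering stage.
Cell = tuple[str, SpeakerRole]


@dataclass
class ClusterModel:
    cell: Cell
    k: int
    assignments: dict[str, int]  # utterance_id -> cluster index
    silhouette: Optional[float]  # None for the degenerate fallback
    seed: int
    metric: str = "euclidean"
    fallback: bool = False


@dataclass
class ClusterSummary:
    cell: Cell
    cluster_index: int
    center: np.ndarray
    member_ids: tuple[str, ...]
    prototypes: tuple[str, ...] = ()
    peripherals: tuple[str, ...] = ()


def fit_cell(
    vectors: SentenceVectors,
    cell: Cell = ("care.virtue", SpeakerRole.CHILD),
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    metric: str = "euclidean",
) -> ClusterModel:
    """Fit mixtures over a k grid and keep the silhouette-best model.

    Fewer than 3 vectors cannot support a silhouette comparison; the
    degenerate fallback assigns everything to one cluster and flags it.
    If n <= max(k_range) the grid is truncated to k <= n - 1.
    """
    X = vectors.values
    n = X.shape[0]
    ids = vectors.ids
    if n < 3:
        logger.warning("cell %s: %d vectors, single-cluster fallback", cell, n)
        return ClusterModel(
            cell, 1, {u: 0 for u in ids}, None, seed, metric, fallback=True
        )
    ks = [k for k in k_range if k <= n - 1]
    if not ks:
        ks = [2]
    if max(k_range) > n - 1:
        logger.warning("cell %s: k range truncated to <= %d", cell, n - 1)

    best: tuple[float, int, np.ndarray] | None = None
    for k in ks:
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-4,
            random_state=seed,
            n_init=2,
        )
        labels = gmm.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue  # silhouette undefined for a single realized cluster
        score = float(silhouette_score(X, labels, metric=metric))
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        logger.warning("cell %s: degenerate data, single-cluster fallback", cell)
        return ClusterModel(
            cell, 1, {u: 0 for u in ids}, None, seed, metric, fallback=True
        )
    score, k, labels = best
    return ClusterModel(
        cell, k, dict(zip(ids, (int(x) for x in labels))), score, seed, metric
    )


def proximity(v: np.ndarray, center: np.ndarray) -> float:
    """Cosine of a sentence vector with its cluster's member mean."""
    v = np.asarray(v, dtype=float)
    center = np.asarray(center, dtype=float)
    if v.shape != center.shape:
        raise ValueError("vector/center dimension mismatch")
    nv, nc = np.linalg.norm(v), np.linalg.norm(center)
    if nv == 0 or nc == 0:
        raise ValueError("zero vector in proximity computation")
    return float(v @ center / (nv * nc))


def summarize_clusters(
    model: ClusterModel, vectors: SentenceVectors
) -> list[ClusterSummary]:
    """Member mean (the cluster center used by proximity) per cluster."""
    index = {u: i for i, u in enumerate(vectors.ids)}
    out = []
    for c in sorted(set(model.assignments.values())):
        members = tuple(u for u, lab in model.assignments.items() if lab == c)
        rows = [index[u] for u in members]
        center = vectors.values[rows].mean(axis=0)
        out.append(ClusterSummary(model.cell, c, center, members))
    return out


def select_survey_sentences(
    model: ClusterModel,
    vectors: SentenceVectors,
    texts: dict[str, str],
    n_proto: int = 10,
) -> list[ClusterSummary]:
    """Pick prototype/peripheral sentences per cluster for annotation.

    Prototypes are the ``n_proto`` members with the highest proximity to
    the cluster mean, peripherals the lowest.  Sentences are de-duplicated
    by text globally (across both lists and across clusters), so repeated
    utterances are surveyed once.
    """
    summaries = summarize_clusters(model, vectors)
    index = {u: i for i, u in enumerate(vectors.ids)}
    seen_texts: set[str] = set()

    def _safe_prox(v: np.ndarray, center: np.ndarray) -> float:
        # reduced vectors are mean-centred, so a member can sit exactly at
        # the origin; such points are neither prototypical nor peripheral
        if np.linalg.norm(v) == 0 or np.linalg.norm(center) == 0:
            return 0.0
        return proximity(v, center)

    def _take(order: Sequence[str], limit: int) -> tuple[str, ...]:
        picked = []
        for uid in order:
            txt = texts.get(uid, uid)
            if txt in seen_texts:
                continue
            seen_texts.add(txt)
            picked.append(uid)
            if len(picked) == limit:
                break
        return tuple(picked)

    for summ in summaries:
        prox = {
            u: _safe_prox(vectors.values[index[u]], summ.center)
            for u in summ.member_ids
        }
        by_desc = sorted(summ.member_ids, key=lambda u: (-prox[u], u))
        summ.prototypes = _take(by_desc, n_proto)
        by_asc = sorted(summ.member_ids, key=lambda u: (prox[u], u))
        summ.peripherals = _take(by_asc, n_proto)
    return summaries


@dataclass
class CellResult:
    """Everything the pipeline keeps per clustering cell."""

    cell: Cell
    space: Optional[ReducedSpace]
    vectors: SentenceVectors  # reduced vectors for the cell's utterances
    model: ClusterModel
    summaries: list[ClusterSummary] = field(default_factory=list)


def run_clustering_stage(
    utterances: Sequence[Utterance],
    initial_category: dict[str, str],
    encoder: SentenceEncoder,
    k_range: Sequence[int] = range(2, 11),
    variance_target: float = 0.95,
    n_proto: int = 10,
    seed: int = 0,
) -> dict[Cell, CellResult]:
    """Encode, reduce, and cluster every populated cell.

    ``initial_category`` maps seed-matched utterance ids to their
    dictionary-assigned foundation-polarity category.  Cells with no
    utterances are skipped with a warning.
    """
    by_id = {u.utterance_id: u for u in utterances}
    cells: dict[Cell, list[Utterance]] = {}
    for uid, cat in initial_category.items():
        utt = by_id.get(uid)
        if utt is None:
            continue
        cells.setdefault((cat, utt.speaker_role), []).append(utt)

    from .types import CATEGORIES

    results: dict[Cell, CellResult] = {}
    for cat in CATEGORIES:
        for role in SpeakerRole:
            cell: Cell = (cat, role)
            members = cells.get(cell)
            if not members:
                logger.warning("cell %s/%s empty, skipped", cat, role.value)
                continue
            members = sorted(members, key=lambda u: u.utterance_id)
            enc = encode_contextual(
                [(u.utterance_id, u.text) for u in members], encoder
            )
            if len(members) >= 2:
                space, vecs = reduce(enc, variance_target)
            else:
                space, vecs = None, enc
            model = fit_cell(vecs, cell, k_range, seed=seed)
            texts = {u.utterance_id: u.text for u in members}
            summaries = select_survey_sentences(model, vecs, texts, n_proto)
            results[cell] = CellResult(cell, space, vecs, model, summaries)
    return results


def surveyed_ids(results: dict[Cell, CellResult]) -> list[str]:
    """All prototype/peripheral utterance ids across cells (deduplicated)."""
    out: list[str] = []
    seen: set[str] = set()
    for res in results.values():
        for summ in res.summaries:
            for uid in summ.prototypes + summ.peripherals:
                if uid not in seen:
                    seen.add(uid)
                    out.append(uid)
    return out
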