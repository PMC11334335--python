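"""Extending survey labels to the full corpus.

Seed-matched utterances that were not surveyed get the majority vote of
three labels: their cluster's label and the labels of their two nearest
surveyed neighbours (by cosine similarity of sentence vectors).  A
three-way foundation tie resolves to the utterance's initial
(dictionary) foundation when it is among the votes, else to the
cluster's foundation.

Utterances with no seed word were never clustered; they get the majority
vote of their three nearest surveyed neighbours, with a three-way
foundation tie resolving to the rank-1 neighbour's label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .embeddings import SentenceVectors
from .types import AggregatedLabel


@dataclass(frozen=True)
class NeighborHit:
    query_id: str
    neighbor_id: str
    cosine: float
    rank: int  # 1-based


def nearest_surveyed(
    query: np.ndarray,
    query_id: str,
    surveyed: SentenceVectors,
    k: int,
) -> list[NeighborHit]:
    """Top-k surveyed utterances by cosine; exact ties break by id."""
    n = len(surveyed.ids)
    if k > n:
        raise ValueError(f"k={k} exceeds surveyed pool of {n}")
    q = np.asarray(query, dtype=float)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError(f"zero query vector for {query_id!r}")
    norms = np.linalg.norm(surveyed.values, axis=1)
    norms[norms == 0] = np.inf  # zero-vector pool entries can never win
    cos = surveyed.values @ q / (norms * qn)
    order = sorted(range(n), key=lambda i: (-cos[i], surveyed.ids[i]))[:k]
    return [
        NeighborHit(query_id, surveyed.ids[i], float(cos[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]


def _vote(labels: Sequence[AggregatedLabel]) -> tuple[str, Optional[str], bool]:
    """Majority relevance and foundation; returns (rel, fnd, fnd_tied)."""
    rel_votes = Counter(l.relevance for l in labels)
    relevance = "moral" if rel_votes["moral"] * 2 > len(labels) else "nonmoral"
    fnd_votes = Counter(l.foundation for l in labels if l.foundation is not None)
    if not fnd_votes or relevance == "nonmoral":
        return relevance, None, False
    top = max(fnd_votes.values())
    tied = sorted(f for f, c in fnd_votes.items() if c == top)
    return relevance, tied[0], len(tied) > 1


def propagate_seeded(
    cluster_label: AggregatedLabel,
    neighbor_labels: Sequence[AggregatedLabel],
    initial_foundation: str,
) -> AggregatedLabel:
    """Cluster + 2-nearest-neighbour majority vote for a seeded utterance."""
    if len(neighbor_labels) != 2:
        raise ValueError("propagate_seeded needs exactly 2 neighbour labels")
    votes = [cluster_label, *neighbor_labels]
    relevance, foundation, tied = _vote(votes)
    notes: tuple[str, ...] = ()
    if relevance == "moral":
        foundations = [l.foundation for l in votes if l.foundation is not None]
        counts = Counter(foundations)
        if counts and max(counts.values()) == 1 and len(counts) == 3:
            # three-way tie among distinct foundations
            if initial_foundation in counts:
                foundation = initial_foundation
                notes = ("tie->initial",)
            else:
                foundation = cluster_label.foundation
                notes = ("tie->cluster",)
        if foundation is None:
            # moral majority but no foundation vote available: fall back
            foundation = initial_foundation
            notes = notes + ("no_foundation_votes->initial",)
    return AggregatedLabel(relevance, foundation, provenance="propagated", notes=notes)


def propagate_unseeded(
    neighbor_labels: Sequence[AggregatedLabel],
) -> AggregatedLabel:
    """3-nearest-neighbour majority vote for an utterance with no seed word.

    ``neighbor_labels`` must be in rank order; a three-way foundation tie
    resolves to the rank-1 neighbour's foundation.
    """
    if len(neighbor_labels) != 3:
        raise ValueError("propagate_unseeded needs exactly 3 neighbour labels")
    relevance, foundation, _ = _vote(neighbor_labels)
    notes: tuple[str, ...] = ()
    if relevance == "moral":
        counts = Counter(
            l.foundation for l in neighbor_labels if l.foundation is not None
        )
        if counts and max(counts.values()) == 1 and len(counts) == 3:
            foundation = neighbor_labels[0].foundation
            notes = ("tie->rank1",)
        if foundation is None:
            moral_ranked = [l for l in neighbor_labels if l.foundation is not None]
            foundation = moral_ranked[0].foundation if moral_ranked else None
    if foundation is None and relevance == "moral":
        relevance = "nonmoral"  # unreachable with consistent labels; guard
    return AggregatedLabel(relevance, foundation, provenance="propagated", notes=notes)


def propagate_corpus(
    seeded: dict[str, tuple[AggregatedLabel, Sequence[AggregatedLabel], str]],
    unseeded: dict[str, Sequence[AggregatedLabel]],
) -> dict[str, AggregatedLabel]:
    """Apply both propagation rules over pre-gathered votes."""
    out: dict[str, AggregatedLabel] = {}
    for uid, (cluster_label, neigh, initial) in seeded.items():
        out[uid] = propagate_seeded(cluster_label, neigh, initial)
    for uid, neigh in unseeded.items():
        out[uid] = propagate_unseeded(neigh)
    return out
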