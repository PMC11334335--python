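"""End-to-end orchestration of the synthetic study.

Chains the stages: generate corpus -> seed matching -> per-cell
clustering -> survey simulation -> label aggregation -> propagation.
The result object carries every intermediate product so analyses, tests
and the acceptance script can inspect any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import annotation, clustering, corpus_io, propagation, synthetic_data
from .embeddings import HashSentenceEncoder, SentenceVectors, encode_contextual
from .types import AggregatedLabel, AnnotationRecord, SpeakerRole, Utterance

logger = logging.getLogger(__name__)


def manifest_labels(
    manifest: synthetic_data.GroundTruthManifest,
) -> dict[str, AggregatedLabel]:
    """Ground-truth labels in the aggregated-label format."""
    out = {}
    for uid, g in manifest.entries.items():
        if g.true_relevance == "moral":
            out[uid] = AggregatedLabel("moral", g.true_category, provenance="unanimous_rule")
        else:
            out[uid] = AggregatedLabel("nonmoral", provenance="unanimous_rule")
    return out


@dataclass
class StudyResult:
    config: synthetic_data.GeneratorConfig
    utterances: list[Utterance]
    manifest: synthetic_data.GroundTruthManifest
    initial: dict[str, str]  # seed-matched utterance -> initial category
    cells: dict[clustering.Cell, clustering.CellResult]
    surveyed: list[str]
    records: list[AnnotationRecord]
    survey_labels: dict[str, AggregatedLabel]
    cluster_labels: dict[tuple[clustering.Cell, int], AggregatedLabel]
    agreement: dict[tuple[clustering.Cell, int], tuple[float, float]]
    labels: dict[str, AggregatedLabel]  # final label for every utterance
    contextual: SentenceVectors  # full-corpus contextual vectors

    @property
    def by_id(self) -> dict[str, Utterance]:
        return {u.utterance_id: u for u in self.utterances}


def _batch_neighbors(
    queries: SentenceVectors,
    pool: SentenceVectors,
    k: int,
) -> list[list[propagation.NeighborHit]]:
    """Vectorized k-NN by cosine over a shared pool (id tie-break)."""
    P = pool.values
    pnorm = np.linalg.norm(P, axis=1)
    pnorm[pnorm == 0] = np.inf
    Q = queries.values
    qnorm = np.linalg.norm(Q, axis=1)
    qnorm[qnorm == 0] = 1.0
    cos = (Q @ P.T) / (qnorm[:, None] * pnorm[None, :])
    id_rank = np.argsort(np.argsort(pool.ids))
    out = []
    for qi, qid in enumerate(queries.ids):
        order = np.lexsort((id_rank, -cos[qi]))[:k]
        out.append(
            [
                propagation.NeighborHit(qid, pool.ids[i], float(cos[qi, i]), r)
                for r, i in enumerate(order, start=1)
            ]
        )
    return out


def run_synthetic_study(
    config: synthetic_data.GeneratorConfig,
    encoder=None,
    k_range: Sequence[int] = range(2, 11),
    n_proto: int = 10,
    variance_target: float = 0.95,
    survey_seed: Optional[int] = None,
) -> StudyResult:
    """Generate a corpus and run the full labelling pipeline on it."""
    utterances, manifest = synthetic_data.generate_corpus(config)
    lexicon = synthetic_data.default_lexicon()
    matches = corpus_io.match_seeds(utterances, lexicon)
    initial = corpus_io.initial_foundation(matches)
    return label_corpus(
        utterances, initial, manifest, config,
        encoder=encoder, k_range=k_range, n_proto=n_proto,
        variance_target=variance_target, survey_seed=survey_seed,
    )


def label_corpus(
    utterances: list[Utterance],
    initial: dict[str, str],
    manifest: synthetic_data.GroundTruthManifest,
    config: synthetic_data.GeneratorConfig,
    encoder=None,
    k_range: Sequence[int] = range(2, 11),
    n_proto: int = 10,
    variance_target: float = 0.95,
    survey_seed: Optional[int] = None,
) -> StudyResult:
    """Cluster, survey, aggregate, and propagate labels over a corpus."""
    encoder = encoder or HashSentenceEncoder()

    cells = clustering.run_clustering_stage(
        utterances, initial, encoder,
        k_range=k_range, variance_target=variance_target,
        n_proto=n_proto, seed=config.seed,
    )
    surveyed = clustering.surveyed_ids(cells)

    records = synthetic_data.simulate_survey(manifest, surveyed, config, seed=survey_seed)
    kept = annotation.filter_annotators(records)
    by_utt: dict[str, list[AnnotationRecord]] = {}
    for r in kept:
        by_utt.setdefault(r.utterance_id, []).append(r)

    by_id = {u.utterance_id: u for u in utterances}
    survey_labels: dict[str, AggregatedLabel] = {}
    for uid in surveyed:
        recs = by_utt.get(uid)
        if not recs:
            logger.warning("surveyed utterance %s has no surviving records", uid)
            continue
        survey_labels[uid] = annotation.aggregate_utterance(
            recs, initial[uid], tokens=by_id[uid].tokens
        )

    # cluster-level labels and agreement ratios
    cluster_labels: dict[tuple[clustering.Cell, int], AggregatedLabel] = {}
    agreement: dict[tuple[clustering.Cell, int], tuple[float, float]] = {}
    for cell, res in cells.items():
        for summ in res.summaries:
            surveyed_members = [
                u for u in summ.prototypes + summ.peripherals if u in by_utt
            ]
            pooled = [r for u in surveyed_members for r in by_utt[u]]
            if not pooled:
                continue
            clab = annotation.aggregate_cluster(pooled)
            cluster_labels[(cell, summ.cluster_index)] = clab
            member_labels = [
                survey_labels[u] for u in surveyed_members if u in survey_labels
            ]
            if member_labels:
                agreement[(cell, summ.cluster_index)] = annotation.agreement_ratio(
                    member_labels, clab
                )

    # final labels: survey verdicts, then propagation
    labels: dict[str, AggregatedLabel] = dict(survey_labels)

    for cell, res in cells.items():
        surveyed_in_cell = [u for u in res.vectors.ids if u in survey_labels]
        if len(surveyed_in_cell) < 2:
            logger.warning("cell %s: <2 surveyed members, cluster-label only", cell)
        pool = res.vectors.subset(surveyed_in_cell) if len(surveyed_in_cell) >= 2 else None
        todo = [u for u in res.vectors.ids if u not in survey_labels]
        if not todo:
            continue
        hits_by_query = (
            dict(
                zip(
                    todo,
                    _batch_neighbors(res.vectors.subset(todo), pool, 2),
                )
            )
            if pool is not None
            else {}
        )
        for uid in todo:
            key = (cell, res.model.assignments[uid])
            clab = cluster_labels.get(key)
            if clab is None:
                continue
            hits = hits_by_query.get(uid)
            if hits is None:
                labels[uid] = AggregatedLabel(
                    clab.relevance, clab.foundation, provenance="propagated"
                )
                continue
            neigh = [survey_labels[h.neighbor_id] for h in hits]
            labels[uid] = propagation.propagate_seeded(clab, neigh, initial[uid])

    # unseeded utterances: 3-NN in the full contextual space
    contextual = encode_contextual(
        [(u.utterance_id, u.text) for u in utterances], encoder
    )
    surveyed_global = [u for u in surveyed if u in survey_labels]
    pool = contextual.subset(surveyed_global)
    unseeded = [u.utterance_id for u in utterances if u.utterance_id not in initial]
    if unseeded and len(surveyed_global) >= 3:
        for uid, hits in zip(
            unseeded, _batch_neighbors(contextual.subset(unseeded), pool, 3)
        ):
            neigh = [survey_labels[h.neighbor_id] for h in hits]
            labels[uid] = propagation.propagate_unseeded(neigh)

    return StudyResult(
        config=config,
        utterances=utterances,
        manifest=manifest,
        initial=initial,
        cells=cells,
        surveyed=surveyed,
        records=records,
        survey_labels=survey_labels,
        cluster_labels=cluster_labels,
        agreement=agreement,
        labels=labels,
        contextual=contextual,
    )
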