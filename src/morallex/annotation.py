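"""Aggregating per-annotator survey responses into moral labels.

An utterance's verdict is decided by the share of annotators calling it
morally relevant:

* share >= 75%            -> moral, foundation = majority vote;
* share < 50%             -> nonmoral;
* 50% <= share < 75%      -> moral only if the majority-vote foundation
  matches the utterance's initial (dictionary-assigned) foundation,
  otherwise nonmoral.

Single-word utterances from a fixed blacklist (kin terms and similar
context-free words) are always nonmoral.  Cluster-level labels pool the
records of all the cluster's surveyed utterances and take plain majority
votes; relevance ties resolve to nonmoral, foundation ties to the
lexicographically first tied category (both logged).
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional, Sequence

from .types import AggregatedLabel, AnnotationRecord

logger = logging.getLogger(__name__)

#: One-word utterances treated as nonmoral regardless of votes.
DEFAULT_BLACKLIST = frozenset(
    {
        "mommy", "mother", "cried", "together", "monarch", "food", "blood",
        "mucky", "trash", "garbage", "nurse", "queen", "refused", "country",
        "wife", "daddy", "dad",
    }
)


def filter_annotators(
    records: Sequence[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Drop every record from annotators who failed the attention check."""
    failed = {r.annotator_id for r in records if not r.passed_attention}
    return [r for r in records if r.annotator_id not in failed]


def _majority_foundation(
    records: Sequence[AnnotationRecord], initial: Optional[str]
) -> Optional[str]:
    """Majority vote over selected categories; each selection is one vote.

    Ties go to the initial foundation when it is among the tied
    categories, else to the lexicographically first tied category.
    """
    votes = Counter(cat for r in records for cat in r.foundations)
    if not votes:
        return None
    top = max(votes.values())
    tied = sorted(cat for cat, c in votes.items() if c == top)
    if len(tied) > 1:
        logger.debug("foundation tie among %s (initial=%s)", tied, initial)
        if initial in tied:
            return initial
    return tied[0]


def aggregate_utterance(
    records: Sequence[AnnotationRecord],
    initial_foundation: str,
    blacklist: frozenset[str] = DEFAULT_BLACKLIST,
    tokens: Optional[Sequence[str]] = None,
) -> AggregatedLabel:
    """Aggregate one utterance's (already filtered) annotation records."""
    if not records:
        raise ValueError("no annotation records for utterance")
    if tokens is not None and len(tokens) == 1 and tokens[0] in blacklist:
        return AggregatedLabel("nonmoral", provenance="blacklist")
    share = sum(r.says_moral for r in records) / len(records)
    majority = _majority_foundation(records, initial_foundation)
    if share >= 0.75:
        # majority is set: moral voters must select >= 1 foundation
        return AggregatedLabel("moral", majority, provenance="unanimous_rule")
    if share < 0.5:
        return AggregatedLabel("nonmoral", provenance="unanimous_rule")
    if majority == initial_foundation and majority is not None:
        return AggregatedLabel("moral", majority, provenance="band_rule")
    return AggregatedLabel("nonmoral", provenance="band_rule")


def aggregate_cluster(
    records: Sequence[AnnotationRecord],
) -> AggregatedLabel:
    """Pooled majority vote over all of a cluster's survey records."""
    if not records:
        raise ValueError("no records for cluster")
    n_moral = sum(r.says_moral for r in records)
    n = len(records)
    if n_moral * 2 == n:
        logger.debug("cluster relevance tie (%d/%d), labelled nonmoral", n_moral, n)
    if n_moral * 2 <= n:
        return AggregatedLabel("nonmoral", provenance="unanimous_rule")
    foundation = _majority_foundation(records, initial=None)
    if foundation is None:
        return AggregatedLabel("nonmoral", provenance="unanimous_rule")
    return AggregatedLabel("moral", foundation, provenance="unanimous_rule")


def agreement_ratio(
    utterance_labels: Sequence[AggregatedLabel],
    cluster_label: AggregatedLabel,
) -> tuple[float, float]:
    """Fraction of surveyed utterances agreeing with their cluster label.

    Returned as ``(relevance_agreement, foundation_agreement)``; the
    second compares the foundation field (both None counts as agreement).
    """
    if not utterance_labels:
        raise ValueError("no labelled survey utterances in cluster")
    n = len(utterance_labels)
    rel = sum(l.relevance == cluster_label.relevance for l in utterance_labels) / n
    fnd = sum(l.foundation == cluster_label.foundation for l in utterance_labels) / n
    return rel, fnd
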