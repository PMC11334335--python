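"""Survey aggregation rules, tie-breaks, and agreement ratios."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morallex.annotation import (
    DEFAULT_BLACKLIST,
    aggregate_cluster,
    aggregate_utterance,
    agreement_ratio,
    filter_annotators,
)
from morallex.types import AggregatedLabel, AnnotationRecord, CATEGORIES


def rec(uid, ann, moral, fnds=(), passed=True):
    return AnnotationRecord(uid, ann, moral, tuple(fnds), passed)


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the utterance aggregation rule,
# written directly from the rule statement (not from the implementation).
# ---------------------------------------------------------------------------

def oracle_aggregate(votes_moral, foundation_votes, initial):
    """votes_moral: list of bool; foundation_votes: flat list of categories."""
    n = len(votes_moral)
    share = sum(votes_moral) / n
    counts = Counter(foundation_votes)
    if counts:
        top = max(counts.values())
        tied = sorted(c for c, k in counts.items() if k == top)
        majority = initial if (len(tied) > 1 and initial in tied) else tied[0]
    else:
        majority = None
    if share >= 0.75:
        return ("moral", majority)
    if share < 0.5:
        return ("nonmoral", None)
    if majority == initial and majority is not None:
        return ("moral", majority)
    return ("nonmoral", None)


def _records_from(votes_moral, foundation_votes, uid="u"):
    """One foundation pick per moral voter (consumed in order)."""
    records, fi = [], 0
    for i, m in enumerate(votes_moral):
        fnds = (foundation_votes[fi],) if m else ()
        fi += int(m)
        records.append(rec(uid, f"a{i}", m, fnds))
    return records


class TestFilterAnnotators:
    def test_all_pass_is_identity(self):
        records = [rec("u", "a", True, ("care.virtue",)), rec("u", "b", False)]
        assert filter_annotators(records) == records

    def test_failing_annotator_fully_removed(self):
        records = [
            rec("u1", "a", True, ("care.virtue",)),
            rec("u2", "a", False, passed=False),
            rec("u1", "b", False),
        ]
        kept = filter_annotators(records)
        assert {r.annotator_id for r in kept} == {"b"}

    def test_simulated_failure_count(self):
        """300 simulated annotators with 50 planted failures -> 250 remain."""
        rng = np.random.default_rng(0)
        failing = set(rng.choice(300, size=50, replace=False))
        records = [
            rec(f"u{i % 40}", f"ann{i}", True, ("care.virtue",), passed=i not in failing)
            for i in range(300)
        ]
        kept = filter_annotators(records)
        assert len({r.annotator_id for r in kept}) == 250


class TestAggregateUtterance:
    def test_majority_overrides_initial_foundation(self):
        """6/7 moral with plurality Loyalty overrides a Fairness seed."""
        votes = [True] * 6 + [False]
        fnds = ["loyalty.vice"] * 4 + ["fairness.vice"] * 2
        label = aggregate_utterance(
            _records_from(votes, fnds), "fairness.vice"
        )
        assert label.relevance == "moral" and label.foundation == "loyalty.vice"

    def test_zero_moral_votes(self):
        label = aggregate_utterance(_records_from([False] * 8, []), "care.virtue")
        assert label.relevance == "nonmoral" and label.foundation is None

    def test_band_requires_matching_initial(self):
        """62.5% moral: kept only when the majority matches the seed."""
        votes = [True] * 5 + [False] * 3
        match = aggregate_utterance(
            _records_from(votes, ["care.virtue"] * 5), "care.virtue"
        )
        assert match.relevance == "moral" and match.foundation == "care.virtue"
        clash = aggregate_utterance(
            _records_from(votes, ["authority.virtue"] * 5), "care.virtue"
        )
        assert clash.relevance == "nonmoral"

    def test_exactly_half_falls_in_band(self):
        votes = [True] * 4 + [False] * 4
        label = aggregate_utterance(
            _records_from(votes, ["care.virtue"] * 4), "care.virtue"
        )
        assert label.relevance == "moral"

    def test_blacklisted_single_word_always_nonmoral(self):
        votes = [True] * 7
        label = aggregate_utterance(
            _records_from(votes, ["care.virtue"] * 7),
            "care.virtue",
            tokens=("daddy",),
        )
        assert label.relevance == "nonmoral" and label.provenance == "blacklist"
        # multi-token utterances are never blacklisted
        label2 = aggregate_utterance(
            _records_from(votes, ["care.virtue"] * 7),
            "care.virtue",
            tokens=("daddy", "helps"),
        )
        assert label2.relevance == "moral"

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            aggregate_utterance([], "care.virtue")

    def test_order_and_annotator_relabeling_invariance(self):
        votes = [True, True, False, True, False]
        fnds = ["care.virtue", "purity.vice", "care.virtue"]
        records = _records_from(votes, fnds)
        shuffled = list(reversed(records))
        renamed = [
            AnnotationRecord(r.utterance_id, f"z{i}", r.says_moral, r.foundations)
            for i, r in enumerate(shuffled)
        ]
        a = aggregate_utterance(records, "care.virtue")
        b = aggregate_utterance(renamed, "care.virtue")
        assert (a.relevance, a.foundation) == (b.relevance, b.foundation)

    @settings(max_examples=300, derandomize=True)
    @given(
        votes=st.lists(st.booleans(), min_size=1, max_size=12),
        fseed=st.integers(0, 2**31 - 1),
        initial=st.sampled_from(CATEGORIES),
    )
    def test_matches_brute_force_oracle(self, votes, fseed, initial):
        rng = np.random.default_rng(fseed)
        fnds = [CATEGORIES[rng.integers(10)] for _ in range(sum(votes))]
        label = aggregate_utterance(_records_from(votes, fnds), initial)
        expected = oracle_aggregate(votes, fnds, initial)
        assert (label.relevance, label.foundation) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        votes=st.lists(st.booleans(), min_size=2, max_size=10),
        fseed=st.integers(0, 2**31 - 1),
    )
    def test_adding_moral_vote_never_flips_moral_to_nonmoral(self, votes, fseed):
        """Monotonicity at the share thresholds (fixed foundation votes)."""
        rng = np.random.default_rng(fseed)
        initial = "care.virtue"
        fnds = [initial] * sum(votes)  # foundation fixed at the initial one
        before = aggregate_utterance(_records_from(votes, fnds), initial)
        more = votes + [True]
        after = aggregate_utterance(
            _records_from(more, [initial] * sum(more)), initial
        )
        if before.relevance == "moral":
            assert after.relevance == "moral"


class TestAggregateCluster:
    def test_unanimous(self):
        records = [rec("u", f"a{i}", True, ("care.virtue",)) for i in range(5)]
        label = aggregate_cluster(records)
        assert label.relevance == "moral" and label.foundation == "care.virtue"

    def test_pooled_counts(self):
        """10 moral vs 30 nonmoral pooled records -> nonmoral."""
        records = [rec(f"u{i%4}", f"a{i}", True, ("care.virtue",)) for i in range(10)]
        records += [rec(f"u{i%4}", f"b{i}", False) for i in range(30)]
        assert aggregate_cluster(records).relevance == "nonmoral"

    def test_exact_tie_is_nonmoral(self):
        records = [rec("u", "a", True, ("care.virtue",)), rec("u", "b", False)]
        assert aggregate_cluster(records).relevance == "nonmoral"

    def test_foundation_tie_lexicographic(self):
        records = [
            rec("u", "a", True, ("purity.vice",)),
            rec("u", "b", True, ("care.virtue",)),
            rec("u", "c", True, ("care.virtue",)),
            rec("u", "d", True, ("purity.vice",)),
            rec("u", "e", True, ("purity.vice", "care.virtue")),
        ]
        assert aggregate_cluster(records).foundation == "care.virtue"


class TestAgreementRatio:
    def _label(self, relevance, foundation=None):
        return AggregatedLabel(relevance, foundation)

    def test_all_agree(self):
        labels = [self._label("moral", "care.virtue")] * 4
        rel, fnd = agreement_ratio(labels, self._label("moral", "care.virtue"))
        assert rel == 1.0 and fnd == 1.0

    def test_three_of_four(self):
        labels = [self._label("moral", "care.virtue")] * 3 + [self._label("nonmoral")]
        rel, fnd = agreement_ratio(labels, self._label("moral", "care.virtue"))
        assert rel == 0.75 and fnd == 0.75

    def test_none_agree(self):
        labels = [self._label("nonmoral")] * 5
        rel, _ = agreement_ratio(labels, self._label("moral", "care.virtue"))
        assert rel == 0.0


class TestRecoveryFromNoisyAnnotators:
    def test_accurate_annotators_recover_truth(self):
        """7 annotators at accuracy 0.95 recover >= 99% of utterances."""
        from morallex.synthetic_data import (
            GeneratorConfig,
            GroundTruth,
            GroundTruthManifest,
            simulate_survey,
        )

        rng = np.random.default_rng(5)
        manifest = GroundTruthManifest()
        for i in range(500):
            if rng.random() < 0.5:
                cat = CATEGORIES[rng.integers(10)]
                manifest.entries[f"u{i}"] = GroundTruth("moral", cat)
            else:
                manifest.entries[f"u{i}"] = GroundTruth("nonmoral", None)
        config = GeneratorConfig(
            seed=5,
            annotator_accuracy=0.95,
            n_annotators_per_utterance=7,
            attention_fail_rate=0.0,
        )
        records = simulate_survey(manifest, list(manifest.entries), config)
        by_utt = {}
        for r in filter_annotators(records):
            by_utt.setdefault(r.utterance_id, []).append(r)
        correct = 0
        for uid, truth in manifest.entries.items():
            initial = truth.true_category or "care.virtue"
            label = aggregate_utterance(by_utt[uid], initial)
            correct += (label.relevance == truth.true_relevance) and (
                label.foundation == truth.true_category
            )
        assert correct / len(manifest.entries) >= 0.99
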