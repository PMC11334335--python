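"""Generator determinism, planted structure, survey noise, test pools."""

import numpy as np
import pytest

from morallex.corpus_io import match_seeds, read_chat_corpus
from morallex.pipeline import manifest_labels
from morallex.emergence import first_appearance_ages, time_course
from morallex.synthetic_data import (
    FOUNDATION_SHARES,
    GeneratorConfig,
    default_lexicon,
    generate_corpus,
    generate_external_tests,
    simulate_survey,
    write_chat,
)
from morallex.types import CATEGORIES, SpeakerRole


class TestGenerateCorpus:
    def test_same_seed_identical_output(self):
        config = GeneratorConfig(seed=9, sentences_per_age_role=60)
        u1, m1 = generate_corpus(config)
        u2, m2 = generate_corpus(config)
        assert u1 == u2
        assert m1.entries == m2.entries

    def test_different_seeds_differ(self):
        u1, _ = generate_corpus(GeneratorConfig(seed=1, sentences_per_age_role=40))
        u2, _ = generate_corpus(GeneratorConfig(seed=2, sentences_per_age_role=40))
        assert [u.text for u in u1] != [u.text for u in u2]

    def test_single_category_config(self):
        shares = {"care": (1.0,) * 6}
        config = GeneratorConfig(
            seed=3, sentences_per_age_role=80, foundation_shares=shares
        )
        _, manifest = generate_corpus(config)
        cats = {
            g.true_category
            for g in manifest.entries.values()
            if g.true_relevance == "moral"
        }
        assert cats <= {"care.virtue", "care.vice"}

    def test_manifest_covers_every_utterance(self):
        utts, manifest = generate_corpus(GeneratorConfig(seed=4, sentences_per_age_role=50))
        assert {u.utterance_id for u in utts} == set(manifest.entries)

    def test_planted_onset_order_recovered(self):
        """First appearances follow Care -> Fairness -> Authority -> Loyalty."""
        config = GeneratorConfig(seed=5, sentences_per_age_role=500)  # n = 6,000
        utts, manifest = generate_corpus(config)
        table = time_course(manifest_labels(manifest), utts)
        # pool both roles: earliest appearance of each foundation anywhere
        ages = {}
        for role in SpeakerRole:
            for cat, age in first_appearance_ages(table, role).items():
                f = cat.split(".")[0]
                ages[f] = min(ages.get(f, 99), age)
        assert ages["care"] < ages["fairness"] < ages["authority"] < ages["loyalty"]

    def test_planted_shares_recovered_with_growing_n(self):
        """Mean absolute share error shrinks as the corpus grows."""
        def mae(n):
            config = GeneratorConfig(seed=6, sentences_per_age_role=n)
            utts, manifest = generate_corpus(config)
            table = time_course(manifest_labels(manifest), utts)
            errs = []
            for age_idx, age in enumerate(config.ages):
                for f, shares in FOUNDATION_SHARES.items():
                    planted = shares[age_idx] / sum(
                        s[age_idx] for s in FOUNDATION_SHARES.values()
                    )
                    got = sum(
                        table.frequency(age, SpeakerRole.CHILD, f"{f}.{p}")
                        for p in ("virtue", "vice")
                    )
                    errs.append(abs(got - planted))
            return float(np.mean(errs))

        assert mae(800) < mae(60)

    def test_ambiguous_sentences_use_polysemous_seeds(self):
        config = GeneratorConfig(seed=7, sentences_per_age_role=300)
        utts, manifest = generate_corpus(config)
        from morallex.synthetic_data import POLYSEMES

        amb = [
            u
            for u in utts
            if manifest[u.utterance_id].is_ambiguous_sense
        ]
        assert amb, "expected ambiguous sentences at the default rate"
        for u in amb:
            assert any(w in u.tokens for w in POLYSEMES)

    def test_seed_matching_finds_planted_moral_sentences(self):
        config = GeneratorConfig(seed=8, sentences_per_age_role=100)
        utts, manifest = generate_corpus(config)
        matched = {m.utterance_id for m in match_seeds(utts, default_lexicon())}
        moral = set(manifest.moral_ids())
        assert moral <= matched

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(moral_rate=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(foundation_shares={"care": (0.5, -0.1, 0, 0, 0, 0)})


class TestChatExport:
    def test_chat_round_trip_counts(self, tmp_path):
        config = GeneratorConfig(seed=10, sentences_per_age_role=30)
        utts, _ = generate_corpus(config)
        write_chat(utts, tmp_path)
        again = read_chat_corpus(tmp_path)
        assert len(again) == len(utts)
        assert {u.child_age_months for u in again} == {
            u.child_age_months for u in utts
        }
        roles = {u.speaker_role for u in again}
        assert roles == {SpeakerRole.CHILD, SpeakerRole.CARETAKER}


class TestSimulateSurvey:
    def _manifest(self, n=60, seed=0):
        from morallex.synthetic_data import GroundTruth, GroundTruthManifest

        rng = np.random.default_rng(seed)
        manifest = GroundTruthManifest()
        for i in range(n):
            if rng.random() < 0.6:
                manifest.entries[f"u{i}"] = GroundTruth(
                    "moral", CATEGORIES[rng.integers(10)]
                )
            else:
                manifest.entries[f"u{i}"] = GroundTruth("nonmoral", None)
        return manifest

    def test_perfect_annotators_match_truth(self):
        manifest = self._manifest()
        config = GeneratorConfig(
            seed=1, annotator_accuracy=1.0, n_annotators_per_utterance=3,
            attention_fail_rate=0.0,
        )
        for r in simulate_survey(manifest, list(manifest.entries), config):
            truth = manifest[r.utterance_id]
            assert r.says_moral == (truth.true_relevance == "moral")
            if r.says_moral:
                assert r.foundations == (truth.true_category,)

    def test_total_attention_failure_leaves_nothing(self):
        from morallex.annotation import filter_annotators

        manifest = self._manifest()
        config = GeneratorConfig(
            seed=2, n_annotators_per_utterance=3, attention_fail_rate=1.0
        )
        records = simulate_survey(manifest, list(manifest.entries), config)
        assert records and filter_annotators(records) == []

    def test_round_robin_coverage(self):
        """Every surveyed utterance receives annotations under the
        participant-pool scheme (300 annotators x 40 utterances each)."""
        manifest = self._manifest(n=50)
        config = GeneratorConfig(
            seed=3, n_annotators=20, utterances_per_annotator=40,
            attention_fail_rate=0.0,
        )
        records = simulate_survey(manifest, list(manifest.entries), config)
        covered = {r.utterance_id for r in records}
        assert covered == set(manifest.entries)
        # each annotator labels at most the configured number, no duplicates
        per_ann = {}
        for r in records:
            per_ann.setdefault(r.annotator_id, []).append(r.utterance_id)
        for uids in per_ann.values():
            assert len(uids) == len(set(uids)) <= 40

    def test_reproducible(self):
        manifest = self._manifest()
        config = GeneratorConfig(seed=4, n_annotators_per_utterance=5)
        r1 = simulate_survey(manifest, list(manifest.entries), config)
        r2 = simulate_survey(manifest, list(manifest.entries), config)
        assert r1 == r2


class TestExternalTests:
    def test_class_balance(self):
        pools = generate_external_tests(GeneratorConfig(seed=5), n_per_class_short=15)
        from collections import Counter

        counts = Counter(lab for _, lab in pools["short_10class"])
        assert set(counts) == set(CATEGORIES)
        assert all(c == 15 for c in counts.values())
        bin_counts = Counter(lab for _, lab in pools["short_binary"])
        assert bin_counts["moral"] == bin_counts["nonmoral"]

    def test_long_documents_majority_expression(self):
        """With full majority expression an oracle sentence classifier
        recovers every document label."""
        from morallex.synthetic_data import CONTEXT_WORDS

        pools = generate_external_tests(
            GeneratorConfig(seed=6), n_per_class_long=10, majority_expression=1.0
        )
        ctx_to_foundation = {
            w: cat.split(".")[0]
            for cat, words in CONTEXT_WORDS.items()
            for w in words
        }

        def oracle_doc_label(text):
            votes = [
                ctx_to_foundation[w]
                for w in text.replace(".", " ").split()
                if w in ctx_to_foundation
            ]
            from collections import Counter

            return Counter(votes).most_common(1)[0][0]

        for text, label in pools["long_5class"]:
            assert oracle_doc_label(text) == label

    def test_long_documents_sentence_counts(self):
        pools = generate_external_tests(GeneratorConfig(seed=7), n_per_class_long=10)
        for text, _ in pools["long_5class"]:
            n_sent = sum(1 for s in text.split(".") if s.strip())
            assert 2 <= n_sent <= 6

    def test_reproducible(self):
        p1 = generate_external_tests(GeneratorConfig(seed=8))
        p2 = generate_external_tests(GeneratorConfig(seed=8))
        assert p1 == p2
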