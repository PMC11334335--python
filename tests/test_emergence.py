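"""Frequency time-courses, permutation significance, negation, MLU, ANOVA."""

import numpy as np
import pytest

from morallex.emergence import (
    OBLIGATION_MODALS,
    PROPERTY_WORDS,
    compare_roles,
    contains_pattern,
    first_appearance_ages,
    lexical_subset_course,
    mlu,
    mlu_course,
    negation_split,
    pooled_age,
    significance_table,
    time_course,
    word_significance,
)
from morallex.types import AggregatedLabel, SpeakerRole, Utterance


def _utt(uid, text, age_years=3, role=SpeakerRole.CHILD, gender="unknown"):
    tokens = tuple(text.lower().split())
    return Utterance(uid, text, tokens, role, age_years * 12 + 3, gender)


def _moral(cat):
    return AggregatedLabel("moral", cat)


class TestTimeCourse:
    def test_single_moral_utterance_full_share(self):
        utt = _utt("u", "help me", age_years=2)
        table = time_course({"u": _moral("care.virtue")}, [utt])
        assert table.frequency(2, SpeakerRole.CHILD, "care.virtue") == 1.0

    def test_planted_split_recovered_exactly(self):
        utts = [_utt(f"c{i}", "care words") for i in range(60)]
        utts += [_utt(f"f{i}", "fair words") for i in range(40)]
        labels = {f"c{i}": _moral("care.virtue") for i in range(60)}
        labels |= {f"f{i}": _moral("fairness.virtue") for i in range(40)}
        table = time_course(labels, utts)
        assert table.frequency(3, SpeakerRole.CHILD, "care.virtue") == pytest.approx(0.6)
        assert table.frequency(3, SpeakerRole.CHILD, "fairness.virtue") == pytest.approx(0.4)

    def test_per_total_sentences_normalization(self):
        utts = [_utt(f"u{i}", "words here") for i in range(100)]
        labels = {f"u{i}": _moral("care.virtue") for i in range(5)}
        table = time_course(labels, utts, normalization="per_total_sentences")
        assert table.frequency(3, SpeakerRole.CHILD, "care.virtue") == pytest.approx(0.05)

    def test_share_of_moral_sums_to_one(self, small_study):
        labels = {u: l for u, l in small_study.labels.items() if l.is_moral}
        table = time_course(labels, small_study.utterances)
        df = table.to_frame()
        for (_, _), sub in df.groupby(["age_year", "role"]):
            assert sub.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gender_stratification(self):
        utts = [
            _utt("f1", "x", gender="female"),
            _utt("m1", "x", gender="male"),
        ]
        labels = {"f1": _moral("care.virtue"), "m1": _moral("purity.vice")}
        fem = time_course(labels, utts, gender="female")
        assert fem.frequency(3, SpeakerRole.CHILD, "care.virtue") == 1.0
        assert fem.frequency(3, SpeakerRole.CHILD, "purity.vice") == 0.0

    def test_age_pooling(self):
        utts = [_utt(f"u{a}", "x", age_years=a) for a in (7, 9, 11)]
        labels = {u.utterance_id: _moral("care.virtue") for u in utts}
        table = time_course(labels, utts, age_binner=pooled_age(7, 11))
        df = table.to_frame()
        assert set(df.age_year) == {7}
        assert int(df["count"].iloc[0]) == 3

    def test_first_appearance(self):
        utts = [_utt(f"u{i}", "x", age_years=a) for i, a in enumerate([1, 1, 2, 4])]
        labels = {
            "u0": _moral("care.virtue"),
            "u1": _moral("care.vice"),
            "u2": _moral("fairness.virtue"),
            "u3": _moral("loyalty.virtue"),
        }
        ages = first_appearance_ages(time_course(labels, utts), SpeakerRole.CHILD)
        assert ages["care.virtue"] == 1
        assert ages["fairness.virtue"] == 2
        assert ages["loyalty.virtue"] == 4


class TestWordSignificance:
    def test_single_word_is_never_flagged(self):
        """A word comprising all seed usage sits at the mean: p = 1."""
        token_lists = [["help"] for _ in range(50)]
        res = word_significance(token_lists, "help", {"help"}, n_perm=500, seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.flagged_insignificant

    def test_word_at_mean_in_every_resample(self):
        """Two words, one occurrence each per sentence: both sit at the mean."""
        token_lists = [["aa", "bb"] for _ in range(40)]
        res = word_significance(token_lists, "aa", {"aa", "bb"}, n_perm=500, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_rare_word_flagged(self):
        """1 occurrence vs ~1000 tokens over 20 words -> flagged at 0.01."""
        rng = np.random.default_rng(1)
        common = [f"w{i:02d}" for i in range(19)]
        token_lists = [[common[rng.integers(19)]] for _ in range(999)]
        token_lists.append(["rare"])
        seed_words = set(common) | {"rare"}
        res = word_significance(
            token_lists, "rare", seed_words, n_perm=2000, alpha=0.01, seed=2
        )
        assert res.flagged_insignificant
        assert res.p_value < 0.01

    def test_matches_naive_bootstrap_oracle(self):
        """Direct sentence-resampling loop agrees with the fast path."""
        rng = np.random.default_rng(3)
        words = ["aa", "bb", "cc", "dd"]
        token_lists = [
            [words[rng.integers(4)]] + (["aa"] if rng.random() < 0.3 else [])
            for _ in range(120)
        ]
        seed_words = set(words)
        res = {
            r.word: r.p_value
            for r in significance_table(token_lists, seed_words, n_perm=4000, seed=4)
        }
        # independent naive implementation
        n = len(token_lists)
        counts = np.zeros((n, 4))
        widx = {w: j for j, w in enumerate(words)}
        for i, sent in enumerate(token_lists):
            for t in sent:
                counts[i, widx[t]] += 1
        rng2 = np.random.default_rng(99)
        ge = np.zeros(4)
        n_perm = 4000
        for _ in range(n_perm):
            idx = rng2.integers(n, size=n)
            freq = counts[idx].sum(axis=0)
            ge += freq >= freq.mean()
        naive_p = (1 + ge) / (n_perm + 1)
        for j, w in enumerate(words):
            assert res[w] == pytest.approx(naive_p[j], abs=0.03)

    def test_flagged_iff_p_below_alpha(self):
        token_lists = [["x"], ["y"], ["x"], ["x"]]
        for r in significance_table(token_lists, {"x", "y"}, n_perm=200, seed=0):
            assert r.flagged_insignificant == (r.p_value < r.alpha)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            significance_table([], {"x"})
        with pytest.raises(ValueError):
            word_significance([["a"]], "missing", {"missing", "a"})


class TestNegationSplit:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("it's not fair", "negative"),
            ("it’s not fair", "negative"),  # curly apostrophe
            ("help me", "positive"),
            ("nobody wiped the germ off", "positive"),  # "no" must stand alone
            ("no that's mine", "negative"),
            ("I don't want it", "negative"),  # n't clitic
            ("a note on the door", "positive"),
        ],
    )
    def test_examples(self, text, expected):
        assert negation_split(text) == expected

    def test_pure_function_of_text(self):
        assert negation_split("not here") == negation_split("not here")


class TestMlu:
    def test_simple_means(self):
        assert mlu([_utt("a", "help me")]) == 2.0
        assert mlu([_utt("a", "a b"), _utt("b", "a b c d")]) == 3.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mlu([])

    def test_planted_age_slope_recovered(self):
        """The generator plants utterance length growing with age."""
        from morallex.synthetic_data import GeneratorConfig, generate_corpus

        utts, _ = generate_corpus(GeneratorConfig(seed=2, sentences_per_age_role=300))
        df = mlu_course(utts)
        for role, sub in df.groupby("role"):
            sub = sub.sort_values("age_year")
            assert sub.mlu.iloc[-1] > sub.mlu.iloc[0]


class TestLexicalSubsets:
    def test_property_sentence_counted_in_both_modes(self):
        utt = _utt("p", "no, that's mine", age_years=2)
        labels = {"p": _moral("fairness.virtue")}
        for mode in ("moral_only", "all"):
            df = lexical_subset_course([utt], labels, PROPERTY_WORDS, mode=mode)
            any_row = df[df.category == "any"]
            assert any_row["count"].iloc[0] == 1

    def test_modal_sentence_counted(self):
        utt = _utt("m", "you should go")
        df = lexical_subset_course([utt], {}, OBLIGATION_MODALS, mode="all")
        assert df[df.category == "any"]["count"].iloc[0] == 1

    def test_patterns_matched_as_listed(self):
        """"mustn't" matches its own pattern, not via the "must" prefix."""
        assert not contains_pattern("you mustn't shout", ["must"])
        assert contains_pattern("you mustn't shout", ["mustn't"])
        assert contains_pattern("you mustn’t shout", ["mustn't"])
        assert contains_pattern("that's n't mine", ["n't mine"])
        assert not contains_pattern("undermine the plan", ["mine"])

    def test_moral_only_excludes_unlabelled(self):
        utt = _utt("p", "that's mine")
        df = lexical_subset_course([utt], {}, PROPERTY_WORDS, mode="moral_only")
        assert df[df.category == "any"].empty

    def test_empty_word_set_errors(self):
        with pytest.raises(ValueError):
            lexical_subset_course([], {}, [], mode="all")


class TestCompareRoles:
    def test_identical_rates_give_zero_f(self):
        rates = [0.1, 0.2, 0.3, 0.25, 0.15, 0.2]
        f, p = compare_roles(rates, rates)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_two_group_anova(self):
        """Hand-computed F for two groups of 6 ages each."""
        a = np.array([0.10, 0.12, 0.08, 0.11, 0.09, 0.10])
        b = np.array([0.50, 0.52, 0.48, 0.51, 0.49, 0.50])
        f, p = compare_roles(a, b)
        n = 6
        grand = np.concatenate([a, b]).mean()
        ssb = n * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / (2 * n - 2))
        assert f == pytest.approx(f_hand, rel=1e-12)
        assert p < 0.001

    def test_planted_role_effect_detected(self):
        """Caretakers are planted to stress Fairness far more than children."""
        from morallex.pipeline import manifest_labels
        from morallex.synthetic_data import GeneratorConfig, generate_corpus
        from morallex.emergence import compare_roles_table, time_course

        utts, manifest = generate_corpus(
            GeneratorConfig(seed=6, sentences_per_age_role=800)
        )
        table = time_course(
            manifest_labels(manifest), utts, normalization="per_total_sentences"
        )
        df = compare_roles_table(table)
        row = df[df.category == "fairness.virtue"]
        assert not row.empty and float(row.p.iloc[0]) < 0.05

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            compare_roles([0.1], [0.2])
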