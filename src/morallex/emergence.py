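"""Developmental analyses of moral-foundation language.

Given moral labels for an age-tagged corpus these routines compute:

* frequency time-courses per foundation-polarity category, either as a
  share of moral language at each (age, role) or normalized by the total
  number of sentences;
* bootstrap/permutation significance of individual moral words against
  the average seed-word frequency at an age;
* the negation split (utterances containing *no*, *not*, or *n't*);
* mean length of utterance (MLU, in words);
* time-courses for arbitrary lexical subsets (property words, obligation
  modals) matched as listed patterns on raw text;
* one-way ANOVA comparing per-age category rates between child speech
  and child-directed speech.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import normalize_apostrophes
from .types import AggregatedLabel, SpeakerRole, Utterance

AgeBinner = Callable[[int], int]


def identity_age(age_years: int) -> int:
    return age_years


def pooled_age(pool_from: int, pool_to: int) -> AgeBinner:
    """Bin ages in [pool_from, pool_to] into one bin labelled pool_from.

    Data above age 6 is sparse and noisy per year; the pooled bin (e.g.
    ages 7-11) aggregates it.
    """

    def _bin(age_years: int) -> int:
        if pool_from <= age_years <= pool_to:
            return pool_from
        return age_years

    return _bin


@dataclass
class FrequencyTable:
    """Counts of moral utterances per (age, role, category) cell."""

    counts: dict[tuple[int, SpeakerRole, str], int]
    denominators: dict[tuple[int, SpeakerRole], int]
    normalization: str  # "share_of_moral" | "per_total_sentences"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        moral_totals: dict[tuple[int, SpeakerRole], int] = {}
        for (age, role, _cat), c in self.counts.items():
            moral_totals[(age, role)] = moral_totals.get((age, role), 0) + c
        for (age, role, cat), c in sorted(
            self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2])
        ):
            if self.normalization == "share_of_moral":
                denom = moral_totals[(age, role)]
            else:
                denom = self.denominators.get((age, role), 0)
            rows.append(
                {
                    "age_year": age,
                    "role": role.value,
                    "category": cat,
                    "count": c,
                    "denominator": denom,
                    "frequency": c / denom if denom else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def frequency(self, age: int, role: SpeakerRole, cat: str) -> float:
        df = self.to_frame()
        row = df[
            (df.age_year == age) & (df.role == role.value) & (df.category == cat)
        ]
        return float(row.frequency.iloc[0]) if len(row) else 0.0


def time_course(
    labels: Mapping[str, AggregatedLabel],
    utterances: Sequence[Utterance],
    normalization: str = "share_of_moral",
    age_binner: AgeBinner = identity_age,
    gender: Optional[str] = None,
) -> FrequencyTable:
    """Count morally labelled utterances per (age, role, category).

    ``gender`` restricts the table to one child-gender stratum.
    Denominators count *all* utterances at each (age, role), so the
    per_total_sentences normalization is a rate over everything said.
    """
    if normalization not in ("share_of_moral", "per_total_sentences"):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts: dict[tuple[int, SpeakerRole, str], int] = {}
    denoms: dict[tuple[int, SpeakerRole], int] = {}
    for utt in utterances:
        if gender is not None and utt.child_gender != gender:
            continue
        age = age_binner(utt.age_years)
        key = (age, utt.speaker_role)
        denoms[key] = denoms.get(key, 0) + 1
        lab = labels.get(utt.utterance_id)
        if lab is not None and lab.is_moral:
            ckey = (age, utt.speaker_role, lab.foundation)
            counts[ckey] = counts.get(ckey, 0) + 1
    return FrequencyTable(counts, denoms, normalization)


def first_appearance_ages(
    table: FrequencyTable,
    role: SpeakerRole,
    min_share: float = 0.0,
) -> dict[str, int]:
    """Earliest age bin at which each category exceeds ``min_share``."""
    df = table.to_frame()
    df = df[(df.role == role.value) & (df.frequency > min_share)]
    return {
        cat: int(sub.age_year.min()) for cat, sub in df.groupby("category")
    }


# ---------------------------------------------------------------------------
# Word-level permutation significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    word: str
    age_year: int
    p_value: float
    flagged_insignificant: bool
    n_perm: int
    alpha: float
    seed: int


def significance_table(
    token_lists: Sequence[Sequence[str]],
    seed_words: set[str],
    n_perm: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
    age_year: int = -1,
) -> list[PermutationResult]:
    """Bootstrap significance for every seed word used in the input.

    Resamples the moral sentences with replacement (same size as the
    original), counts each seed word's frequency in the resample, and
    compares it with the mean frequency over all seed words present in
    the original data.  The p-value is the add-one estimator

        p = (1 + #{resamples with freq_word >= mean}) / (n_perm + 1)

    so a small p flags a word whose usage sits significantly *below* the
    average moral-word frequency (noise-level appearances).
    """
    if not token_lists:
        raise ValueError("no moral utterances supplied")
    words = sorted(
        {t for sent in token_lists for t in sent if t in seed_words}
    )
    if not words:
        raise ValueError("no seed word occurs in the supplied utterances")
    widx = {w: j for j, w in enumerate(words)}
    n, W = len(token_lists), len(words)
    M = np.zeros((n, W))
    for i, sent in enumerate(token_lists):
        for t in sent:
            j = widx.get(t)
            if j is not None:
                M[i, j] += 1.0
    rng = np.random.default_rng(seed)
    # bootstrap of sentences == multinomial over distinct seed-count
    # profiles (sums of multinomial blocks are multinomial), so collapse
    # identical rows of M before sampling
    profiles, group_counts = np.unique(M, axis=0, return_counts=True)
    C = rng.multinomial(n, group_counts / n, size=n_perm).astype(float)
    freq = C @ profiles  # (n_perm, W) seed-word counts per resample
    means = freq.mean(axis=1, keepdims=True)
    ge = (freq >= means).sum(axis=0)
    pvals = (1.0 + ge) / (n_perm + 1.0)
    return [
        PermutationResult(
            w, age_year, float(pvals[j]), bool(pvals[j] < alpha), n_perm, alpha, seed
        )
        for j, w in enumerate(words)
    ]


def word_significance(
    token_lists: Sequence[Sequence[str]],
    word: str,
    seed_words: set[str],
    n_perm: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
    age_year: int = -1,
) -> PermutationResult:
    """Significance of one word's frequency among moral utterances."""
    results = significance_table(
        token_lists, seed_words, n_perm, alpha, seed, age_year
    )
    for r in results:
        if r.word == word:
            return r
    raise ValueError(f"word {word!r} does not occur in the moral utterances")


# ---------------------------------------------------------------------------
# Negation, MLU, lexical subsets
# ---------------------------------------------------------------------------

_NEG_RE = re.compile(r"\b(?:no|not)\b")


def negation_split(text: str) -> str:
    """Classify an utterance as negative or positive.

    Negative utterances contain the standalone words *no* or *not*, or
    the clitic *n't* anywhere ("nobody" is positive: *no* must stand
    alone).
    """
    t = normalize_apostrophes(text).lower()
    if "n't" in t or _NEG_RE.search(t):
        return "negative"
    return "positive"


def mlu(utterances: Sequence[Utterance]) -> float:
    """Mean length of utterance in words."""
    if not utterances:
        raise ValueError("MLU of an empty utterance set")
    return float(np.mean([len(u.tokens) for u in utterances]))


def mlu_course(
    utterances: Sequence[Utterance],
    labels: Optional[Mapping[str, AggregatedLabel]] = None,
    age_binner: AgeBinner = identity_age,
) -> pd.DataFrame:
    """MLU per (age, role); restricted to moral utterances when labelled."""
    rows: dict[tuple[int, str], list[int]] = {}
    for u in utterances:
        if labels is not None:
            lab = labels.get(u.utterance_id)
            if lab is None or not lab.is_moral:
                continue
        rows.setdefault((age_binner(u.age_years), u.speaker_role.value), []).append(
            len(u.tokens)
        )
    return pd.DataFrame(
        [
            {"age_year": a, "role": r, "mlu": float(np.mean(v)), "n": len(v)}
            for (a, r), v in sorted(rows.items())
        ]
    )


def _pattern_regex(pattern: str) -> re.Pattern:
    pat = normalize_apostrophes(pattern.lower())
    left = r"\b" if not pat.startswith("n't") else ""
    right = r"\b" if pat[-1].isalnum() else ""
    return re.compile(left + re.escape(pat) + right)


def contains_pattern(text: str, patterns: Sequence[str]) -> bool:
    """Whether raw text contains any of the listed word patterns.

    Patterns are matched exactly as listed with word boundaries, so
    *must* does not match *mustn't*; multi-word patterns match on the raw
    lowercased text; curly apostrophes are normalized first.
    """
    t = normalize_apostrophes(text).lower()
    return any(_pattern_regex(p).search(t) for p in patterns)


PROPERTY_WORDS = ("mine", "yours", "not mine", "not yours", "n't mine", "n't yours")
OBLIGATION_MODALS = ("should", "must", "shouldn't", "mustn't", "should not", "must not")


def lexical_subset_course(
    utterances: Sequence[Utterance],
    labels: Mapping[str, AggregatedLabel],
    word_set: Sequence[str],
    mode: str = "moral_only",
    age_binner: AgeBinner = identity_age,
) -> pd.DataFrame:
    """Per-(age, role) rate of sentences containing listed patterns.

    ``mode="moral_only"`` counts only morally labelled sentences;
    ``mode="all"`` counts every sentence.  Rates are normalized by the
    total number of sentences at that (age, role).  A per-category
    breakdown of the matched moral sentences is attached as extra rows in
    the ``category`` column (the aggregate rows carry category "any").
    """
    if mode not in ("moral_only", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if not word_set:
        raise ValueError("empty word set")
    totals: dict[tuple[int, str], int] = {}
    hits: dict[tuple[int, str], int] = {}
    by_cat: dict[tuple[int, str, str], int] = {}
    for u in utterances:
        key = (age_binner(u.age_years), u.speaker_role.value)
        totals[key] = totals.get(key, 0) + 1
        if not contains_pattern(u.text, word_set):
            continue
        lab = labels.get(u.utterance_id)
        is_moral = lab is not None and lab.is_moral
        if mode == "moral_only" and not is_moral:
            continue
        hits[key] = hits.get(key, 0) + 1
        if is_moral:
            ck = (key[0], key[1], lab.foundation)
            by_cat[ck] = by_cat.get(ck, 0) + 1
    rows = []
    for key, c in sorted(hits.items()):
        rows.append(
            {
                "age_year": key[0],
                "role": key[1],
                "category": "any",
                "count": c,
                "denominator": totals[key],
                "frequency": c / totals[key],
            }
        )
    for (age, role, cat), c in sorted(by_cat.items()):
        rows.append(
            {
                "age_year": age,
                "role": role,
                "category": cat,
                "count": c,
                "denominator": totals[(age, role)],
                "frequency": c / totals[(age, role)],
            }
        )
    return pd.DataFrame(
        rows, columns=["age_year", "role", "category", "count", "denominator", "frequency"]
    )


def compare_roles(
    cs_rates: Sequence[float], cds_rates: Sequence[float]
) -> tuple[float, float]:
    """One-way ANOVA on per-age category rates with role as the factor."""
    if len(cs_rates) < 2 or len(cds_rates) < 2:
        raise ValueError("need at least 2 age bins per role")
    f, p = stats.f_oneway(np.asarray(cs_rates, float), np.asarray(cds_rates, float))
    return float(f), float(p)


def compare_roles_table(
    table: FrequencyTable,
) -> pd.DataFrame:
    """ANOVA per category over the per-age rate vectors of the two roles."""
    df = table.to_frame()
    rows = []
    for cat, sub in df.groupby("category"):
        cs = sub[sub.role == SpeakerRole.CHILD.value].sort_values("age_year")
        cds = sub[sub.role == SpeakerRole.CARETAKER.value].sort_values("age_year")
        if len(cs) < 2 or len(cds) < 2:
            continue
        f, p = compare_roles(cs.frequency.to_numpy(), cds.frequency.to_numpy())
        rows.append({"category": cat, "F": f, "p": p})
    return pd.DataFrame(rows, columns=["category", "F", "p"])
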