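"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here so each stage is
testable offline: an age-structured child/caretaker corpus (CHAT and
JSONL), a toy moral lexicon in the ten-category .dic schema, simulated
survey annotators, and out-of-domain labelled test documents.

The generator plants:

* per-category usage curves over ages 1-6 with staggered onsets
  (Care from age 1, Fairness from 2, Purity from 2, Authority from 3,
  Loyalty from 4) and a Care-dominated share profile, mirroring the
  developmental ordering the emergence analyses are designed to detect;
* ambiguous (nonmoral) senses of designated polysemous seed words --
  "fair" appears both in fair-sharing contexts and in carnival contexts;
* negation at per-category rates, higher in child speech and for
  Fairness/Authority;
* utterance length growing with age (so MLU has a planted slope);
* noisy annotators with configurable accuracy and attention-check
  failures;
* short single-sentence and multi-sentence out-of-domain test documents
  built from the same category vocabularies plus adult-only filler.

Sentences are simple subject-verb-object templates; each category owns a
distinct context vocabulary so that hash-based sentence encoders
separate the categories geometrically and downstream clustering and
classification have recoverable signal.  All outputs are pure functions
of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import (
    AnnotationRecord,
    CATEGORIES,
    LexiconEntry,
    SpeakerRole,
    Utterance,
    split_category,
)
from .corpus_io import tokenize_sentence

AGES = (1, 2, 3, 4, 5, 6)

SEED_WORDS: dict[str, tuple[str, ...]] = {
    "care.virtue": ("help", "care", "rescue", "hug"),
    "care.vice": ("hurt", "fight", "hit", "harm"),
    "fairness.virtue": ("fair", "share", "honest", "equal"),
    "fairness.vice": ("cheat", "steal", "unfair", "trick"),
    "loyalty.virtue": ("together", "team", "loyal", "friend"),
    "loyalty.vice": ("enemy", "betray", "traitor", "desert"),
    "authority.virtue": ("obey", "permission", "respect", "rule"),
    "authority.vice": ("disobey", "rebel", "defy", "illegal"),
    "purity.virtue": ("clean", "pure", "holy", "bless"),
    "purity.vice": ("dirty", "gross", "germ", "filthy"),
}

#: distinct per-category context vocabulary (drives embedding geometry)
CONTEXT_WORDS: dict[str, tuple[str, ...]] = {
    "care.virtue": ("gentle", "kindly", "comfort", "soothe", "tend"),
    "care.vice": ("ouch", "bruise", "wound", "cruel", "smack"),
    "fairness.virtue": ("evenly", "turns", "portion", "deserve", "split"),
    "fairness.vice": ("swindle", "sneaky", "crooked", "grab", "hoard"),
    "loyalty.virtue": ("club", "side", "buddy", "stick", "group"),
    "loyalty.vice": ("rival", "deserter", "turncoat", "against", "quit"),
    "authority.virtue": ("listen", "allowed", "teacher", "polite", "ask"),
    "authority.vice": ("naughty", "forbidden", "ignore", "refuse", "breaking"),
    "purity.virtue": ("wash", "fresh", "tidy", "neat", "sparkling"),
    "purity.vice": ("yucky", "mud", "smelly", "sticky", "rotten"),
}

#: polysemous seed word -> its nonmoral context vocabulary
POLYSEMES: dict[str, tuple[str, ...]] = {
    "fair": ("ride", "carnival", "ferris", "wheel", "ticket"),
    "hit": ("ball", "bat", "swing", "base", "catch"),
    "rule": ("ruler", "measure", "line", "draw", "paper"),
}

SUBJECTS = ("you", "i", "we", "he", "she", "they")
FILLER = (
    "ball", "truck", "banana", "juice", "block", "puppy", "story", "park",
    "bath", "shoe", "sock", "spoon", "cup", "book", "train", "doll", "look",
    "want", "go", "see", "play", "eat", "put", "get", "come", "little", "big",
    "the", "a", "my", "your", "now", "here", "there", "again",
)
ADULT_FILLER = (
    "meeting", "office", "budget", "decided", "community", "project",
    "yesterday", "manager", "proposal", "committee", "report", "weekend",
)
ADULT_SUBJECTS = ("people", "workers", "neighbors", "strangers", "everyone")

#: share of moral language per foundation at each age (columns = ages 1..6).
#: Onsets stagger Care -> Fairness/Purity -> Authority -> Loyalty; Care
#: dominates throughout, Loyalty stays rare -- the profile the emergence
#: analyses are designed to recover.
FOUNDATION_SHARES: dict[str, tuple[float, ...]] = {
    "care": (0.97, 0.90, 0.84, 0.81, 0.785, 0.76),
    "fairness": (0.00, 0.05, 0.07, 0.08, 0.09, 0.10),
    "purity": (0.03, 0.05, 0.06, 0.06, 0.06, 0.07),
    "authority": (0.00, 0.00, 0.03, 0.04, 0.05, 0.05),
    "loyalty": (0.00, 0.00, 0.00, 0.01, 0.015, 0.02),
}

#: virtue share within each foundation
VIRTUE_SHARE = {"care": 0.6, "fairness": 0.5, "loyalty": 0.5, "authority": 0.5, "purity": 0.4}

#: (child, caretaker) rate multipliers creating role asymmetries:
#: children talk more about cheating, caretakers more about fairness and
#: (physical) degradation.
ROLE_BIAS: dict[str, tuple[float, float]] = {
    "fairness.virtue": (0.7, 1.3),
    "fairness.vice": (1.3, 0.7),
    "purity.vice": (0.7, 1.5),
}

#: per-category negation rates for child speech (caretakers use half)
NEGATION_RATES: dict[str, float] = {
    **{c: 0.15 for c in CATEGORIES},
    "fairness.virtue": 0.45,
    "fairness.vice": 0.35,
    "authority.virtue": 0.35,
    "authority.vice": 0.35,
    "purity.vice": 0.25,
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    ages: tuple[int, ...] = AGES
    sentences_per_age_role: int = 500
    moral_rate: float = 0.15  # share of utterances that are moral
    foundation_shares: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: FOUNDATION_SHARES
    )
    ambiguity_rate: float = 0.3  # nonmoral share of polysemous seed usage
    negation_rates: Mapping[str, float] = field(
        default_factory=lambda: NEGATION_RATES
    )
    cds_negation_multiplier: float = 0.5
    annotator_accuracy: float = 0.9
    n_annotators: int = 300
    utterances_per_annotator: int = 40
    n_annotators_per_utterance: Optional[int] = None  # overrides the above
    attention_fail_rate: float = 50 / 300
    corpus_name: str = "SynCorpus"

    def __post_init__(self) -> None:
        for name, probs in [
            ("moral_rate", [self.moral_rate]),
            ("ambiguity_rate", [self.ambiguity_rate]),
            ("annotator_accuracy", [self.annotator_accuracy]),
            ("attention_fail_rate", [self.attention_fail_rate]),
        ]:
            for p in probs:
                if not 0 <= p <= 1:
                    raise ValueError(f"{name} outside [0, 1]")
        for f, shares in self.foundation_shares.items():
            if any(s < 0 for s in shares) or len(shares) != len(self.ages):
                raise ValueError(f"invalid share curve for {f}")


@dataclass(frozen=True)
class GroundTruth:
    true_relevance: str  # moral | nonmoral
    true_category: Optional[str]  # foundation-polarity category
    is_ambiguous_sense: bool = False


@dataclass
class GroundTruthManifest:
    entries: dict[str, GroundTruth] = field(default_factory=dict)

    def __getitem__(self, uid: str) -> GroundTruth:
        return self.entries[uid]

    def __contains__(self, uid: str) -> bool:
        return uid in self.entries

    def moral_ids(self) -> list[str]:
        return [u for u, g in self.entries.items() if g.true_relevance == "moral"]

    def save(self, path) -> None:
        import json

        payload = {
            uid: [g.true_relevance, g.true_category, g.is_ambiguous_sense]
            for uid, g in self.entries.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GroundTruthManifest":
        import json

        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        manifest = cls()
        for uid, (rel, cat, amb) in payload.items():
            manifest.entries[uid] = GroundTruth(rel, cat, amb)
        return manifest


def default_lexicon() -> list[LexiconEntry]:
    """Toy ten-category lexicon; the first word per category is a stem."""
    entries = []
    for cat, words in SEED_WORDS.items():
        foundation, polarity = split_category(cat)
        for i, w in enumerate(words):
            entries.append(LexiconEntry(w, i == 0, foundation, polarity))
    return entries


def _category_probs(config: GeneratorConfig, age_idx: int, role: SpeakerRole) -> dict[str, float]:
    probs: dict[str, float] = {}
    for f, shares in config.foundation_shares.items():
        for pol, vs in (("virtue", VIRTUE_SHARE[f]), ("vice", 1 - VIRTUE_SHARE[f])):
            cat = f"{f}.{pol}"
            p = shares[age_idx] * vs
            bias = ROLE_BIAS.get(cat)
            if bias is not None:
                p *= bias[0] if role == SpeakerRole.CHILD else bias[1]
            probs[cat] = p
    total = sum(probs.values())
    return {c: p / total for c, p in probs.items()} if total else probs


def _pad(rng: np.random.Generator, age: int, vocab: Sequence[str] = FILLER) -> list[str]:
    n = int(rng.poisson(1.0 + 0.8 * age))
    return [vocab[i] for i in rng.integers(len(vocab), size=n)]


def _moral_sentence(
    rng: np.random.Generator, cat: str, age: int, negated: bool
) -> str:
    words = [SUBJECTS[rng.integers(len(SUBJECTS))]]
    if negated:
        words.append("not" if rng.random() < 0.7 else "don't")
    seeds = SEED_WORDS[cat]
    words.append(seeds[rng.integers(len(seeds))])
    ctx = CONTEXT_WORDS[cat]
    k = 2 if rng.random() < 0.7 else 3
    words.extend(ctx[i] for i in rng.choice(len(ctx), size=k, replace=False))
    # age-scaled padding stays within the category vocabulary so moral
    # sentences keep a sharp per-category geometry for the encoder
    words.extend(_pad(rng, age, ctx + seeds))
    return " ".join(words)


def _nonmoral_sentence(rng: np.random.Generator, age: int) -> str:
    words = [SUBJECTS[rng.integers(len(SUBJECTS))]]
    n = 2 + int(rng.integers(3))
    words.extend(FILLER[i] for i in rng.integers(len(FILLER), size=n))
    words.extend(_pad(rng, age))
    return " ".join(words)


def _ambiguous_sentence(rng: np.random.Generator, word: str, age: int) -> str:
    ctx = POLYSEMES[word]
    words = [SUBJECTS[rng.integers(len(SUBJECTS))], word]
    words.extend(ctx[i] for i in rng.choice(len(ctx), size=2, replace=False))
    words.extend(_pad(rng, age))
    return " ".join(words)


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Utterance], GroundTruthManifest]:
    """Generate the age-structured corpus with its ground-truth manifest.

    Per (age, role) cell, a fixed number of utterances is drawn; each is
    moral with probability ``moral_rate`` (its category drawn from the
    planted curves), an ambiguous nonmoral use of a polysemous seed word
    at a rate tied to ``ambiguity_rate``, or plain nonmoral filler.
    """
    rng = np.random.default_rng(config.seed)
    utterances: list[Utterance] = []
    manifest = GroundTruthManifest()
    poly_words = list(POLYSEMES)
    for age_idx, age in enumerate(config.ages):
        for role in SpeakerRole:
            cat_probs = _category_probs(config, age_idx, role)
            cats = list(cat_probs)
            pvec = np.array([cat_probs[c] for c in cats])
            n = config.sentences_per_age_role
            role_tag = "cs" if role == SpeakerRole.CHILD else "cds"
            for i in range(n):
                uid = f"syn-{age}-{role_tag}-{i:05d}"
                gender = "female" if i % 2 == 0 else "male"
                r = rng.random()
                amb_rate = config.moral_rate * config.ambiguity_rate
                if r < config.moral_rate and pvec.sum() > 0:
                    cat = cats[rng.choice(len(cats), p=pvec)]
                    neg_rate = config.negation_rates.get(cat, 0.15)
                    if role == SpeakerRole.CARETAKER:
                        neg_rate *= config.cds_negation_multiplier
                    text = _moral_sentence(rng, cat, age, rng.random() < neg_rate)
                    truth = GroundTruth("moral", cat)
                elif r < config.moral_rate + amb_rate:
                    w = poly_words[rng.integers(len(poly_words))]
                    text = _ambiguous_sentence(rng, w, age)
                    truth = GroundTruth("nonmoral", None, is_ambiguous_sense=True)
                else:
                    text = _nonmoral_sentence(rng, age)
                    truth = GroundTruth("nonmoral", None)
                utterances.append(
                    Utterance(
                        utterance_id=uid,
                        text=text,
                        tokens=tuple(tokenize_sentence(text)),
                        speaker_role=role,
                        child_age_months=age * 12 + 6,
                        child_gender=gender,
                        corpus_name=config.corpus_name,
                    )
                )
                manifest.entries[uid] = truth
    return utterances, manifest


def write_chat(utterances: Sequence[Utterance], out_dir: str | Path) -> list[Path]:
    """Write utterances as CHAT files (one per age/gender group)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, int, str], list[Utterance]] = {}
    for u in utterances:
        groups.setdefault((u.corpus_name, u.child_age_months, u.child_gender), []).append(u)
    paths = []
    for (corpus, months, gender), members in sorted(groups.items()):
        years, rem = divmod(months, 12)
        path = out_dir / f"{corpus.lower()}_{years:02d}_{gender}.cha"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("@UTF8\n@Begin\n@Languages:\teng\n")
            fh.write("@Participants:\tCHI Target_Child, MOT Mother\n")
            fh.write(
                f"@ID:\teng|{corpus}|CHI|{years};{rem:02d}.00|{gender}|||Target_Child|||\n"
            )
            fh.write(f"@ID:\teng|{corpus}|MOT|||||Mother|||\n")
            for u in members:
                tier = "CHI" if u.speaker_role == SpeakerRole.CHILD else "MOT"
                fh.write(f"*{tier}:\t{u.text} .\n")
            fh.write("@End\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Simulated survey
# ---------------------------------------------------------------------------

def _wrong_answer(
    rng: np.random.Generator, truth: GroundTruth
) -> tuple[bool, tuple[str, ...]]:
    """A uniformly random alternative to the true annotation."""
    if truth.true_relevance == "moral":
        options = ["nonmoral"] + [c for c in CATEGORIES if c != truth.true_category]
    else:
        options = list(CATEGORIES)
    pick = options[rng.integers(len(options))]
    if pick == "nonmoral":
        return False, ()
    return True, (pick,)


def simulate_survey(
    manifest: GroundTruthManifest,
    surveyed_ids: Sequence[str],
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> list[AnnotationRecord]:
    """Simulate annotators over the surveyed utterances.

    With ``n_annotators_per_utterance`` set, each utterance receives that
    many annotators.  Otherwise each of ``n_annotators`` participants
    labels ``utterances_per_annotator`` utterances assigned by shuffled
    round-robin, so coverage is near-uniform.  Each response matches the
    ground truth with probability ``annotator_accuracy`` and is otherwise
    a uniformly random alternative; whole annotators fail the attention
    check at ``attention_fail_rate``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    surveyed = [u for u in surveyed_ids if u in manifest]
    if not surveyed:
        return []

    assignments: dict[str, list[str]] = {}
    if config.n_annotators_per_utterance is not None:
        k = config.n_annotators_per_utterance
        for j, uid in enumerate(surveyed):
            for a in range(k):
                assignments.setdefault(f"ann{j * k + a:05d}", []).append(uid)
    else:
        need = config.n_annotators * config.utterances_per_annotator
        stream: list[str] = []
        while len(stream) < need:
            stream.extend(np.array(surveyed)[rng.permutation(len(surveyed))])
        for a in range(config.n_annotators):
            chunk = stream[
                a * config.utterances_per_annotator : (a + 1) * config.utterances_per_annotator
            ]
            seen: set[str] = set()
            assignments[f"ann{a:05d}"] = [
                u for u in chunk if not (u in seen or seen.add(u))
            ]

    records: list[AnnotationRecord] = []
    for ann_id in sorted(assignments):
        passed = rng.random() >= config.attention_fail_rate
        for uid in assignments[ann_id]:
            truth = manifest[uid]
            if rng.random() < config.annotator_accuracy:
                says = truth.true_relevance == "moral"
                fnds = (truth.true_category,) if says else ()
            else:
                says, fnds = _wrong_answer(rng, truth)
            records.append(
                AnnotationRecord(uid, ann_id, says, fnds, passed_attention=passed)
            )
    return records


# ---------------------------------------------------------------------------
# Out-of-domain test documents
# ---------------------------------------------------------------------------

def _test_sentence(rng: np.random.Generator, cat: str) -> str:
    words = [ADULT_SUBJECTS[rng.integers(len(ADULT_SUBJECTS))]]
    seeds = SEED_WORDS[cat]
    words.append(seeds[rng.integers(len(seeds))])
    ctx = CONTEXT_WORDS[cat]
    words.extend(ctx[i] for i in rng.choice(len(ctx), size=2, replace=False))
    words.extend(
        ADULT_FILLER[i] for i in rng.integers(len(ADULT_FILLER), size=int(rng.integers(1, 3)))
    )
    return " ".join(words)


def _test_nonmoral(rng: np.random.Generator) -> str:
    # everyday nonmoral content: adult filler plus common concrete nouns,
    # so nonmoral test documents share (nonmoral) vocabulary with the
    # conversational domain the classifiers were trained on
    words = [ADULT_SUBJECTS[rng.integers(len(ADULT_SUBJECTS))]]
    words.extend(
        ADULT_FILLER[i] for i in rng.integers(len(ADULT_FILLER), size=2 + int(rng.integers(2)))
    )
    words.extend(FILLER[i] for i in rng.integers(len(FILLER), size=2))
    return " ".join(words)


def generate_external_tests(
    config: GeneratorConfig,
    n_per_class_short: int = 40,
    n_per_class_long: int = 30,
    majority_expression: float = 0.75,
    seed: Optional[int] = None,
) -> dict[str, list[tuple[str, str]]]:
    """Labelled out-of-domain test pools.

    * ``short_binary``: single sentences labelled moral/nonmoral;
    * ``short_10class``: single sentences labelled with the ten
      foundation-polarity categories;
    * ``long_5class``: documents of 2-6 sentences labelled with one of
      the five foundations, where a ``majority_expression`` fraction of
      sentences express the document's foundation and the rest express
      random other foundations.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    short_10: list[tuple[str, str]] = []
    short_bin: list[tuple[str, str]] = []
    for cat in CATEGORIES:
        for _ in range(n_per_class_short):
            short_10.append((_test_sentence(rng, cat), cat))
    n_bin = n_per_class_short * 5
    for _ in range(n_bin):
        cat = CATEGORIES[rng.integers(len(CATEGORIES))]
        short_bin.append((_test_sentence(rng, cat), "moral"))
        short_bin.append((_test_nonmoral(rng), "nonmoral"))

    foundations = sorted({c.split(".")[0] for c in CATEGORIES})
    long_5: list[tuple[str, str]] = []
    for f in foundations:
        own_cats = [c for c in CATEGORIES if c.startswith(f + ".")]
        other_cats = [c for c in CATEGORIES if not c.startswith(f + ".")]
        for _ in range(n_per_class_long):
            n_sent = int(rng.integers(2, 7))
            sents = []
            for j in range(n_sent):
                if j == 0 or rng.random() < majority_expression:
                    cat = own_cats[rng.integers(len(own_cats))]
                else:
                    cat = other_cats[rng.integers(len(other_cats))]
                sents.append(_test_sentence(rng, cat))
            long_5.append((". ".join(sents) + ".", f))
    return {
        "short_binary": short_bin,
        "short_10class": short_10,
        "long_5class": long_5,
    }
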