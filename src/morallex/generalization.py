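"""Blank-slate moral inference from labelled conversational speech.

Logistic-regression classifiers are trained on averaged static token
embeddings of labelled utterances and evaluated on out-of-domain test
documents.  Three tasks are supported:

* ``binary_relevance`` -- moral vs nonmoral;
* ``fine_10class``     -- the ten foundation-polarity categories;
* ``fine_5class``      -- five foundations with polarity collapsed (the
  format of comment corpora that label Equality/Proportionality, which
  are folded into Fairness).

The model grid varies the cumulative age cutoff (years 1..6), four
embedding variants (two corpus-independent hash tables standing in for
general-purpose pretrained embeddings, and skip-gram / PPMI-SVD tables
trained on the corpus itself), and the speaker role (child vs
caretaker): 6 x 4 x 2 = 48 configurations per task.  Random controls
retrain each configuration on same-size seedless utterance samples with
randomly assigned labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .corpus_io import split_sentences, tokenize_sentence
from .embeddings import EmbeddingTable, mean_embedding
from .lemmatize import Lemmatizer, rule_lemma
from .types import AggregatedLabel, SpeakerRole, Utterance, CATEGORIES, FOUNDATIONS

TASKS = ("binary_relevance", "fine_10class", "fine_5class")
EMBEDDING_VARIANTS = (
    "static_pretrained_a",
    "static_pretrained_b",
    "static_corpus_a",
    "static_corpus_b",
)
AGE_CUTOFFS = (1, 2, 3, 4, 5, 6)

_FOUNDATION_NAMES = {f.value for f in FOUNDATIONS}


@dataclass(frozen=True)
class ModelConfig:
    task: str
    age_cutoff_years: int
    embedding_variant: str
    speaker_role: SpeakerRole
    train_source: str = "moral_labels"  # or "random_control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.embedding_variant not in EMBEDDING_VARIANTS:
            raise ValueError(f"unknown variant {self.embedding_variant!r}")


@dataclass(frozen=True)
class EvalResult:
    config: ModelConfig
    test_set_name: str
    micro_f1: float
    ci95: tuple[float, float]
    n_test_sets: int


def collapse_labels(label: str, to_five: bool = False) -> str:
    """Normalize a moral label.

    Equality and Proportionality (the split used by some comment
    corpora) map to Fairness.  With ``to_five`` a foundation-polarity
    category drops its polarity (``care.virtue -> care``).
    """
    lab = label.lower()
    if lab in ("equality", "proportionality"):
        return "fairness"
    if lab in CATEGORIES:
        return lab.split(".")[0] if to_five else lab
    if lab in _FOUNDATION_NAMES or lab in ("moral", "nonmoral"):
        return lab
    raise ValueError(f"unknown label {label!r}")


def task_label(label: AggregatedLabel, task: str) -> Optional[str]:
    """Map an aggregated label to a training target (None = excluded)."""
    if task == "binary_relevance":
        return label.relevance
    if not label.is_moral:
        return None
    if task == "fine_10class":
        return label.foundation
    return collapse_labels(label.foundation, to_five=True)


def build_training_matrix(
    labels: Mapping[str, AggregatedLabel],
    utterances: Sequence[Utterance],
    config: ModelConfig,
    table: EmbeddingTable,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assemble (features, targets, n_zero_excluded) for one config.

    Rows are mean static embeddings of labelled utterances of the
    configured role with age <= the cumulative cutoff.  All-out-of-
    vocabulary (zero-vector) utterances are excluded but counted.
    """
    X, y = [], []
    n_zero = 0
    for utt in utterances:
        if utt.speaker_role != config.speaker_role:
            continue
        if utt.age_years > config.age_cutoff_years:
            continue
        lab = labels.get(utt.utterance_id)
        if lab is None:
            continue
        target = task_label(lab, config.task)
        if target is None:
            continue
        vec, n_in = mean_embedding(utt.tokens, table)
        if n_in == 0:
            n_zero += 1
            continue
        X.append(vec)
        y.append(target)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(
            f"degenerate training set for {config.task}: classes {classes}"
        )
    return np.vstack(X), np.array(y), n_zero


def train_linear(
    features: np.ndarray, targets: np.ndarray, seed: int = 0, C: float = 1.0
) -> LogisticRegression:
    """Fit a regularized multinomial logistic-regression classifier.

    Class weights are balanced: moral language is heavily Care-dominated,
    and without reweighting the fine-grained models collapse to majority
    prediction on the rare foundations.
    """
    classes = np.unique(targets)
    if len(classes) < 2:
        raise ValueError(f"single-class training set: {list(classes)}")
    model = LogisticRegression(
        C=C, max_iter=2000, random_state=seed, class_weight="balanced"
    )
    model.fit(features, targets)
    return model


@dataclass
class MoralClassifier:
    """A fitted linear model together with its feature pipeline."""

    model: LogisticRegression
    table: EmbeddingTable
    lemmatizer: Lemmatizer = rule_lemma

    def features(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        return np.vstack([mean_embedding(t, self.table)[0] for t in token_lists])

    def predict_tokens(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        return self.model.predict(self.features(token_lists))

    def predict_text(self, texts: Sequence[str]) -> list[str]:
        return [
            predict_long_text(t, self, splitter=split_sentences) for t in texts
        ]


def predict_long_text(
    document: str,
    classifier: MoralClassifier,
    splitter: Callable[[str], list[str]] = split_sentences,
) -> str:
    """Label a multi-sentence document by sentence majority vote.

    Each sentence is classified independently; the document label is the
    majority of sentence labels, with ties broken by the highest summed
    predicted probability.
    """
    sentences = [s for s in splitter(document) if s.strip()]
    token_lists = [
        tokenize_sentence(s, classifier.lemmatizer) for s in sentences
    ]
    token_lists = [t for t in token_lists if t]
    if not token_lists:
        raise ValueError("empty document")
    X = classifier.features(token_lists)
    proba = classifier.model.predict_proba(X)
    classes = classifier.model.classes_
    preds = classes[np.argmax(proba, axis=1)]
    counts = pd.Series(preds).value_counts()
    top = counts.max()
    tied = sorted(counts[counts == top].index)
    if len(tied) == 1:
        return tied[0]
    sums = proba.sum(axis=0)
    by_class = {c: sums[i] for i, c in enumerate(classes)}
    return max(tied, key=lambda c: by_class[c])


def balanced_eval(
    pool: Sequence[tuple[str, str]],
    n_sets: int = 10,
    seed: int = 0,
    cap: Optional[int] = None,
) -> list[list[tuple[str, str]]]:
    """Draw class-balanced test sets from a labelled pool.

    Each set contains an equal number of documents per class (the
    minority-class count, optionally capped), sampled without
    replacement within a set; sets differ by their random draw.
    """
    by_class: dict[str, list[tuple[str, str]]] = {}
    for item in pool:
        by_class.setdefault(item[1], []).append(item)
    if len(by_class) < 2:
        raise ValueError("balanced evaluation needs at least two classes")
    m = min(len(v) for v in by_class.values())
    if cap is not None:
        m = min(m, cap)
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        chosen: list[tuple[str, str]] = []
        for cls in sorted(by_class):
            idx = rng.choice(len(by_class[cls]), size=m, replace=False)
            chosen.extend(by_class[cls][i] for i in idx)
        sets.append(chosen)
    return sets


def micro_f1(predictions: Sequence[str], golds: Sequence[str]) -> float:
    """Micro-averaged F1; equals accuracy for single-label prediction."""
    if len(predictions) != len(golds):
        raise ValueError("prediction/gold length mismatch")
    if len(golds) == 0:
        raise ValueError("empty evaluation")
    correct = sum(p == g for p, g in zip(predictions, golds))
    return correct / len(golds)


def _ci95(scores: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(scores, float)
    mean = arr.mean()
    half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return (float(mean - half), float(mean + half))


def evaluate_classifier(
    clf: MoralClassifier,
    test_sets: Sequence[Sequence[tuple[str, str]]],
    config: ModelConfig,
    test_set_name: str,
) -> EvalResult:
    scores = []
    for ts in test_sets:
        preds = clf.predict_text([text for text, _ in ts])
        scores.append(micro_f1(preds, [lab for _, lab in ts]))
    return EvalResult(
        config, test_set_name, float(np.mean(scores)), _ci95(scores), len(test_sets)
    )


@dataclass
class _PreparedSet:
    """Sentence features for one balanced test set (table-specific)."""

    X: np.ndarray  # stacked sentence features
    doc_slices: list[tuple[int, int]]
    golds: list[str]


def _prepare_test_sets(
    test_sets: Sequence[Sequence[tuple[str, str]]],
    table: EmbeddingTable,
    lemmatizer: Lemmatizer,
) -> list[_PreparedSet]:
    prepared = []
    for ts in test_sets:
        rows, slices, golds = [], [], []
        for text, gold in ts:
            token_lists = [
                t
                for t in (
                    tokenize_sentence(s, lemmatizer) for s in split_sentences(text)
                )
                if t
            ]
            if not token_lists:
                raise ValueError(f"empty test document {text!r}")
            start = len(rows)
            rows.extend(mean_embedding(t, table)[0] for t in token_lists)
            slices.append((start, len(rows)))
            golds.append(gold)
        prepared.append(_PreparedSet(np.vstack(rows), slices, golds))
    return prepared


def _vote_documents(
    proba: np.ndarray, classes: np.ndarray, slices: Sequence[tuple[int, int]]
) -> list[str]:
    """Sentence-majority document labels with probability-sum tie-break."""
    sent_pred = np.argmax(proba, axis=1)
    out = []
    for lo, hi in slices:
        counts = np.bincount(sent_pred[lo:hi], minlength=len(classes))
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out.append(classes[tied[0]])
        else:
            sums = proba[lo:hi].sum(axis=0)
            out.append(classes[tied[np.argmax(sums[tied])]])
    return out


def _score_model(model: LogisticRegression, prepared: Sequence[_PreparedSet]) -> list[float]:
    scores = []
    for ps in prepared:
        proba = model.predict_proba(ps.X)
        preds = _vote_documents(proba, model.classes_, ps.doc_slices)
        scores.append(micro_f1(preds, ps.golds))
    return scores


def _control_training_set(
    control_pool: Sequence[Utterance],
    classes: Sequence[str],
    size: int,
    config: ModelConfig,
    table: EmbeddingTable,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Seedless utterances with random class assignment, size-matched."""
    eligible = [
        u
        for u in control_pool
        if u.speaker_role == config.speaker_role
        and u.age_years <= config.age_cutoff_years
    ]
    if len(eligible) < len(classes):
        raise ValueError("control pool too small")
    idx = rng.choice(len(eligible), size=min(size, len(eligible)), replace=False)
    X, y = [], []
    for i in idx:
        vec, n_in = mean_embedding(eligible[i].tokens, table)
        if n_in == 0:
            continue
        X.append(vec)
        y.append(classes[rng.integers(len(classes))])
    if len(set(y)) < 2:  # force both classes present
        y[: len(classes)] = list(classes)
    return np.vstack(X), np.array(y)


def run_grid(
    utterances: Sequence[Utterance],
    labels: Mapping[str, AggregatedLabel],
    tables: Mapping[str, EmbeddingTable],
    test_sets: Mapping[str, Sequence[Sequence[tuple[str, str]]]],
    tasks: Sequence[str] = TASKS,
    train_source: str = "moral_labels",
    control_pool: Sequence[Utterance] = (),
    n_control: int = 20,
    seed: int = 0,
    lemmatizer: Lemmatizer = rule_lemma,
    age_cutoffs: Sequence[int] = AGE_CUTOFFS,
) -> list[EvalResult]:
    """Train and evaluate the full 48-configuration grid per task.

    ``tables`` must provide all four embedding variants.  ``test_sets``
    maps each task to its balanced evaluation sets.  With
    ``train_source="random_control"`` every configuration is retrained
    ``n_control`` times on random same-size seedless samples with random
    class assignment, and the reported score averages over those runs.
    """
    for variant in EMBEDDING_VARIANTS:
        if variant not in tables:
            raise ValueError(f"missing embedding variant {variant!r}")
    results: list[EvalResult] = []
    rng = np.random.default_rng(seed)
    # test features depend only on (task, variant): compute once
    prepared: dict[tuple[str, str], list[_PreparedSet]] = {}
    for task in tasks:
        for variant in EMBEDDING_VARIANTS:
            prepared[(task, variant)] = _prepare_test_sets(
                test_sets[task], tables[variant], lemmatizer
            )
    for task in tasks:
        for cutoff in age_cutoffs:
            for variant in EMBEDDING_VARIANTS:
                for role in SpeakerRole:
                    config = ModelConfig(
                        task, cutoff, variant, role, train_source, seed
                    )
                    table = tables[variant]
                    prep = prepared[(task, variant)]
                    X, y, _ = build_training_matrix(
                        labels, utterances, config, table
                    )
                    if train_source == "moral_labels":
                        model = train_linear(X, y, seed=seed)
                        scores = _score_model(model, prep)
                    else:
                        classes = sorted(set(y))
                        scores = []
                        for _ in range(n_control):
                            Xc, yc = _control_training_set(
                                control_pool, classes, len(y), config, table, rng
                            )
                            model = train_linear(Xc, yc, seed=seed)
                            scores.extend(_score_model(model, prep))
                    results.append(
                        EvalResult(
                            config,
                            task,
                            float(np.mean(scores)),
                            _ci95(scores),
                            len(test_sets[task]),
                        )
                    )
    return results


def results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "task": r.config.task,
                "age_cutoff": r.config.age_cutoff_years,
                "variant": r.config.embedding_variant,
                "role": r.config.speaker_role.value,
                "train_source": r.config.train_source,
                "test_set": r.test_set_name,
                "micro_f1": r.micro_f1,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "n_test_sets": r.n_test_sets,
            }
            for r in results
        ]
    )
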