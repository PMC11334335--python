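#!/usr/bin/env python
"""Blank-slate moral inference: the 48-model grid and random controls.

Trains logistic-regression models on averaged static embeddings of the
labelled seed-matched utterances (6 cumulative age cutoffs x 4 embedding
variants x 2 speaker roles) and evaluates each on ten balanced
out-of-domain test sets per task.  Random controls retrain on same-size
seedless samples with random labels.  Results mirror a train-source x
embedding-variant score table.
"""

import json
from pathlib import Path

import pandas as pd

from morallex import generalization as G
from morallex.corpus_io import read_jsonl
from morallex.embeddings import HashEmbeddingTable, train_static
from morallex.types import AggregatedLabel

SIM = Path(__file__).resolve().parent.parent / "results" / "simdata"
OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def load(path):
    labels, seeded = {}, set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            labels[rec["utterance_id"]] = (
                AggregatedLabel("moral", rec["foundation"])
                if rec["relevance"] == "moral"
                else AggregatedLabel("nonmoral")
            )
            if rec["seeded"]:
                seeded.add(rec["utterance_id"])
    return labels, seeded


def read_pool(name):
    with open(SIM / f"test_{name}.jsonl", encoding="utf-8") as fh:
        return [
            (rec["text"], rec["label"])
            for rec in (json.loads(line) for line in fh)
        ]


def main() -> None:
    utterances = read_jsonl(SIM / "utterances.jsonl")
    labels, seeded = load(OUT / "labels.jsonl")
    train_labels = {u: l for u, l in labels.items() if u in seeded}

    sents = [list(u.tokens) for u in utterances]
    tables = {
        "static_pretrained_a": HashEmbeddingTable(100, "pre-a"),
        "static_pretrained_b": HashEmbeddingTable(100, "pre-b"),
        "static_corpus_a": train_static(sents, "skipgram", 32, seed=SEED, epochs=3),
        "static_corpus_b": train_static(sents, "glove_style", 32, seed=SEED),
    }
    test_sets = {
        "binary_relevance": G.balanced_eval(read_pool("short_binary"), 10, seed=SEED, cap=40),
        "fine_10class": G.balanced_eval(read_pool("short_10class"), 10, seed=SEED + 1, cap=20),
        "fine_5class": G.balanced_eval(read_pool("long_5class"), 10, seed=SEED + 2, cap=15),
    }

    results = G.run_grid(utterances, train_labels, tables, test_sets, seed=SEED)
    df = G.results_frame(results)
    df.to_csv(OUT / "grid_results.csv", index=False)
    print(f"trained {len(df[df.task == 'binary_relevance'])} models per task")

    control_pool = [u for u in utterances if u.utterance_id not in seeded]
    controls = G.run_grid(
        utterances, train_labels, tables, test_sets,
        train_source="random_control", control_pool=control_pool,
        n_control=20, seed=SEED, age_cutoffs=[6],
    )
    dfc = G.results_frame(controls)
    dfc.to_csv(OUT / "grid_controls.csv", index=False)

    print("\nmean micro-F1 by task and variant (moral vs random-control):")
    moral = df.groupby(["task", "variant"]).micro_f1.mean().round(3)
    rand = dfc.groupby(["task", "variant"]).micro_f1.mean().round(3)
    summary = pd.DataFrame({"moral": moral, "random": rand})
    print(summary.to_string())
    summary.to_csv(OUT / "grid_summary.csv")

    chance = {"binary_relevance": 0.5, "fine_10class": 0.1, "fine_5class": 0.2}
    for task, level in chance.items():
        m = df[df.task == task].micro_f1.mean()
        r = dfc[dfc.task == task].micro_f1.mean()
        print(f"{task}: moral {m:.3f} vs control {r:.3f} (chance {level})")
    print(f"wrote grid_results.csv, grid_controls.csv, grid_summary.csv to {OUT}")


if __name__ == "__main__":
    main()
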