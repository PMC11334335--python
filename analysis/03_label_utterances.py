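#!/usr/bin/env python
"""Disambiguate and label every utterance.

Clusters the seed-matched utterances per foundation-polarity x role cell
(PCA to 95% variance, Gaussian mixtures with silhouette-selected k),
selects prototype/peripheral sentences, simulates the annotation survey,
aggregates utterance- and cluster-level labels under the 75%/50% rules,
and propagates labels to the rest of the corpus (cluster + 2-NN for
seeded utterances, 3-NN for the rest).  Writes labels and diagnostics.
"""

import json
from pathlib import Path

import pandas as pd

from morallex.corpus_io import read_jsonl
from morallex.pipeline import label_corpus
from morallex.synthetic_data import GeneratorConfig, GroundTruthManifest

SIM = Path(__file__).resolve().parent.parent / "results" / "simdata"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    utterances = read_jsonl(SIM / "utterances.jsonl")
    manifest = GroundTruthManifest.load(SIM / "manifest.json")
    sim_config = json.loads((SIM / "config.json").read_text())
    initial = (
        pd.read_csv(OUT / "initial_categories.csv")
        .set_index("utterance_id")["initial_category"]
        .to_dict()
    )
    config = GeneratorConfig(
        seed=sim_config["seed"],
        sentences_per_age_role=sim_config["sentences_per_age_role"],
    )

    study = label_corpus(utterances, initial, manifest, config)

    print(f"fitted {len(study.cells)} cell models, "
          f"{sum(len(r.summaries) for r in study.cells.values())} clusters, "
          f"{len(study.surveyed)} sentences sent to the survey")
    kept = {r.annotator_id for r in study.records if r.passed_attention}
    print(f"simulated {len({r.annotator_id for r in study.records})} annotators, "
          f"{len(kept)} passed the attention check")

    rel = sum(a[0] for a in study.agreement.values()) / len(study.agreement)
    fnd = sum(a[1] for a in study.agreement.values()) / len(study.agreement)
    print(f"cluster agreement ratios: relevance {rel:.2f}, foundation {fnd:.2f}")

    # accuracy against the ground truth (available here because the corpus
    # is synthetic; a real study has no such column)
    ok = tot = 0
    for uid in initial:
        lab = study.labels.get(uid)
        if lab is None:
            continue
        g = manifest[uid]
        tot += 1
        ok += (lab.relevance == g.true_relevance) and (lab.foundation == g.true_category)
    print(f"seed-matched label accuracy vs ground truth: {ok / tot:.3f} ({tot} utterances)")

    n_moral = sum(l.is_moral for l in study.labels.values())
    print(f"final labels: {n_moral} moral of {len(study.labels)}")

    with open(OUT / "labels.jsonl", "w", encoding="utf-8") as fh:
        for uid, lab in study.labels.items():
            fh.write(
                json.dumps(
                    {
                        "utterance_id": uid,
                        "relevance": lab.relevance,
                        "foundation": lab.foundation,
                        "provenance": lab.provenance,
                        "seeded": uid in initial,
                    }
                )
                + "\n"
            )
    rows = []
    for (cell, idx), clab in study.cluster_labels.items():
        rel_a, fnd_a = study.agreement.get((cell, idx), (float("nan"),) * 2)
        rows.append(
            {
                "category": cell[0],
                "role": cell[1].value,
                "cluster": idx,
                "k": study.cells[cell].model.k,
                "silhouette": study.cells[cell].model.silhouette,
                "label_relevance": clab.relevance,
                "label_foundation": clab.foundation,
                "agreement_relevance": rel_a,
                "agreement_foundation": fnd_a,
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "clusters.csv", index=False)
    print(f"wrote labels.jsonl and clusters.csv to {OUT}")


if __name__ == "__main__":
    main()
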