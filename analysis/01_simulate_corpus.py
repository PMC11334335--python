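#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emits an age-structured child/caretaker corpus (CHAT files and the JSONL
dialect), the toy ten-category moral lexicon (.dic), the ground-truth
manifest, and the out-of-domain labelled test pools, all under
results/simdata/.  Everything downstream reads these files.
"""

import json
from collections import Counter
from pathlib import Path

from morallex.corpus_io import write_jsonl, write_lexicon
from morallex.synthetic_data import (
    GeneratorConfig,
    default_lexicon,
    generate_corpus,
    generate_external_tests,
    write_chat,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=SEED)  # default study conditions
    utterances, manifest = generate_corpus(config)

    write_chat(utterances, OUT / "chat")
    write_jsonl(utterances, OUT / "utterances.jsonl")
    write_lexicon(default_lexicon(), OUT / "mfd_toy.dic")
    manifest.save(OUT / "manifest.json")
    (OUT / "config.json").write_text(
        json.dumps({"seed": SEED, "sentences_per_age_role": config.sentences_per_age_role}, indent=2)
    )

    pools = generate_external_tests(config, n_per_class_short=40, n_per_class_long=30)
    for name, pool in pools.items():
        with open(OUT / f"test_{name}.jsonl", "w", encoding="utf-8") as fh:
            for text, label in pool:
                fh.write(json.dumps({"text": text, "label": label}) + "\n")

    n_moral = len(manifest.moral_ids())
    by_role = Counter(u.speaker_role.value for u in utterances)
    print(f"wrote {len(utterances)} utterances "
          f"({by_role['child']} CS / {by_role['caretaker']} CDS) to {OUT}")
    print(f"ground truth: {n_moral} moral utterances "
          f"({n_moral / len(utterances):.1%} of the corpus)")
    amb = sum(g.is_ambiguous_sense for g in manifest.entries.values())
    print(f"{amb} nonmoral uses of polysemous seed words planted")
    for name, pool in pools.items():
        print(f"test pool {name}: {len(pool)} documents")


if __name__ == "__main__":
    main()
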