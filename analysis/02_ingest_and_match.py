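#!/usr/bin/env python
"""Ingest the corpus and match the moral seed lexicon.

Parses the CHAT files written by 01 as a format round-trip check, then
matches the .dic lexicon (exact lemmas, prefix stems) on the JSONL
corpus whose utterance ids align with the ground-truth manifest.  The
1-6 year age window applies.  Writes the seed-match table with each
utterance's initial (dictionary-assigned) foundation-polarity category.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from morallex.corpus_io import (
    initial_foundation,
    load_lexicon,
    match_seeds,
    read_chat_corpus,
    read_jsonl,
)

SIM = Path(__file__).resolve().parent.parent / "results" / "simdata"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    stats: dict[str, int] = {}
    from_chat = read_chat_corpus(SIM / "chat", exclude_corpora=["Hall"], stats=stats)
    utterances = read_jsonl(SIM / "utterances.jsonl")
    assert len(from_chat) == len(utterances), "CHAT round trip lost utterances"
    print(f"parsed {len(from_chat)} utterances from CHAT "
          f"(skipped: {stats or 'none'}); JSONL corpus matches")

    lexicon = load_lexicon(SIM / "mfd_toy.dic")
    print(f"lexicon: {len(lexicon)} patterns, "
          f"{sum(e.is_stem for e in lexicon)} stems")

    matches = match_seeds(utterances, lexicon)
    initial = initial_foundation(matches)
    print(f"{len(matches)} seed matches in {len(initial)} utterances "
          f"({len(initial) / len(utterances):.1%} of the corpus)")

    by_cat = Counter(m.entry.category for m in matches)
    for cat, n in by_cat.most_common():
        print(f"  {cat:<18} {n}")

    pd.DataFrame(
        [
            {
                "utterance_id": m.utterance_id,
                "token": m.matched_token,
                "pattern": m.entry.pattern,
                "category": m.entry.category,
            }
            for m in matches
        ]
    ).to_csv(OUT / "seed_matches.csv", index=False)
    pd.Series(initial, name="initial_category").rename_axis("utterance_id").to_csv(
        OUT / "initial_categories.csv"
    )
    print(f"wrote seed_matches.csv and initial_categories.csv to {OUT}")


if __name__ == "__main__":
    main()
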