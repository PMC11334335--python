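"""Deterministic rule/table lemmatizer.

The preprocessing contract only needs a function ``str -> str`` mapping a
lowercase token to its lemma.  The default backend below combines a table
of irregular forms with conservative suffix rules; it is fully
deterministic, so preprocessed token lists are reproducible across runs
and machines.  A different backend (e.g. a full NLP pipeline) can be
plugged in wherever a ``lemmatizer`` argument is accepted.
"""

from __future__ import annotations

from typing import Callable

Lemmatizer = Callable[[str], str]

# Irregulars and high-frequency function words that suffix rules would
# mangle.  Function words map to themselves.
_IRREGULAR = {
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose", "people": "person",
    "went": "go", "gone": "go", "goes": "go", "going": "go",
    "was": "be", "were": "be", "is": "be", "are": "be", "am": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "did": "do", "does": "do", "done": "do", "doing": "do",
    "said": "say", "says": "say", "saying": "say",
    "made": "make", "making": "make",
    "got": "get", "gotten": "get", "getting": "get",
    "took": "take", "taken": "take", "taking": "take",
    "gave": "give", "given": "give", "giving": "give",
    "came": "come", "coming": "come",
    "saw": "see", "seen": "see", "seeing": "see",
    "told": "tell", "felt": "feel", "kept": "keep", "left": "leave",
    "stole": "steal", "stolen": "steal", "fought": "fight",
    "hurting": "hurt", "hitting": "hit", "ran": "run", "running": "run",
    "lying": "lie", "lied": "lie", "cried": "cry", "crying": "cry",
}

# Words ending in s that are not plurals / 3sg verbs.
_S_EXCEPTIONS = {
    "this", "his", "hers", "its", "yours", "ours", "theirs", "us",
    "as", "is", "was", "has", "yes", "thus", "always", "perhaps",
    "less", "unless", "plus", "bus", "gas",
}

_VOWELS = set("aeiou")


def _strip_ed_ing(token: str, suffix: str) -> str | None:
    stem = token[: -len(suffix)]
    if len(stem) < 2:
        return None
    # doubled final consonant: "hugged" -> "hug", "sitting" -> "sit"
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
        return stem[:-1]
    # consonant + e elision: "cared" -> "care", "making" handled by table;
    # restore "e" when the stem ends consonant+consonant? keep simple:
    # "bark" + ed -> "bark"; "rescue" + ed -> "rescued" strips to "rescu",
    # so restore the e after u/v or soft endings.
    if stem[-1] in {"u", "v"} or stem.endswith(("at", "it", "iz", "is")):
        return stem + "e"
    return stem


def rule_lemma(token: str) -> str:
    """Map one lowercase token to a lemma (identity when unsure)."""
    if not token:
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if "'" in token:  # contractions (it's, don't) stay attached, unchanged
        return token
    if token in _S_EXCEPTIONS:
        return token
    n = len(token)
    if token.endswith("ies") and n > 4:
        return token[:-3] + "y"
    if token.endswith(("ches", "shes", "xes", "zes", "sses")) and n > 4:
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")) and n > 3:
        return token[:-1]
    if token.endswith("ied") and n > 4:
        return token[:-3] + "y"
    if token.endswith("ed") and n > 4:
        out = _strip_ed_ing(token, "ed")
        if out:
            return out
    if token.endswith("ing") and n > 5:
        out = _strip_ed_ing(token, "ing")
        if out:
            return out
    return token


def table_lemmatizer(table: dict[str, str]) -> Lemmatizer:
    """A lemmatizer that only applies an explicit lookup table.

    Used in tests to pin outputs independent of the rule backend.
    """

    def _lemma(token: str) -> str:
        return table.get(token, token)

    return _lemma
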