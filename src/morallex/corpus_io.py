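"""Reading conversational corpora and the moral lexicon.

Supports two transcript formats:

* CHAT (``.cha``), the TalkBank/CHILDES transcript standard.  Only main
  speaker tiers (``*CHI:`` etc.) are parsed; dependent tiers (``%mor``,
  ``%gra``) and header lines are metadata.  The target child's age is
  read from the ``@ID`` header (``y;m.d`` notation) and converted to
  months.
* a JSONL dialect with one utterance object per line
  (``{id, text, role, age_months, gender, corpus, tokens}``).

The moral lexicon is a LIWC-style ``.dic`` file following the MFD 2.0
schema: a ``%``-delimited header block mapping numeric category ids to
the ten foundation-polarity categories, then one pattern per line with
its category ids.  A trailing ``*`` on a pattern gives it prefix (stem)
semantics.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .lemmatize import Lemmatizer, rule_lemma
from .types import (
    Foundation,
    LexiconEntry,
    Polarity,
    SeedMatch,
    SpeakerRole,
    Utterance,
)

logger = logging.getLogger(__name__)

_SENT_SPLIT = re.compile(r"[.!?]+")
# keep letters, digits and word-internal apostrophes ("n't" stays attached)
_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'"})


def normalize_apostrophes(text: str) -> str:
    return text.translate(_APOSTROPHES)


def split_sentences(text: str) -> list[str]:
    """Split raw text on terminal punctuation; drop empty pieces."""
    return [s.strip() for s in _SENT_SPLIT.split(text) if s.strip()]


def tokenize_sentence(sentence: str, lemmatizer: Lemmatizer = rule_lemma) -> list[str]:
    """Lowercase, strip punctuation, lemmatize one sentence."""
    cleaned = _PUNCT.sub(" ", normalize_apostrophes(sentence).lower())
    tokens = []
    for raw in cleaned.split():
        tok = raw.strip("'")
        if tok:
            tokens.append(lemmatizer(tok))
    return tokens


def preprocess(text: str, lemmatizer: Lemmatizer = rule_lemma) -> list[list[str]]:
    """Raw text -> list of sentence token lists (lowercased lemmas).

    Empty sentences are dropped; an empty or punctuation-only input
    yields an empty list.
    """
    out = []
    for sentence in split_sentences(text):
        tokens = tokenize_sentence(sentence, lemmatizer)
        if tokens:
            out.append(tokens)
    return out


# ---------------------------------------------------------------------------
# CHAT parsing
# ---------------------------------------------------------------------------

_AGE_RE = re.compile(r"^(\d+);(\d+)(?:\.(\d+))?")

# CHAT inline codes stripped before sentence splitting
_CHAT_NOISE = [
    re.compile(r"\[[^\]]*\]"),   # [...] event/retrace codes
    re.compile(r"&=?\S+"),        # &=laughs, &uh fillers
    re.compile(r"\+[<,.!?/^\"]*"),  # +... continuation markers
    re.compile(r"[<>]"),          # angle brackets (keep enclosed words)
    re.compile(r"\b(?:xxx|yyy|www)\b"),  # unintelligible
]


def parse_chat_age(age_field: str) -> Optional[int]:
    """CHAT age string ``y;m.d`` -> whole months, or None if absent."""
    m = _AGE_RE.match(age_field.strip())
    if not m:
        return None
    years, months = int(m.group(1)), int(m.group(2))
    return years * 12 + months


def _clean_chat_text(text: str) -> str:
    for pat in _CHAT_NOISE:
        text = pat.sub(" ", text)
    return text


class ChatParseError(ValueError):
    pass


def _read_logical_lines(path: Path) -> list[tuple[int, str]]:
    """Join tab-continuation lines; return (first line number, text)."""
    logical: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("\t", " ")) and logical:
                n0, prev = logical[-1]
                logical[-1] = (n0, prev + " " + line.strip())
            else:
                logical.append((lineno, line))
    return logical


def read_chat_file(
    path: str | Path,
    role_map: Optional[dict[str, SpeakerRole]] = None,
    lemmatizer: Lemmatizer = rule_lemma,
    corpus_name: Optional[str] = None,
    stats: Optional[dict[str, int]] = None,
) -> list[Utterance]:
    """Parse one ``.cha`` file into utterances (one per sentence).

    ``role_map`` maps participant codes to roles; by default ``CHI`` is
    the child and every other declared participant is a caretaker.
    Utterances from undeclared tiers are skipped with a warning, and
    utterances without a recorded child age are dropped and counted in
    ``stats['no_age']``.
    """
    path = Path(path)
    stats = stats if stats is not None else {}
    participants: dict[str, str] = {}
    age_months: Optional[int] = None
    gender = "unknown"
    corpus = corpus_name or ""
    utterances: list[Utterance] = []
    counter = 0

    for lineno, line in _read_logical_lines(path):
        if line.startswith("@"):
            if line.startswith("@Participants:"):
                body = line.split(":", 1)[1]
                for part in body.split(","):
                    fields = part.split()
                    if fields:
                        participants[fields[0]] = (
                            fields[-1] if len(fields) > 1 else fields[0]
                        )
            elif line.startswith("@ID:"):
                fields = line.split(":", 1)[1].strip().split("|")
                if len(fields) < 5:
                    raise ChatParseError(
                        f"{path}:{lineno}: malformed @ID header"
                    )
                if not corpus:
                    corpus = fields[1]
                if fields[2] == "CHI":
                    age_months = parse_chat_age(fields[3])
                    if fields[4] in ("female", "male"):
                        gender = fields[4]
            continue
        if line.startswith("%"):
            continue  # dependent tiers ignored
        if line.startswith("*"):
            if ":" not in line:
                raise ChatParseError(f"{path}:{lineno}: malformed main tier")
            tier, text = line[1:].split(":", 1)
            tier = tier.strip()
            if role_map is not None:
                role = role_map.get(tier)
            elif tier == "CHI":
                role = SpeakerRole.CHILD
            elif tier in participants:
                role = SpeakerRole.CARETAKER
            else:
                role = None
            if role is None:
                logger.warning("%s:%d: unknown tier %s, skipped", path, lineno, tier)
                stats["unknown_tier"] = stats.get("unknown_tier", 0) + 1
                continue
            if age_months is None:
                stats["no_age"] = stats.get("no_age", 0) + 1
                continue
            cleaned = _clean_chat_text(text)
            for sent in split_sentences(cleaned):
                tokens = tokenize_sentence(sent, lemmatizer)
                if not tokens:
                    continue
                counter += 1
                utterances.append(
                    Utterance(
                        utterance_id=f"{path.stem}:{lineno}:{counter}",
                        text=sent,
                        tokens=tuple(tokens),
                        speaker_role=role,
                        child_age_months=age_months,
                        child_gender=gender,
                        corpus_name=corpus or path.stem,
                    )
                )
            continue
        raise ChatParseError(f"{path}:{lineno}: unrecognized line {line[:40]!r}")

    return utterances


def read_chat_corpus(
    path: str | Path,
    role_map: Optional[dict[str, SpeakerRole]] = None,
    exclude_corpora: Sequence[str] = (),
    lemmatizer: Lemmatizer = rule_lemma,
    stats: Optional[dict[str, int]] = None,
) -> list[Utterance]:
    """Read a ``.cha`` file or a directory of them.

    ``exclude_corpora`` drops whole sub-corpora by name (the analysis
    excludes the Hall corpus, which was collected under controlled
    demographic conditions).
    """
    path = Path(path)
    stats = stats if stats is not None else {}
    files = sorted(path.rglob("*.cha")) if path.is_dir() else [path]
    excluded = {name.lower() for name in exclude_corpora}
    out: list[Utterance] = []
    for f in files:
        for utt in read_chat_file(f, role_map, lemmatizer, stats=stats):
            if utt.corpus_name.lower() in excluded:
                stats["excluded_corpus"] = stats.get("excluded_corpus", 0) + 1
                continue
            out.append(utt)
    return out


# ---------------------------------------------------------------------------
# JSONL dialect
# ---------------------------------------------------------------------------

def write_jsonl(utterances: Iterable[Utterance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in utterances:
            fh.write(
                json.dumps(
                    {
                        "id": u.utterance_id,
                        "text": u.text,
                        "tokens": list(u.tokens),
                        "role": u.speaker_role.value,
                        "age_months": u.child_age_months,
                        "gender": u.child_gender,
                        "corpus": u.corpus_name,
                    }
                )
                + "\n"
            )


def read_jsonl(
    path: str | Path, lemmatizer: Lemmatizer = rule_lemma
) -> list[Utterance]:
    """Read the JSONL dialect; missing ``tokens`` are recomputed."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as err:
                raise ChatParseError(f"{path}:{lineno}: bad JSON ({err})") from err
            tokens = rec.get("tokens")
            if tokens is None:
                sents = preprocess(rec["text"], lemmatizer)
                tokens = [t for s in sents for t in s]
            out.append(
                Utterance(
                    utterance_id=str(rec["id"]),
                    text=rec["text"],
                    tokens=tuple(tokens),
                    speaker_role=SpeakerRole(rec["role"]),
                    child_age_months=int(rec["age_months"]),
                    child_gender=rec.get("gender", "unknown"),
                    corpus_name=rec.get("corpus", ""),
                )
            )
    return out


# ---------------------------------------------------------------------------
# LIWC-style .dic lexicon
# ---------------------------------------------------------------------------

def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Parse a LIWC-style ``.dic`` file into lexicon entries.

    Layout: a header block delimited by lines containing only ``%``,
    with ``<id>\\t<category>`` rows naming the ten foundation-polarity
    categories (``care.virtue`` ... ``purity.vice``); then one
    ``<pattern>\\t<id> [<id> ...]`` row per word.  Unknown category ids
    are a hard error; duplicate (pattern, category) rows collapse to one
    entry with a warning.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    # locate header block
    seps = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(seps) < 2:
        raise ValueError(f"{path}: missing %% header delimiters")
    header = lines[seps[0] + 1 : seps[1]]
    body = lines[seps[1] + 1 :]

    cat_by_id: dict[str, tuple[Foundation, Polarity]] = {}
    for ln in header:
        if not ln.strip():
            continue
        fields = ln.split()
        if len(fields) != 2:
            raise ValueError(f"{path}: malformed category line {ln!r}")
        cid, name = fields
        name = name.strip().lower()
        try:
            f_name, p_name = name.split(".")
            cat_by_id[cid] = (Foundation(f_name), Polarity(p_name))
        except ValueError as err:
            raise ValueError(f"{path}: unknown category name {name!r}") from err
    if not cat_by_id:
        raise ValueError(f"{path}: empty category block")

    entries: list[LexiconEntry] = []
    seen: set[tuple[str, bool, Foundation, Polarity]] = set()
    for ln in body:
        if not ln.strip():
            continue
        fields = ln.split()
        pattern, ids = fields[0].lower(), fields[1:]
        if not ids:
            raise ValueError(f"{path}: pattern {pattern!r} has no category")
        is_stem = pattern.endswith("*")
        if is_stem:
            pattern = pattern[:-1]
        for cid in ids:
            if cid not in cat_by_id:
                raise ValueError(
                    f"{path}: pattern {fields[0]!r} uses unknown category id {cid!r}"
                )
            foundation, polarity = cat_by_id[cid]
            key = (pattern, is_stem, foundation, polarity)
            if key in seen:
                logger.warning("%s: duplicate lexicon line %r", path, ln)
                continue
            seen.add(key)
            entries.append(LexiconEntry(pattern, is_stem, foundation, polarity))
    return entries


def write_lexicon(entries: Sequence[LexiconEntry], path: str | Path) -> None:
    """Write entries back to the .dic layout (ten fixed category ids)."""
    from .types import CATEGORIES

    cat_ids = {cat: str(i + 1) for i, cat in enumerate(CATEGORIES)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for cat, cid in cat_ids.items():
            fh.write(f"{cid}\t{cat}\n")
        fh.write("%\n")
        for e in entries:
            pat = e.pattern + ("*" if e.is_stem else "")
            fh.write(f"{pat}\t{cat_ids[e.category]}\n")


# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------

def match_seeds(
    utterances: Sequence[Utterance],
    lexicon: Sequence[LexiconEntry],
    min_age_years: int = 1,
    max_age_years: int = 6,
) -> list[SeedMatch]:
    """Find lexicon hits in preprocessed utterances.

    Non-stem patterns require exact lemma equality; stem patterns match
    by prefix.  Only utterances whose child age (in whole years) falls in
    ``[min_age_years, max_age_years]`` are scanned.  One match is
    reported per distinct (utterance, token, entry) triple.
    """
    exact: dict[str, list[LexiconEntry]] = {}
    stems: list[LexiconEntry] = []
    for e in lexicon:
        if e.is_stem:
            stems.append(e)
        else:
            exact.setdefault(e.pattern, []).append(e)

    matches: list[SeedMatch] = []
    for utt in utterances:
        age = utt.age_years
        if age < min_age_years or age > max_age_years:
            continue
        seen: set[tuple[str, LexiconEntry]] = set()
        for tok in utt.tokens:
            for e in exact.get(tok, ()):
                if (tok, e) not in seen:
                    seen.add((tok, e))
                    matches.append(SeedMatch(utt.utterance_id, tok, e))
            for e in stems:
                if tok.startswith(e.pattern) and (tok, e) not in seen:
                    seen.add((tok, e))
                    matches.append(SeedMatch(utt.utterance_id, tok, e))
    return matches


def initial_foundation(
    matches: Sequence[SeedMatch],
) -> dict[str, str]:
    """Per-utterance initial category from its seed matches.

    When an utterance hits several categories, the category of its first
    match (token order, then lexicon order) is used; ties are inherent to
    polysemous dictionaries and the survey stage overrides them anyway.
    """
    out: dict[str, str] = {}
    for m in matches:
        out.setdefault(m.utterance_id, m.entry.category)
    return out
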