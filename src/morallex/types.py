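"""Core domain types shared across the pipeline.

Moral Foundations Theory posits five foundations -- Care, Fairness,
Loyalty, Authority, Purity -- each with a virtue (positive) and a vice
(negative) polarity, giving ten foundation-polarity categories.  A
category is written ``"care.virtue"``, ``"fairness.vice"`` etc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Foundation(str, Enum):
    CARE = "care"
    FAIRNESS = "fairness"
    LOYALTY = "loyalty"
    AUTHORITY = "authority"
    PURITY = "purity"


class Polarity(str, Enum):
    VIRTUE = "virtue"
    VICE = "vice"


class SpeakerRole(str, Enum):
    CHILD = "child"
    CARETAKER = "caretaker"


FOUNDATIONS: tuple[Foundation, ...] = tuple(Foundation)
POLARITIES: tuple[Polarity, ...] = tuple(Polarity)

#: The ten foundation-polarity categories, e.g. "care.virtue".
CATEGORIES: tuple[str, ...] = tuple(
    f"{f.value}.{p.value}" for f in FOUNDATIONS for p in POLARITIES
)

#: Common vice aliases used in the literature (Harm = care.vice, etc.).
VICE_NAMES = {
    Foundation.CARE: "harm",
    Foundation.FAIRNESS: "cheating",
    Foundation.LOYALTY: "betrayal",
    Foundation.AUTHORITY: "subversion",
    Foundation.PURITY: "degradation",
}


def category(foundation: Foundation, polarity: Polarity) -> str:
    return f"{foundation.value}.{polarity.value}"


def split_category(cat: str) -> tuple[Foundation, Polarity]:
    f, p = cat.split(".")
    return Foundation(f), Polarity(p)


@dataclass(frozen=True)
class Utterance:
    """One transcribed sentence with speaker and child metadata.

    ``child_age_months`` is the age of the target child at recording
    time; the analysis bins it as integer years ``floor(months / 12)``.
    """

    utterance_id: str
    text: str
    tokens: tuple[str, ...]
    speaker_role: SpeakerRole
    child_age_months: int
    child_gender: str = "unknown"  # "female" | "male" | "unknown"
    corpus_name: str = ""

    def __post_init__(self) -> None:
        if self.child_age_months < 0:
            raise ValueError(
                f"negative age for utterance {self.utterance_id!r}"
            )

    @property
    def age_years(self) -> int:
        return self.child_age_months // 12


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary pattern mapped to a foundation-polarity category.

    ``is_stem`` entries (written ``help*`` in the .dic file) match any
    token of which ``pattern`` is a prefix; plain entries require exact
    lemma equality.
    """

    pattern: str
    is_stem: bool
    foundation: Foundation
    polarity: Polarity

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty lexicon pattern")

    @property
    def category(self) -> str:
        return category(self.foundation, self.polarity)

    def matches(self, token: str) -> bool:
        if self.is_stem:
            return token.startswith(self.pattern)
        return token == self.pattern


@dataclass(frozen=True)
class SeedMatch:
    utterance_id: str
    matched_token: str
    entry: LexiconEntry


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotator's response for one utterance."""

    utterance_id: str
    annotator_id: str
    says_moral: bool
    foundations: tuple[str, ...] = ()  # categories; empty iff not moral
    passed_attention: bool = True

    def __post_init__(self) -> None:
        if self.foundations and not self.says_moral:
            raise ValueError("foundations set on a non-moral record")
        for cat in self.foundations:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")


@dataclass(frozen=True)
class AggregatedLabel:
    """Moral-relevance + foundation verdict for an utterance or cluster."""

    relevance: str  # "moral" | "nonmoral"
    foundation: Optional[str] = None  # category, set iff moral
    provenance: str = "unanimous_rule"
    # free-form audit notes (tie-breaks taken, neighbour ids, ...)
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.relevance == "moral" and self.foundation is None:
            raise ValueError("moral label requires a foundation")
        if self.relevance == "nonmoral" and self.foundation is not None:
            raise ValueError("nonmoral label must not carry a foundation")

    @property
    def is_moral(self) -> bool:
        return self.relevance == "moral"
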