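"""Keyword/synonym search over clinical free text with polarity filtering.

The cohort definition needs documented evidence of hepatic steatosis in
imaging, pathology, or clinical notes; the same machinery is reused to
find cirrhosis mentions, death mentions, and MELD severity scores.  The
approach is a deterministic NegEx-style scan, not machine-learned NER:

* every case-insensitive occurrence of a lexicon term is a mention;
* a negation cue (``no``, ``not``, ``absence of``, ``without``,
  ``negative for``, ``denies``, ``free of``) within a 6-token window
  before the term marks the mention negated;
* a kinship noun in the same sentence (period/newline-bounded) marks it
  family_or_false_positive;
* everything else is positive.

Each raw occurrence receives exactly one polarity, so polarity counts
partition the raw match count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

NEGATION_CUES = (
    "no",
    "not",
    "absence of",
    "without",
    "negative for",
    "denies",
    "free of",
)
FAMILY_CUES = (
    "mother",
    "father",
    "brother",
    "sister",
    "aunt",
    "uncle",
    "grandmother",
    "grandfather",
    "family history",
    "family",
)
NEGATION_WINDOW_TOKENS = 6

STEATOSIS_TERMS = (
    "steatosis",
    "steatohepatitis",
    "fatty liver",
    "hepatic steatosis",
    "nash",
    "nafld",
)
CIRRHOSIS_TERMS = ("cirrhosis", "cirrhotic")
DEATH_TERMS = ("deceased", "expired", "passed away", "death")


@dataclass(frozen=True)
class SynonymLexicon:
    """A named concept with its case-insensitive surface forms."""

    concept: str
    terms: tuple

    def __post_init__(self):
        folded = [t.lower() for t in self.terms]
        if not folded:
            raise ValueError(f"lexicon {self.concept!r} has no terms")
        if len(set(folded)) != len(folded):
            raise ValueError(f"lexicon {self.concept!r} has duplicate terms after case-folding")

    def pattern(self) -> re.Pattern:
        # longest-first alternation so 'hepatic steatosis' is not also
        # counted as an inner 'steatosis' match
        alts = sorted((re.escape(t) for t in self.terms), key=len, reverse=True)
        return re.compile(r"\b(?:%s)\b" % "|".join(alts), re.IGNORECASE)


STEATOSIS_LEXICON = SynonymLexicon("hepatic_steatosis", STEATOSIS_TERMS)
CIRRHOSIS_LEXICON = SynonymLexicon("cirrhosis", CIRRHOSIS_TERMS)
DEATH_LEXICON = SynonymLexicon("death", DEATH_TERMS)


@dataclass(frozen=True)
class MentionResult:
    concept: str
    term: str
    start: int
    end: int
    polarity: str  # positive | negated | family_or_false_positive
    patient_id: str | None = None
    doc_date: date | None = None


_TOKEN = re.compile(r"[A-Za-z0-9']+")


def _sentence_bounds(text: str, pos: int) -> tuple:
    start = max(text.rfind(".", 0, pos), text.rfind("\n", 0, pos)) + 1
    stop_candidates = [i for i in (text.find(".", pos), text.find("\n", pos)) if i != -1]
    stop = min(stop_candidates) if stop_candidates else len(text)
    return start, stop


def _classify(text: str, start: int, stop_sentence: tuple) -> str:
    sent_start, sent_stop = stop_sentence
    sentence = text[sent_start:sent_stop].lower()
    for cue in FAMILY_CUES:
        if re.search(r"\b%s\b" % re.escape(cue), sentence):
            return "family_or_false_positive"
    before = text[sent_start:start].lower()
    tokens = _TOKEN.findall(before)
    window = " ".join(tokens[-NEGATION_WINDOW_TOKENS:])
    for cue in NEGATION_CUES:
        if re.search(r"\b%s\b" % re.escape(cue), window):
            return "negated"
    return "positive"


def find_mentions(text: str, lexicon: SynonymLexicon, patient_id=None, doc_date=None) -> list:
    """All lexicon-term occurrences in ``text``, each with one polarity."""
    results = []
    for m in lexicon.pattern().finditer(text):
        bounds = _sentence_bounds(text, m.start())
        polarity = _classify(text, m.start(), bounds)
        results.append(
            MentionResult(
                concept=lexicon.concept,
                term=m.group(0),
                start=m.start(),
                end=m.end(),
                polarity=polarity,
                patient_id=patient_id,
                doc_date=doc_date,
            )
        )
    return results


def patient_has_concept(documents, lexicon: SynonymLexicon) -> tuple:
    """(has positive mention?, earliest positive-mention document date).

    ``documents`` is an iterable of (date, text) pairs for one patient.
    """
    earliest = None
    for doc_date, text in documents:
        for m in find_mentions(text, lexicon, doc_date=doc_date):
            if m.polarity == "positive":
                if earliest is None or doc_date < earliest:
                    earliest = doc_date
    return (earliest is not None), earliest


def detect_death_mention(documents) -> tuple:
    """Death-mention scan over a patient's documents; see patient_has_concept."""
    return patient_has_concept(documents, DEATH_LEXICON)


_MELD_RE = re.compile(
    r"\bmeld\b(?:[\s:=-]|score|of|is|was)*?(\d{1,3})", re.IGNORECASE
)


def extract_meld(text: str) -> int | None:
    """First plausible MELD score (integer 6..40) following the token MELD."""
    for m in _MELD_RE.finditer(text):
        value = int(m.group(1))
        if 6 <= value <= 40:
            return value
    return None
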