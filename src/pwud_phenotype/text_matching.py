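"""Misspelling-tolerant keyword detection over clinical note text.

This implements the NLP criterion (flag N): a lexicon of drug-use keywords
and phrases is matched against each note of an encounter at the token
level, tolerating small typographical errors via the optimal-string-
alignment (OSA) Damerau–Levenshtein distance — unit-cost substitutions,
insertions, deletions, and adjacent transpositions, the dominant clinical
typo classes ("herion" for "heroin").

Design choices, all surfaced in :class:`MatcherConfig`:

* case-insensitive by default (the lexicon mixes "FENTANYL" and "heroin");
* fuzzy matching only for entries whose longest token has at least 5
  characters — fuzzy matching of 3–4-letter acronyms (SUD, OUD, IVDU)
  floods false positives, so those match exactly and only as standalone
  tokens ("SUD" never fires inside "sudden");
* phrases ("injection drug use") match consecutive token runs, each word
  matched under the same per-word rule, with any whitespace/punctuation
  as separator;
* presence detection only — negation ("denies IVDU") is out of scope.

Every match is returned as a :class:`MatchSpan` with character offsets
into the original text, so evidence can be audited and re-extracted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .types import Encounter, Note

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

DEFAULT_LEXICON_VERSION = "textbox-1"


def dl_distance(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau–Levenshtein distance.

    Unit cost for substitution, insertion, deletion, and transposition of
    two adjacent characters; under OSA no substring is edited twice.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # DP over the (la+1) x (lb+1) edit lattice, keeping three rows for the
    # transposition lookback.
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cb = b[j - 1]
            cost = 0 if ca == cb else 1
            best = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ca == b[j - 2] and a[i - 2] == cb:
                best = min(best, prev2[j - 2] + 1)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    is_phrase: bool
    fuzzy_eligible: bool

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.surface.lower().split())


@dataclass
class KeywordLexicon:
    """A compiled keyword lexicon.

    Surfaces are unique after case-folding. An entry is fuzzy-eligible iff
    its longest token has length >= 5; shorter entries (acronyms) are
    matched exactly.
    """

    entries: list[LexiconEntry]
    version: str = DEFAULT_LEXICON_VERSION

    @classmethod
    def from_surfaces(cls, surfaces: Iterable[str], version: str = "custom") -> "KeywordLexicon":
        entries: list[LexiconEntry] = []
        seen: set[str] = set()
        for raw in surfaces:
            surface = raw.strip()
            if not surface:
                continue
            folded = " ".join(surface.lower().split())
            if folded in seen:
                continue
            seen.add(folded)
            words = folded.split()
            fuzzy = max(len(w) for w in words) > 4
            entries.append(
                LexiconEntry(surface=surface, is_phrase=len(words) > 1, fuzzy_eligible=fuzzy)
            )
        return cls(entries=entries, version=version)

    @classmethod
    def from_file(cls, path: str | Path, version: Optional[str] = None) -> "KeywordLexicon":
        """Read a lexicon from a plain-text file, one entry per line.

        Lines starting with "#" (after stripping) are comments.
        """
        path = Path(path)
        surfaces = [
            line for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.strip().startswith("#")
        ]
        return cls.from_surfaces(surfaces, version=version or path.stem)

    @classmethod
    def default(cls) -> "KeywordLexicon":
        """The packaged default lexicon of drug-use keywords."""
        text = resources.files("pwud_phenotype.data").joinpath("lexicon.txt").read_text(
            encoding="utf-8"
        )
        surfaces = [
            line for line in text.splitlines()
            if line.strip() and not line.strip().startswith("#")
        ]
        return cls.from_surfaces(surfaces, version=DEFAULT_LEXICON_VERSION)

    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]


@dataclass
class MatcherConfig:
    max_distance: int = 1
    min_token_len_for_fuzzy: int = 5
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_distance <= 2:
            raise ValueError("max_distance must be in 0..2")
        if self.min_token_len_for_fuzzy < 2:
            raise ValueError("min_token_len_for_fuzzy must be >= 2")


@dataclass
class MatchSpan:
    """One located piece of keyword evidence in a note.

    Offsets are 0-based, half-open, character-indexed into the original
    note text, so ``text[start:end] == matched_text``.
    """

    note_index: int
    start: int
    end: int
    matched_text: str
    lexicon_entry: str
    distance: int


def normalize_and_tokenize(text: str, case_sensitive: bool = False) -> list[tuple[str, int, int]]:
    """Split text into maximal alphanumeric runs with original offsets.

    Punctuation and whitespace are boundaries, so "IVDU." yields the token
    "ivdu". Tokens are case-folded unless ``case_sensitive``.
    """
    out = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        if not case_sensitive:
            tok = tok.lower()
        out.append((tok, m.start(), m.end()))
    return out


def _word_matches(token: str, word: str, fuzzy: bool, config: MatcherConfig) -> Optional[int]:
    """Distance if ``token`` matches lexicon word ``word``, else None."""
    if token == word:
        return 0
    if not fuzzy or config.max_distance == 0:
        return None
    if len(word) < config.min_token_len_for_fuzzy:
        return None
    # cheap length pre-filter: |len difference| bounds the distance
    if abs(len(token) - len(word)) > config.max_distance:
        return None
    d = dl_distance(token, word)
    return d if d <= config.max_distance else None


def match_note(
    note: Note,
    lexicon: KeywordLexicon,
    config: Optional[MatcherConfig] = None,
    note_index: int = 0,
) -> list[MatchSpan]:
    """Find all lexicon matches in one note, in text order.

    Overlapping matches for *distinct* entries are all reported. For a
    single entry, overlapping candidate spans are resolved keeping the
    lowest distance, breaking ties by leftmost start then longest span.
    """
    config = config or MatcherConfig()
    tokens = normalize_and_tokenize(note.text, case_sensitive=config.case_sensitive)
    if not tokens:
        return []
    spans: list[MatchSpan] = []
    for entry in lexicon.entries:
        words = entry.words if not config.case_sensitive else tuple(entry.surface.split())
        nw = len(words)
        candidates: list[tuple[int, int, int, int]] = []  # (distance, start, -length, end)
        for i in range(len(tokens) - nw + 1):
            dists = []
            ok = True
            for (tok, _s, _e), word in zip(tokens[i:i + nw], words):
                d = _word_matches(tok, word, entry.fuzzy_eligible, config)
                if d is None:
                    ok = False
                    break
                dists.append(d)
            if ok:
                start = tokens[i][1]
                end = tokens[i + nw - 1][2]
                candidates.append((max(dists) if dists else 0, start, -(end - start), end))
        # resolve overlaps within this one entry
        candidates.sort()  # by distance, then leftmost, then longest
        chosen: list[tuple[int, int, int]] = []  # (start, end, distance)
        for dist, start, neglen, end in candidates:
            if all(end <= s or start >= e for s, e, _ in chosen):
                chosen.append((start, end, dist))
        for start, end, dist in sorted(chosen):
            spans.append(
                MatchSpan(
                    note_index=note_index,
                    start=start,
                    end=end,
                    matched_text=note.text[start:end],
                    lexicon_entry=entry.surface,
                    distance=dist,
                )
            )
    spans.sort(key=lambda s: (s.start, s.end, s.lexicon_entry))
    return spans


def detect_encounter(
    encounter: Encounter,
    lexicon: Optional[KeywordLexicon] = None,
    config: Optional[MatcherConfig] = None,
) -> tuple[bool, list[MatchSpan]]:
    """Evaluate the NLP criterion over every note of an encounter.

    The flag is true iff any note of any type yields at least one match;
    the evidence list concatenates all spans across notes.
    """
    lexicon = lexicon or KeywordLexicon.default()
    config = config or MatcherConfig()
    evidence: list[MatchSpan] = []
    for idx, note in enumerate(encounter.notes):
        evidence.extend(match_note(note, lexicon, config, note_index=idx))
    return bool(evidence), evidence
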