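"""Value sets and lexicons for the base phenotype rules.

Three kinds of matcher are packaged as an editable plain-text file
(``data/lexicon.txt``) and loaded into:

* :class:`DxValueSet` — asthma diagnosis-code prefixes (ICD-9-CM ``493.*``,
  ICD-10-CM ``J45.*``), matched dot-insensitively by prefix;
* :class:`MedLexicon` — inhaled bronchodilator (BDR) and inhaled
  corticosteroid (ICS) generic/brand name terms, matched as case-insensitive
  word-bounded substrings of free-text order strings;
* :class:`KeywordLexicon` — asthma-specific (kw1) and nonspecific
  respiratory (kw2) note phrases, compiled to word-boundary-anchored
  case-insensitive regular expressions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

__all__ = [
    "DxValueSet",
    "MedLexicon",
    "KeywordLexicon",
    "Lexicons",
    "KeywordMention",
    "load_lexicons",
    "default_lexicons",
]


class LexiconError(ValueError):
    """Raised for malformed lexicon files."""


def normalize_code(code: str) -> str:
    """Upper-case a diagnosis code and strip dots (``J45.901`` -> ``J45901``)."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class DxValueSet:
    """Diagnosis-code prefix sets per code system."""

    prefixes: dict[str, tuple[str, ...]]  # code_system -> normalized prefixes

    def match(self, code_system: str, code: str) -> bool:
        if code_system not in self.prefixes:
            raise LexiconError(f"unknown code system {code_system!r}")
        if not code or not code.strip():
            raise LexiconError("empty diagnosis code")
        normalized = normalize_code(code)
        return any(normalized.startswith(p) for p in self.prefixes[code_system])


def _term_regex(term: str) -> re.Pattern:
    # Word-bounded, case-insensitive; internal whitespace matches any run of
    # whitespace so "shortness  of breath" still matches.
    escaped = r"\s+".join(re.escape(w) for w in term.split())
    return re.compile(rf"\b{escaped}\b", re.IGNORECASE)


@dataclass(frozen=True)
class MedLexicon:
    """Medication name terms for one category (BDR or ICS).

    ``families`` groups generic + brand names of one product family (one
    blank-line-separated block of the lexicon file); ``terms`` is the flat
    lower-cased, deduplicated union.
    """

    category: str  # "BDR" or "ICS"
    families: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if not self.families:
            raise LexiconError(f"{self.category}: empty medication lexicon")
        object.__setattr__(self, "_patterns", tuple(_term_regex(t) for t in self.terms))

    @property
    def terms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for family in self.families:
            for term in family:
                seen.setdefault(term.lower())
        return tuple(seen)

    def matches(self, drug_text: str) -> bool:
        return any(p.search(drug_text) for p in self._patterns)


class KeywordMention(NamedTuple):
    """One keyword hit in a note: category, matched term, character span."""

    category: str  # "KW1" or "KW2"
    term: str
    span: tuple[int, int]


@dataclass(frozen=True)
class KeywordLexicon:
    """Keyword phrase patterns for one category (KW1 or KW2)."""

    category: str
    phrases: tuple[str, ...]

    def __post_init__(self):
        if not self.phrases:
            raise LexiconError(f"{self.category}: empty keyword lexicon")
        object.__setattr__(self, "_patterns", tuple(_term_regex(p) for p in self.phrases))

    def find_mentions(self, text: str) -> list[KeywordMention]:
        mentions = [
            KeywordMention(self.category, phrase, m.span())
            for phrase, pattern in zip(self.phrases, self._patterns)
            for m in pattern.finditer(text)
        ]
        mentions.sort(key=lambda m: (m.span, m.term))
        return mentions


@dataclass(frozen=True)
class Lexicons:
    """The full bundle used by feature extraction."""

    dx: DxValueSet
    bdr: MedLexicon
    ics: MedLexicon
    kw1: KeywordLexicon
    kw2: KeywordLexicon


def match_dx_code(code_system: str, code: str, valueset: DxValueSet | None = None) -> bool:
    """True iff the (dot-normalized) code starts with an asthma prefix."""
    vs = valueset if valueset is not None else default_lexicons().dx
    return vs.match(code_system, code)


def classify_medication(drug_text: str, lexicons: "Lexicons | None" = None) -> str:
    """Classify a free-text medication order as ``BDR``, ``ICS`` or ``NONE``.

    Combination matches are degenerate inputs (the packaged lists contain no
    combination products): ICS takes precedence with a warning.
    """
    lex = lexicons if lexicons is not None else default_lexicons()
    is_bdr = lex.bdr.matches(drug_text)
    is_ics = lex.ics.matches(drug_text)
    if is_bdr and is_ics:
        warnings.warn(f"drug text matches both BDR and ICS, classifying as ICS: {drug_text!r}")
        return "ICS"
    if is_ics:
        return "ICS"
    if is_bdr:
        return "BDR"
    return "NONE"


def _parse_lexicon_text(text: str, source: str) -> Lexicons:
    sections: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().upper()
            current = sections.setdefault(name, [])
            current.append([])
            continue
        if not line:
            if current is not None and current[-1]:
                current.append([])  # blank line starts a new family block
            continue
        if current is None:
            raise LexiconError(f"{source}:{lineno}: term before any [SECTION] header")
        current[-1].append(line)

    def blocks(name: str) -> list[list[str]]:
        got = [b for b in sections.get(name, []) if b]
        if not got:
            raise LexiconError(f"{source}: missing or empty section [{name}]")
        return got

    def flat(name: str) -> list[str]:
        return [term for block in blocks(name) for term in block]

    prefixes = {
        "ICD9CM": tuple(normalize_code(c) for c in flat("DX:ICD9CM")),
        "ICD10CM": tuple(normalize_code(c) for c in flat("DX:ICD10CM")),
    }
    bdr = MedLexicon("BDR", tuple(tuple(b) for b in blocks("BDR")))
    ics = MedLexicon("ICS", tuple(tuple(b) for b in blocks("ICS")))
    overlap = set(bdr.terms) & set(ics.terms)
    if overlap:
        raise LexiconError(f"{source}: term(s) in both BDR and ICS: {sorted(overlap)}")
    kw1 = KeywordLexicon("KW1", tuple(dict.fromkeys(t.lower() for t in flat("KW1"))))
    kw2 = KeywordLexicon("KW2", tuple(dict.fromkeys(t.lower() for t in flat("KW2"))))
    return Lexicons(dx=DxValueSet(prefixes), bdr=bdr, ics=ics, kw1=kw1, kw2=kw2)


def load_lexicons(source: str | Path | None = None) -> Lexicons:
    """Load lexicons from a file (or the packaged defaults when omitted)."""
    if source is None:
        text = resources.files("compac.data").joinpath("lexicon.txt").read_text(encoding="utf-8")
        return _parse_lexicon_text(text, "packaged lexicon.txt")
    path = Path(source)
    if path.is_dir():
        path = path / "lexicon.txt"
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    return _parse_lexicon_text(path.read_text(encoding="utf-8"), str(path))


_DEFAULT: Lexicons | None = None


def default_lexicons() -> Lexicons:
    """The packaged default lexicon bundle (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_lexicons(None)
    return _DEFAULT
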