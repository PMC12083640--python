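"""Phenotype-rule DSL: parsing, evaluation, built-in phenotypes, base-rule
pattern stratification, and rule-combination enumeration.

The DSL expresses rules over the five visit-level feature counts::

    (dx>=2 | dx>=1 & (bdr>=2 | ics>=1)) & kw1>=1

Atoms are ``feature>=k`` or ``feature=k`` (k >= 1); ``&`` is AND, ``|`` is
OR, with AND binding tighter than OR; parentheses group.  Feature names are
case-insensitive and ``IB`` is accepted as an alias for ``BDR`` (both
spellings denote inhaled bronchodilators).  The unicode variants ``∣`` and
``≥`` are accepted on input; the canonical printer emits ASCII.

The final COMPAC phenotype is
``(dx>=2 | dx>=1 & (bdr>=2 | ics>=1)) & kw1>=1``: at least two asthma-coded
visits, or one coded visit plus bronchodilator/corticosteroid prescriptions,
and in every case at least one asthma-specific keyword visit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .ehr_model import Cohort
from .feature_extraction import (
    apply_age_window,
    build_feature_events,
)
from .lexicons import Lexicons, _term_regex, default_lexicons

FEATURES = ("dx", "bdr", "ics", "kw1", "kw2")

_ALIASES = {"ib": "bdr"}

#: published per-feature base-rule thresholds (a feature is "present" in the
#: base-rule sense when its count reaches this)
BASE_THRESHOLDS = {"dx": 1, "bdr": 2, "ics": 1, "kw1": 1, "kw2": 2}


class RuleSyntaxError(ValueError):
    """Raised for malformed rule text, with the offending position."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleAtom:
    """A threshold atom: ``feature op threshold``."""

    feature: str
    op: str  # ">=" or "="
    threshold: int

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise RuleSyntaxError(f"unknown feature {self.feature!r}")
        if self.op not in (">=", "="):
            raise RuleSyntaxError(f"unknown operator {self.op!r}")
        if self.threshold < 1:
            raise RuleSyntaxError(f"threshold must be >= 1, got {self.threshold}")

    def __str__(self) -> str:
        return f"{self.feature}{self.op}{self.threshold}"


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


Node = Union[RuleAtom, And, Or]


@dataclass(frozen=True)
class PhenotypeRule:
    """A parsed rule: AST plus the original source text."""

    root: Node
    source_text: str

    def __str__(self) -> str:
        return print_rule(self.root)

    @property
    def atoms(self) -> tuple[RuleAtom, ...]:
        out: list[RuleAtom] = []

        def walk(node: Node):
            if isinstance(node, RuleAtom):
                if node not in out:
                    out.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return tuple(out)


# ---------------------------------------------------------------------------
# Parser (recursive descent; AND binds tighter than OR)
# ---------------------------------------------------------------------------

class _Tokenizer:
    _PUNCT = {"&": "AND", "|": "OR", "∣": "OR", "(": "LP", ")": "RP"}

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, str, int]] = []  # (kind, value, pos)
        self._tokenize()
        self.index = 0

    def _tokenize(self):
        text = self.text
        i = 0
        while i < len(text):
            ch = text[i]
            if ch.isspace():
                i += 1
                continue
            if ch in self._PUNCT:
                self.tokens.append((self._PUNCT[ch], ch, i))
                i += 1
            elif text.startswith(">=", i):
                self.tokens.append(("GE", ">=", i))
                i += 2
            elif ch == "≥":
                self.tokens.append(("GE", "≥", i))
                i += 1
            elif ch == "=":
                self.tokens.append(("EQ", "=", i))
                i += 1
            elif ch.isalpha():
                j = i
                while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                    j += 1
                self.tokens.append(("NAME", text[i:j], i))
                i = j
            elif ch.isdigit():
                j = i
                while j < len(text) and text[j].isdigit():
                    j += 1
                self.tokens.append(("INT", text[i:j], i))
                i = j
            else:
                raise RuleSyntaxError(f"unexpected character {ch!r} at position {i}")

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def next(self) -> tuple[str, str, int] | None:
        tok = self.peek()
        if tok is not None:
            self.index += 1
        return tok


def _flatten(cls, children: Iterable[Node]) -> tuple[Node, ...]:
    flat: list[Node] = []
    for child in children:
        if isinstance(child, cls):
            flat.extend(child.children)
        else:
            flat.append(child)
    return tuple(flat)


def parse_rule(text: str) -> PhenotypeRule:
    """Parse rule text into a :class:`PhenotypeRule`.

    Raises :class:`RuleSyntaxError` with the character position on malformed
    input or unknown feature names.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty rule text")
    tz = _Tokenizer(text)

    def parse_or() -> Node:
        children = [parse_and()]
        while tz.peek() is not None and tz.peek()[0] == "OR":
            tz.next()
            children.append(parse_and())
        return children[0] if len(children) == 1 else Or(_flatten(Or, children))

    def parse_and() -> Node:
        children = [parse_factor()]
        while tz.peek() is not None and tz.peek()[0] == "AND":
            tz.next()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else And(_flatten(And, children))

    def parse_factor() -> Node:
        tok = tz.next()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of rule: {text!r}")
        kind, value, pos = tok
        if kind == "LP":
            inner = parse_or()
            closing = tz.next()
            if closing is None or closing[0] != "RP":
                raise RuleSyntaxError(f"unbalanced parenthesis opened at position {pos}")
            return inner
        if kind == "NAME":
            feature = value.lower()
            feature = _ALIASES.get(feature, feature)
            if feature not in FEATURES:
                raise RuleSyntaxError(f"unknown feature {value!r} at position {pos}")
            op_tok = tz.next()
            if op_tok is None or op_tok[0] not in ("GE", "EQ"):
                raise RuleSyntaxError(f"expected '>=' or '=' after {value!r} at position {pos}")
            int_tok = tz.next()
            if int_tok is None or int_tok[0] != "INT":
                raise RuleSyntaxError(f"expected integer threshold at position {op_tok[2]}")
            op = ">=" if op_tok[0] == "GE" else "="
            return RuleAtom(feature, op, int(int_tok[1]))
        raise RuleSyntaxError(f"unexpected token {value!r} at position {pos}")

    root = parse_or()
    trailing = tz.peek()
    if trailing is not None:
        raise RuleSyntaxError(f"unexpected token {trailing[1]!r} at position {trailing[2]}")
    return PhenotypeRule(root=root, source_text=text)


def print_rule(node: Node) -> str:
    """Canonical printer.  AND binds tighter than OR, so only OR children of
    an AND need parentheses; ``parse(print_rule(ast)) == ast``."""
    if isinstance(node, RuleAtom):
        return str(node)
    if isinstance(node, And):
        parts = [
            f"({print_rule(c)})" if isinstance(c, Or) else print_rule(c)
            for c in node.children
        ]
        return " & ".join(parts)
    return " | ".join(print_rule(c) for c in node.children)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _counts_value(counts, feature: str):
    if isinstance(counts, Mapping):
        if feature in counts:
            return counts[feature]
        return counts[f"n_{feature}"]
    return getattr(counts, f"n_{feature}")


def evaluate_rule(rule: PhenotypeRule | Node, counts) -> bool:
    """Evaluate a rule against one patient's feature counts.

    ``counts`` may be a mapping with keys ``dx``/``bdr``/... (or the
    ``n_``-prefixed column names) or any object with ``n_dx`` etc.
    """
    node = rule.root if isinstance(rule, PhenotypeRule) else rule
    if isinstance(node, RuleAtom):
        value = int(_counts_value(counts, node.feature))
        return value >= node.threshold if node.op == ">=" else value == node.threshold
    if isinstance(node, And):
        return all(evaluate_rule(c, counts) for c in node.children)
    return any(evaluate_rule(c, counts) for c in node.children)


def evaluate_rule_frame(rule: PhenotypeRule | Node, counts_table: pd.DataFrame) -> pd.Series:
    """Vectorized evaluation over a feature-count table -> boolean Series."""
    node = rule.root if isinstance(rule, PhenotypeRule) else rule
    if isinstance(node, RuleAtom):
        col = counts_table[f"n_{node.feature}"]
        return col >= node.threshold if node.op == ">=" else col == node.threshold
    parts = [evaluate_rule_frame(c, counts_table) for c in node.children]
    out = parts[0]
    for p in parts[1:]:
        out = (out & p) if isinstance(node, And) else (out | p)
    return out


def apply_phenotype(rule: PhenotypeRule | Node, counts_table: pd.DataFrame) -> list[str]:
    """Patients whose counts satisfy the rule, sorted for determinism."""
    mask = evaluate_rule_frame(rule, counts_table)
    return sorted(counts_table.loc[mask, "patient_id"].astype(str))


# ---------------------------------------------------------------------------
# Built-in phenotypes
# ---------------------------------------------------------------------------

COMPAC_TEXT = "(dx>=2 | dx>=1 & (bdr>=2 | ics>=1)) & kw1>=1"
#: the equivalent form in which the final rule was originally selected
COMPAC_SELECTION_TEXT = "dx>=1 & (dx>=2 | ib>=2 | ics>=1) & kw1>=1"
CAPRICORN_ADAPTED_TEXT = "dx>=2 | dx>=1 & (bdr>=1 | ics>=1)"

#: The thirteen published benchmark rules (PheKB is a mention-count
#: phenotype, not a count DSL rule — see :func:`phekb_adapted`).
TABLE3_RULES: tuple[tuple[str, str], ...] = (
    ("dx1", "dx>=1"),
    ("max_sensitivity", "dx>=1 | ICS>=1 | kw1>=1 | kw2>=2"),
    ("best_f1", "dx>=1 & (ICS>=1 | kw1>=1)"),
    ("dx_or_any", "dx>=1 & (DX>=2 | BDR>=2 | ICS>=1 | kw1>=1)"),
    ("dx2", "dx>=2"),
    ("meds_or_kw1", "IB>=2 | ICS>=1 | kw1>=1"),
    ("max_specificity", "dx>=2 & ICS>=1"),
    ("capricorn_adapted", CAPRICORN_ADAPTED_TEXT),
    ("compac_variant_kw1", "dx>=2 | dx>=1 & (ICS>=1 | BDR>=2 & kw1>=1)"),
    ("compac_variant_kw2", "dx>=2 | dx>=1 & (ICS>=1 | BDR>=2 & kw1>=2)"),
    ("balanced_combo", "(dx>=2 | dx>=1 & (BDR>=2 | ICS>=1)) & kw1>=1"),
    ("compac", COMPAC_TEXT),
)


@dataclass(frozen=True)
class PheKBMentionRule:
    """Adapted PheKB phenotype: at least ``min_encounters`` distinct
    encounters each carrying an asthma diagnosis code or a note mention of
    "wheezing" or "asthma", anywhere on the timeline (no one-year window).

    ``include_dx`` is configurable because the published adaptation does not
    state whether coded diagnoses count as "mentions"; the default includes
    them.
    """

    min_encounters: int = 3
    keywords: tuple[str, ...] = ("wheezing", "asthma")
    include_dx: bool = True

    def identify(self, cohort: Cohort, lexicons: Lexicons | None = None) -> list[str]:
        return phekb_adapted(
            cohort,
            lexicons,
            min_encounters=self.min_encounters,
            keywords=self.keywords,
            include_dx=self.include_dx,
        )


BUILTIN_NAMES = ("COMPAC", "DX1", "DX2", "CAPRICORN_ADAPTED", "PHEKB_ADAPTED")


def builtin_phenotype(name: str) -> PhenotypeRule | PheKBMentionRule:
    """Return a built-in phenotype by name (case-insensitive)."""
    key = name.strip().upper()
    if key == "COMPAC":
        return parse_rule(COMPAC_TEXT)
    if key == "DX1":
        return parse_rule("dx>=1")
    if key == "DX2":
        return parse_rule("dx>=2")
    if key == "CAPRICORN_ADAPTED":
        return parse_rule(CAPRICORN_ADAPTED_TEXT)
    if key == "PHEKB_ADAPTED":
        return PheKBMentionRule()
    raise ValueError(f"unknown builtin phenotype {name!r}; expected one of {BUILTIN_NAMES}")


def phekb_adapted(
    cohort: Cohort,
    lexicons: Lexicons | None = None,
    min_encounters: int = 3,
    keywords: Sequence[str] = ("wheezing", "asthma"),
    include_dx: bool = True,
) -> list[str]:
    """Patients with >= ``min_encounters`` distinct age-window encounters
    having an asthma diagnosis code or a note mention of one of ``keywords``.

    Mentions in the same encounter count once (visit dedup), and the
    pediatric age window (with 1–2-year carryover) applies.
    """
    lex = lexicons if lexicons is not None else default_lexicons()
    events = apply_age_window(build_feature_events(cohort, lex))
    window_encounters = {(e.patient_id, e.encounter_id) for e in events}

    patterns = [_term_regex(k) for k in keywords]
    enc = cohort.encounters
    pid_of = dict(zip(enc["encounter_id"].astype(str), enc["patient_id"].astype(str)))

    qualifying: dict[str, set[str]] = {}
    if include_dx:
        for e in events:
            if e.category == "DX":
                qualifying.setdefault(e.patient_id, set()).add(e.encounter_id)
    for _, row in cohort.notes.iterrows():
        eid = str(row["encounter_id"])
        pid = pid_of.get(eid)
        if pid is None or (pid, eid) not in window_encounters:
            continue
        if any(p.search(str(row["text"])) for p in patterns):
            qualifying.setdefault(pid, set()).add(eid)
    return sorted(p for p, encs in qualifying.items() if len(encs) >= min_encounters)


# ---------------------------------------------------------------------------
# Base-rule pattern stratification (Identified / Covered semantics)
# ---------------------------------------------------------------------------

IDENTIFIED = "IDENTIFIED"
COVERED = "COVERED"


@dataclass(frozen=True)
class BasePattern:
    """A row of the base-rule combination grid.

    ``flags`` maps each feature to the atom it must satisfy, or ``None``
    for a dash.  A dash means *must be absent* (count below the feature's
    base threshold) in IDENTIFIED mode, and *ignored* in COVERED mode.
    """

    flags: Mapping[str, RuleAtom | None]

    def __post_init__(self):
        unknown = set(self.flags) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature(s) in pattern: {sorted(unknown)}")
        if all(v is None for v in self.flags.values()):
            raise ValueError("pattern must have at least one required feature")
        object.__setattr__(self, "flags", dict(self.flags))

    def __hash__(self):  # flags is a dict, so the generated hash won't do
        return hash(tuple(self.flags.get(f) for f in FEATURES))

    @classmethod
    def from_row(cls, dx: str = "-", bdr: str = "-", ics: str = "-",
                 kw1: str = "-", kw2: str = "-") -> "BasePattern":
        """Build from grid-row cell strings: ``"-"``, ``"+"``, ``">=2"``,
        ``"=1"`` (a bare ``"+"`` uses the feature's base threshold)."""
        cells = {"dx": dx, "bdr": bdr, "ics": ics, "kw1": kw1, "kw2": kw2}
        flags: dict[str, RuleAtom | None] = {}
        for feature, cell in cells.items():
            cell = cell.strip().replace("≥", ">=").replace("−", "-")
            if cell == "-":
                flags[feature] = None
            elif cell == "+":
                flags[feature] = RuleAtom(feature, ">=", BASE_THRESHOLDS[feature])
            elif cell.startswith(">="):
                flags[feature] = RuleAtom(feature, ">=", int(cell[2:]))
            elif cell.startswith("="):
                flags[feature] = RuleAtom(feature, "=", int(cell[1:]))
            else:
                raise ValueError(f"bad pattern cell {cell!r} for {feature}")
        return cls(flags)

    def __str__(self) -> str:
        return ",".join(
            "-" if self.flags.get(f) is None else str(self.flags[f]) for f in FEATURES
        )


def stratify_by_pattern(
    counts_table: pd.DataFrame, pattern: BasePattern, mode: str = IDENTIFIED
) -> list[str]:
    """Patients matching a base-rule pattern row.

    IDENTIFIED: every required atom holds AND every dashed feature is absent
    (count strictly below its base threshold).  COVERED: dashes are ignored.
    By construction IDENTIFIED is a subset of COVERED.
    """
    if mode not in (IDENTIFIED, COVERED):
        raise ValueError(f"mode must be {IDENTIFIED!r} or {COVERED!r}")
    mask = pd.Series(True, index=counts_table.index)
    for feature in FEATURES:
        atom = pattern.flags.get(feature)
        if atom is not None:
            mask &= evaluate_rule_frame(atom, counts_table)
        elif mode == IDENTIFIED:
            mask &= counts_table[f"n_{feature}"] < BASE_THRESHOLDS[feature]
    return sorted(counts_table.loc[mask, "patient_id"].astype(str))


# ---------------------------------------------------------------------------
# Rule-combination enumeration
# ---------------------------------------------------------------------------

def pool_count_grid(atoms: Sequence[RuleAtom]) -> pd.DataFrame:
    """The reachable count grid of an atom pool, as a feature-count frame.

    Per feature the grid holds 0, every threshold t mentioned by the pool,
    and every t+1 (so each run of counts between consecutive thresholds, and
    past the largest, has a representative — needed to separate ``=k`` from
    ``>k`` and to catch differences strictly between thresholds).  Two
    formulas over the pool agree on all count vectors iff they agree on this
    grid.
    """
    grid_values: dict[str, list[int]] = {}
    for feature in FEATURES:
        thresholds = {a.threshold for a in atoms if a.feature == feature}
        if thresholds:
            grid_values[feature] = sorted({0} | thresholds | {t + 1 for t in thresholds})
    features = sorted(grid_values)
    rows = [
        {f"n_{f}": 0 for f in FEATURES} | dict(zip((f"n_{f}" for f in features), combo))
        for combo in itertools.product(*(grid_values[f] for f in features))
    ]
    return pd.DataFrame(rows, columns=[f"n_{f}" for f in FEATURES])


def enumerate_rules(
    atom_pool: Sequence[RuleAtom], max_terms: int, limit: int = 200_000
) -> list[PhenotypeRule]:
    """Deterministically enumerate logically distinct AND/OR rules.

    Candidates are generated in disjunctive normal form: every OR of at most
    ``max_terms`` AND-clauses, each clause a non-empty subset of the atom
    pool.  Any AND/OR formula over the pool with that many clauses in its
    DNF is logically equivalent to one candidate, so deduplication by truth
    table over the pool's reachable count grid yields one representative per
    equivalence class.  Output order: (number of clauses, clause sizes,
    canonical text).
    """
    if not atom_pool:
        raise ValueError("atom_pool must be non-empty")
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    pool = list(dict.fromkeys(atom_pool))
    clauses: list[Node] = []
    for r in range(1, len(pool) + 1):
        for subset in itertools.combinations(pool, r):
            clauses.append(subset[0] if r == 1 else And(tuple(subset)))

    n_clauses = len(clauses)
    n_candidates = sum(
        _ncr(n_clauses, r) for r in range(1, min(max_terms, n_clauses) + 1)
    )
    if n_candidates > limit:
        raise ValueError(
            f"enumeration would generate {n_candidates} candidates (> limit {limit}); "
            "shrink the atom pool or max_terms"
        )

    # vectorized truth signatures: bool mask per clause over the pool grid
    grid = pool_count_grid(pool)
    clause_masks = [evaluate_rule_frame(c, grid).to_numpy() for c in clauses]

    seen: set[bytes] = set()
    out: list[PhenotypeRule] = []
    for r in range(1, min(max_terms, n_clauses) + 1):
        for idx in itertools.combinations(range(n_clauses), r):
            mask = clause_masks[idx[0]]
            for i in idx[1:]:
                mask = mask | clause_masks[i]
            sig = mask.tobytes()
            if sig in seen:
                continue
            seen.add(sig)
            node: Node = clauses[idx[0]] if r == 1 else Or(tuple(clauses[i] for i in idx))
            out.append(PhenotypeRule(root=node, source_text=print_rule(node)))
    return out


def _ncr(n: int, r: int) -> int:
    import math

    return math.comb(n, r) if r <= n else 0
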