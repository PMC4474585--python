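"""Token-pattern rule language: parser and leftmost-longest matcher.

A rule is a labeled sequence of token specifications, each enclosed in
square brackets and optionally quantified::

    SignSymptom => [syn=NN|NNP]{1,3}, [sem=beverb]?, [syn=VBN|JJ, token!="normal"|"regular"|"stable"]

This rule matches one to three nouns (compound signs like "chest pain"),
an optional form of *be*, then a past participle or adjective that is not
one of the normal-condition words — so it accepts "heart is enlarged",
"leg swollen", "abdomen was distended", while "chest is normal" is filtered
by the ``token!=`` exclusion.

Attributes a constraint may test:

``token``  the surface form (case-insensitive)
``syn``    the POS tag (case-sensitive)
``sem``    the semantic type set by the lexicon tagger; the pseudo-type
           ``beverb`` is satisfied by a closed list of *be* forms
``orth``   a coarse orthographic class: ``lower``, ``cap``, ``caps``,
           ``digit``, ``punct`` or ``mixed``

Quantifiers: ``?`` means (0,1), ``{m,n}`` bounded iteration, default (1,1).
Matching is per sentence, leftmost, and longest at each start; a single
rule never reports overlapping matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .docmodel import LABELS, Document, EntityMention, Sentence, Token

ATTRIBUTES = ("token", "syn", "sem", "orth")

#: Closed word list satisfying ``sem=beverb`` without any lexicon.
BE_FORMS = frozenset({"is", "are", "was", "were", "be", "been", "being", "am", "'s"})


class RuleParseError(ValueError):
    """Syntax error in a rule line; carries the 0-based column position."""

    def __init__(self, message: str, column: int):
        self.column = column
        super().__init__(f"column {column}: {message}")


@dataclass(frozen=True)
class Constraint:
    attribute: str  # one of ATTRIBUTES
    negated: bool  # True for !=
    values: tuple[str, ...]


@dataclass(frozen=True)
class TokenSpec:
    constraints: tuple[Constraint, ...]
    min_count: int = 1
    max_count: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.min_count <= self.max_count) or self.max_count < 1:
            raise ValueError(f"bad iteration bounds ({self.min_count},{self.max_count})")


@dataclass(frozen=True)
class Rule:
    label: str
    specs: tuple[TokenSpec, ...]
    rule_id: str = ""
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown rule label {self.label!r}")
        if not self.specs:
            raise ValueError("rule has no token specifications")
        if all(s.min_count == 0 for s in self.specs):
            raise ValueError("rule could match the empty sequence (all specs optional)")


@dataclass(frozen=True)
class RuleMatch:
    rule_id: str
    sentence_index: int
    start_token: int
    end_token: int  # exclusive
    start: int  # character offsets
    end: int
    label: str


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


class _Cursor:
    def __init__(self, line: str):
        self.line = line
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.line) and self.line[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.line[self.pos] if self.pos < len(self.line) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise RuleParseError(f"expected {ch!r}, found {self.peek()!r}", self.pos)
        self.pos += 1

    def at_end(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.line)


_BAREWORD = re.compile(r"[^\s\[\]=!,|{}\"?]+")


def _parse_value(cur: _Cursor) -> str:
    cur.skip_ws()
    if cur.peek() == '"':
        start = cur.pos
        cur.pos += 1
        end = cur.line.find('"', cur.pos)
        if end < 0:
            raise RuleParseError("unterminated quoted value", start)
        value = cur.line[cur.pos:end]
        cur.pos = end + 1
        return value
    m = _BAREWORD.match(cur.line, cur.pos)
    if not m:
        raise RuleParseError("expected a value", cur.pos)
    cur.pos = m.end()
    return m.group()


def _parse_constraint(cur: _Cursor) -> Constraint:
    cur.skip_ws()
    m = re.match(r"[A-Za-z]+", cur.line[cur.pos:])
    if not m:
        raise RuleParseError("expected an attribute name", cur.pos)
    attr = m.group()
    if attr not in ATTRIBUTES:
        raise RuleParseError(f"unknown attribute {attr!r} (expected one of {ATTRIBUTES})", cur.pos)
    cur.pos += m.end()
    cur.skip_ws()
    negated = False
    if cur.peek() == "!":
        negated = True
        cur.pos += 1
    cur.expect("=")
    values = [_parse_value(cur)]
    cur.skip_ws()
    while cur.peek() == "|":
        cur.pos += 1
        values.append(_parse_value(cur))
        cur.skip_ws()
    if not all(values):
        raise RuleParseError("empty value in value list", cur.pos)
    return Constraint(attr, negated, tuple(values))


def _parse_spec(cur: _Cursor) -> TokenSpec:
    cur.skip_ws()
    open_pos = cur.pos
    cur.expect("[")
    constraints = [_parse_constraint(cur)]
    cur.skip_ws()
    while cur.peek() == ",":
        cur.pos += 1
        constraints.append(_parse_constraint(cur))
        cur.skip_ws()
    if cur.peek() != "]":
        raise RuleParseError("unbalanced bracket: expected ']'", open_pos)
    cur.pos += 1
    min_count, max_count = 1, 1
    cur.skip_ws()
    if cur.peek() == "?":
        cur.pos += 1
        min_count, max_count = 0, 1
    elif cur.peek() == "{":
        qpos = cur.pos
        m = re.match(r"\{(\d+),(\d+)\}", cur.line[cur.pos:])
        if not m:
            raise RuleParseError("malformed iterator, expected {m,n}", qpos)
        min_count, max_count = int(m.group(1)), int(m.group(2))
        if min_count > max_count:
            raise RuleParseError(f"iterator lower bound {min_count} exceeds upper bound {max_count}", qpos)
        if max_count < 1:
            raise RuleParseError("iterator upper bound must be >= 1", qpos)
        cur.pos += m.end()
    return TokenSpec(tuple(constraints), min_count, max_count)


def parse_rule(line: str, rule_id: str = "", source_line: int = 0) -> Rule:
    """Parse one rule line ``LABEL => spec (, spec)*``."""
    cur = _Cursor(line)
    cur.skip_ws()
    m = re.match(r"[A-Za-z]+", line[cur.pos:])
    if not m:
        raise RuleParseError("expected a label before '=>'", cur.pos)
    label = m.group()
    if label not in LABELS:
        raise RuleParseError(f"unknown label {label!r} (expected one of {LABELS})", cur.pos)
    cur.pos += m.end()
    cur.skip_ws()
    if not cur.line.startswith("=>", cur.pos):
        raise RuleParseError("expected '=>' after the label", cur.pos)
    cur.pos += 2
    specs = [_parse_spec(cur)]
    cur.skip_ws()
    while cur.peek() == ",":
        cur.pos += 1
        specs.append(_parse_spec(cur))
        cur.skip_ws()
    if not cur.at_end():
        raise RuleParseError(f"unexpected trailing input {cur.line[cur.pos:]!r}", cur.pos)
    try:
        return Rule(label, tuple(specs), rule_id=rule_id or label, source_line=source_line)
    except ValueError as exc:
        raise RuleParseError(str(exc), 0) from None


def format_rule(rule: Rule) -> str:
    """Canonical textual form; ``parse_rule(format_rule(r))`` equals ``r``."""
    parts = []
    for spec in rule.specs:
        cons = []
        for c in spec.constraints:
            op = "!=" if c.negated else "="
            vals = "|".join(f'"{v}"' if re.search(r"[\s\[\]=!,|{}?\"]", v) or not v else v for v in c.values)
            cons.append(f"{c.attribute}{op}{vals}")
        s = f"[{', '.join(cons)}]"
        if (spec.min_count, spec.max_count) == (0, 1):
            s += "?"
        elif (spec.min_count, spec.max_count) != (1, 1):
            s += f"{{{spec.min_count},{spec.max_count}}}"
        parts.append(s)
    return f"{rule.label} => {', '.join(parts)}"


def load_rules(path: str | Path) -> list[Rule]:
    """Load a rule file: one rule per line, ``#`` comments and blanks ignored."""
    rules = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            rules.append(parse_rule(stripped, rule_id=f"R{len(rules) + 1}", source_line=lineno))
        except RuleParseError as exc:
            raise RuleParseError(f"line {lineno}: {exc}", exc.column) from None
    return rules


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def orth_class(text: str) -> str:
    """Coarse orthographic class of a token."""
    if text.isdigit():
        return "digit"
    if all(not ch.isalnum() for ch in text):
        return "punct"
    if text.islower():
        return "lower"
    if text.isupper():
        return "caps"
    if text[0].isupper() and text[1:].islower():
        return "cap"
    return "mixed"


def spec_matches(spec: TokenSpec, token: Token) -> bool:
    """True iff the token satisfies every constraint of the spec.

    Surface comparison is case-insensitive; POS and semantic types are
    case-sensitive.  A missing semantic tag fails ``=`` tests and passes
    ``!=`` tests.
    """
    for c in spec.constraints:
        if c.attribute == "token":
            hit = token.text.lower() in {v.lower() for v in c.values}
        elif c.attribute == "syn":
            hit = token.pos in c.values
        elif c.attribute == "sem":
            hit = (token.sem is not None and token.sem in c.values) or (
                "beverb" in c.values and token.text.lower() in BE_FORMS
            )
        elif c.attribute == "orth":
            hit = orth_class(token.text) in c.values
        else:  # pragma: no cover - parser guarantees the attribute set
            raise ValueError(f"unknown attribute {c.attribute!r}")
        if hit == c.negated:
            return False
    return True


def _expansions(rule: Rule, tokens: list[Token], start: int) -> list[int]:
    """All end positions (exclusive) of successful matches anchored at start."""
    ends: list[int] = []

    def walk(spec_idx: int, pos: int) -> None:
        if spec_idx == len(rule.specs):
            if pos > start:
                ends.append(pos)
            return
        spec = rule.specs[spec_idx]
        # count how far this spec can repeat from pos
        max_here = 0
        while (
            max_here < spec.max_count
            and pos + max_here < len(tokens)
            and spec_matches(spec, tokens[pos + max_here])
        ):
            max_here += 1
        for count in range(max_here, spec.min_count - 1, -1):
            walk(spec_idx + 1, pos + count)

    walk(0, start)
    return ends


def match_rule(rule: Rule, sentence: Sentence, sentence_index: Optional[int] = None) -> list[RuleMatch]:
    """Leftmost-longest, non-overlapping matches of one rule in one sentence."""
    si = sentence.index if sentence_index is None else sentence_index
    tokens = sentence.tokens
    matches: list[RuleMatch] = []
    i = 0
    while i < len(tokens):
        ends = _expansions(rule, tokens, i)
        if ends:
            end = max(ends)
            matches.append(
                RuleMatch(
                    rule_id=rule.rule_id,
                    sentence_index=si,
                    start_token=i,
                    end_token=end,
                    start=tokens[i].start,
                    end=tokens[end - 1].end,
                    label=rule.label,
                )
            )
            i = end
        else:
            i += 1
    return matches


def apply_ruleset(rules: Iterable[Rule], doc: Document) -> list[EntityMention]:
    """Union of per-rule matches, resolved into an overlap-free mention list.

    Conflicts are resolved by earlier start, then longer span, then lower
    source line of the producing rule.
    """
    candidates: list[tuple[int, int, int, RuleMatch, Rule]] = []
    for rule in rules:
        for sent in doc.sentences:
            for m in match_rule(rule, sent):
                candidates.append((m.start, -(m.end - m.start), rule.source_line, m, rule))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    mentions: list[EntityMention] = []
    occupied: list[tuple[int, int]] = []
    for start, _, _, m, rule in candidates:
        if any(s < m.end and m.start < e for s, e in occupied):
            continue
        occupied.append((m.start, m.end))
        mentions.append(EntityMention(doc.doc_id, m.start, m.end, m.label, doc.text[m.start:m.end]))
    return sorted(mentions, key=lambda m: (m.start, m.end))
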