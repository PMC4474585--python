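"""Core document/annotation data model and text-format I/O.

The data model is deliberately small: a :class:`Document` is a raw text plus
a token layer grouped into sentences; an :class:`EntityMention` is a labeled
character span in one of the four phenotype classes used throughout the
package (causes of congestive heart failure, risk factors, signs & symptoms,
and kidney-related non-traditional risk factors).  All offsets are 0-based
and end-exclusive.

Two interchange formats are supported:

* brat-style standoff (``T<n>\\tLabel start end\\tsurface`` lines next to a
  plain-text file), and
* a CoNLL-style TSV dialect with columns ``token start end pos chunk
  [label]``, blank lines separating sentences, which lets pre-tokenized and
  pre-tagged text enter the pipeline without an external tagger.

BIO encoding/decoding between mentions and per-token tag sequences lives
here too, since every sequence labeler depends on it.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

log = logging.getLogger(__name__)

#: The four phenotype classes; the label set of the whole package.
LABELS = ("Cause", "RiskFactor", "SignSymptom", "NonTraditionalRiskFactor")

STYLES = ("discharge", "article")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass
class Token:
    """A token anchored to its document by character offsets.

    ``pos`` is a Penn-style part-of-speech tag, ``chunk`` an IOB chunk tag
    (``B-NP``/``I-NP``/``O``); ``sem`` is an optional semantic type set by
    the lexicon tagger.
    """

    text: str
    start: int
    end: int
    pos: str = ""
    chunk: str = "O"
    sem: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token offsets [{self.start},{self.end})")


@dataclass
class Sentence:
    tokens: list[Token]
    index: int = 0

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end


@dataclass
class Document:
    doc_id: str
    text: str
    style: str = "discharge"
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}; expected one of {STYLES}")

    def tokens(self) -> Iterator[Token]:
        for sent in self.sentences:
            yield from sent.tokens


@dataclass(frozen=True)
class EntityMention:
    """A labeled character span; ``text`` is the document slice."""

    doc_id: str
    start: int
    end: int
    label: str
    text: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not self.start < self.end:
            raise ValueError(f"bad mention offsets [{self.start},{self.end})")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.doc_id == other.doc_id and self.start < other.end and other.start < self.end


@dataclass
class AnnotationSet:
    mentions: list[EntityMention]
    annotator_id: str = "gold"

    def __post_init__(self) -> None:
        seen = set()
        for m in self.mentions:
            key = (m.doc_id, m.start, m.end, m.label)
            if key in seen:
                raise ValueError(f"duplicate mention {key} in annotation set {self.annotator_id!r}")
            seen.add(key)

    def for_doc(self, doc_id: str) -> list[EntityMention]:
        return sorted((m for m in self.mentions if m.doc_id == doc_id), key=lambda m: (m.start, m.end))


@dataclass
class SequenceExample:
    """A sentence paired with BIO tags, the unit consumed by labelers."""

    tokens: list[Token]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(f"{len(self.tokens)} tokens but {len(self.labels)} labels")

    def validate_bio(self) -> None:
        prev = "O"
        for lab in self.labels:
            if lab != "O":
                kind, _, cls = lab.partition("-")
                if kind not in ("B", "I") or cls not in LABELS:
                    raise ValueError(f"malformed BIO tag {lab!r}")
                if kind == "I" and prev not in (f"B-{cls}", f"I-{cls}"):
                    raise ValueError(f"I-{cls} not preceded by B-{cls}/I-{cls}")
            prev = lab


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting (raw-text path)
# ---------------------------------------------------------------------------

_PUNCT = set(string.punctuation)
# Clinical section headers ("HISTORY OF PRESENT ILLNESS:") are their own sentences.
_HEADER_RE = re.compile(r"^[A-Z][A-Z0-9 /\-]*:$")
# Sentence boundary inside a line: terminator, whitespace, then an uppercase opener.
_BOUND_RE = re.compile(r"[.?!](?=\s+[A-Z])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return (start, end) character spans of sentences.

    Newlines always terminate a sentence (telegraphic EHR lists); within a
    line, a ``.?!`` followed by whitespace and an uppercase letter splits.
    """
    spans: list[tuple[int, int]] = []
    offset = 0
    for line in text.splitlines(keepends=True):
        raw = line.rstrip("\n")
        stripped = raw.strip()
        if stripped:
            lstart = offset + (len(raw) - len(raw.lstrip()))
            lend = lstart + len(stripped)
            if _HEADER_RE.match(stripped):
                spans.append((lstart, lend))
            else:
                seg_start = lstart
                for m in _BOUND_RE.finditer(text[lstart:lend]):
                    seg_end = lstart + m.end()
                    spans.append((seg_start, seg_end))
                    nxt = seg_end
                    while nxt < lend and text[nxt].isspace():
                        nxt += 1
                    seg_start = nxt
                if seg_start < lend:
                    spans.append((seg_start, lend))
        offset += len(line)
    return spans


def _tokenize_span(text: str, start: int, end: int) -> list[Token]:
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text[start:end]):
        w = m.group()
        s = start + m.start()
        a, b = 0, len(w)
        while a < b and w[a] in _PUNCT:
            a += 1
        while b > a and w[b - 1] in _PUNCT:
            b -= 1
        for j in range(a):
            tokens.append(Token(w[j], s + j, s + j + 1, pos=w[j]))
        if a < b:
            tokens.append(Token(w[a:b], s + a, s + b))
        for j in range(b, len(w)):
            tokens.append(Token(w[j], s + j, s + j + 1, pos=w[j]))
    return tokens


def tokenize_document(doc_id: str, text: str, style: str = "discharge") -> Document:
    """Whitespace + punctuation-peeling tokenizer over split sentences.

    Tokens carry no POS/chunk tags on this path; pre-tagged CoNLL input or
    the synthetic generator supply those.
    """
    sentences = []
    for i, (s, e) in enumerate(split_sentences(text)):
        toks = _tokenize_span(text, s, e)
        if toks:
            sentences.append(Sentence(toks, index=len(sentences)))
    return Document(doc_id=doc_id, text=text, style=style, sentences=sentences)


def validate_document(doc: Document) -> None:
    """Check token/sentence invariants; raises ValueError on violation."""
    prev_end = -1
    for sent in doc.sentences:
        if not sent.tokens:
            raise ValueError(f"{doc.doc_id}: empty sentence {sent.index}")
        for tok in sent.tokens:
            if doc.text[tok.start:tok.end] != tok.text:
                raise ValueError(
                    f"{doc.doc_id}: token {tok.text!r} does not match slice "
                    f"{doc.text[tok.start:tok.end]!r} at [{tok.start},{tok.end})"
                )
            if tok.start < prev_end:
                raise ValueError(f"{doc.doc_id}: overlapping/unsorted token at {tok.start}")
            prev_end = tok.end


# ---------------------------------------------------------------------------
# BIO encoding/decoding
# ---------------------------------------------------------------------------


def to_bio(document: Document, mentions: Iterable[EntityMention]) -> list[SequenceExample]:
    """Project mentions onto per-sentence BIO tag sequences.

    Mentions whose boundaries fall mid-token are snapped outward to token
    boundaries (with a warning): any token partially covered by a mention is
    considered inside it.  Overlapping mentions and mentions crossing a
    sentence boundary are rejected.
    """
    ms = sorted((m for m in mentions), key=lambda m: (m.start, m.end))
    for m in ms:
        if m.doc_id != document.doc_id:
            raise ValueError(f"mention {m} does not belong to document {document.doc_id!r}")
    for a, b in zip(ms, ms[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping mentions: {a} / {b}")

    labels = [["O"] * len(sent.tokens) for sent in document.sentences]
    for m in ms:
        hits: list[tuple[int, int]] = []
        for si, sent in enumerate(document.sentences):
            for ti, tok in enumerate(sent.tokens):
                if tok.start < m.end and tok.end > m.start:
                    hits.append((si, ti))
        if not hits:
            raise ValueError(f"mention {m} covers no token of {document.doc_id!r}")
        if len({si for si, _ in hits}) > 1:
            raise ValueError(f"mention {m} crosses a sentence boundary")
        si = hits[0][0]
        first_tok = document.sentences[si].tokens[hits[0][1]]
        last_tok = document.sentences[si].tokens[hits[-1][1]]
        if first_tok.start != m.start or last_tok.end != m.end:
            log.warning(
                "mention [%d,%d) %r snapped outward to token boundaries [%d,%d)",
                m.start, m.end, m.text, first_tok.start, last_tok.end,
            )
        for k, (_, ti) in enumerate(hits):
            labels[si][ti] = ("B-" if k == 0 else "I-") + m.label

    return [
        SequenceExample(sent.tokens, labels[si])
        for si, sent in enumerate(document.sentences)
    ]


def from_bio(example: SequenceExample, doc_id: str, text: Optional[str] = None) -> list[EntityMention]:
    """Decode BIO tags back to mentions.

    An ``I-`` tag without a matching preceding ``B-``/``I-`` of the same
    class is repaired by treating it as ``B-``.  Mention surfaces are sliced
    from ``text`` when given, else joined from token texts.
    """
    if len(example.tokens) != len(example.labels):
        raise ValueError("token/label length mismatch")
    mentions: list[EntityMention] = []
    run: list[Token] = []
    run_cls = ""

    def close() -> None:
        nonlocal run, run_cls
        if run:
            s, e = run[0].start, run[-1].end
            surface = text[s:e] if text is not None else " ".join(t.text for t in run)
            mentions.append(EntityMention(doc_id, s, e, run_cls, surface))
        run, run_cls = [], ""

    for tok, lab in zip(example.tokens, example.labels):
        if lab == "O":
            close()
            continue
        kind, _, cls = lab.partition("-")
        if kind not in ("B", "I") or cls not in LABELS:
            raise ValueError(f"malformed BIO tag {lab!r}")
        if kind == "B" or cls != run_cls or not run:
            close()
            run_cls = cls
        run.append(tok)
    close()
    return mentions


# ---------------------------------------------------------------------------
# Standoff I/O (brat-compatible T-lines)
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^T\d+$")


def read_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    doc_id: Optional[str] = None,
    style: str = "discharge",
    annotator_id: str = "gold",
) -> tuple[Document, AnnotationSet]:
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    did = doc_id if doc_id is not None else text_path.stem
    doc = tokenize_document(did, text, style=style)
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        head = line.split("\t", 1)[0]
        if not _T_LINE.match(head):
            continue  # relation/attribute lines are out of scope
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError("expected 'T<n>\\tLabel start end\\tsurface'", lineno)
        try:
            label, s_str, e_str = parts[1].split()
            s, e = int(s_str), int(e_str)
        except ValueError:
            raise FormatError(f"malformed span field {parts[1]!r}", lineno) from None
        if label not in LABELS:
            raise FormatError(f"unknown label {label!r}", lineno)
        if not (0 <= s < e <= len(text)):
            raise FormatError(f"offsets [{s},{e}) outside text of length {len(text)}", lineno)
        if text[s:e] != parts[2]:
            raise FormatError(
                f"surface mismatch: annotation says {parts[2]!r}, text slice is {text[s:e]!r}", lineno
            )
        mentions.append(EntityMention(did, s, e, label, parts[2]))
    return doc, AnnotationSet(mentions, annotator_id=annotator_id)


def write_standoff(
    doc: Document,
    mentions: Iterable[EntityMention],
    text_path: str | Path,
    ann_path: str | Path,
) -> None:
    Path(text_path).write_text(doc.text, encoding="utf-8")
    lines = []
    for i, m in enumerate(sorted(mentions, key=lambda m: (m.start, m.end, m.label)), 1):
        lines.append(f"T{i}\t{m.label} {m.start} {m.end}\t{doc.text[m.start:m.end]}")
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-style TSV I/O
# ---------------------------------------------------------------------------


def read_conll(path: str | Path) -> tuple[list[Document], Optional[AnnotationSet]]:
    """Read the tab-separated dialect: token, start, end, pos, chunk[, label].

    Blank line = sentence break; ``#doc <id> <style>`` lines start a new
    document.  Returns the documents plus an AnnotationSet decoded from the
    label column, or None when no label column is present.
    """
    docs: list[Document] = []
    mentions: list[EntityMention] = []
    has_labels: Optional[bool] = None

    cur_id, cur_style = None, "discharge"
    cur_sents: list[list[tuple[Token, Optional[str]]]] = []
    cur_rows: list[tuple[Token, Optional[str]]] = []

    def close_sentence() -> None:
        nonlocal cur_rows
        if cur_rows:
            cur_sents.append(cur_rows)
            cur_rows = []

    def close_doc() -> None:
        nonlocal cur_sents
        close_sentence()
        if cur_id is None:
            if cur_sents:
                raise FormatError("token rows before any '#doc' header")
            return
        max_end = max((t.end for rows in cur_sents for t, _ in rows), default=0)
        chars = [" "] * max_end
        for rows in cur_sents:
            for t, _ in rows:
                chars[t.start:t.end] = list(t.text)
        text = "".join(chars)
        sentences = [Sentence([t for t, _ in rows], index=i) for i, rows in enumerate(cur_sents)]
        doc = Document(cur_id, text, style=cur_style, sentences=sentences)
        docs.append(doc)
        for rows, sent in zip(cur_sents, sentences):
            labs = [lab for _, lab in rows]
            if any(lab is not None for lab in labs):
                ex = SequenceExample(sent.tokens, [lab or "O" for lab in labs])
                mentions.extend(from_bio(ex, cur_id, text=text))
        cur_sents = []

    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if line.startswith("#doc"):
            close_doc()
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("'#doc' header needs a document id", lineno)
            cur_id = parts[1]
            cur_style = parts[2] if len(parts) > 2 else "discharge"
            continue
        if not line.strip():
            close_sentence()
            continue
        cols = line.split("\t")
        if len(cols) not in (5, 6):
            raise FormatError(f"expected 5 or 6 tab-separated columns, got {len(cols)}", lineno)
        row_has_label = len(cols) == 6
        if has_labels is None:
            has_labels = row_has_label
        elif has_labels != row_has_label:
            raise FormatError("inconsistent column count (label column must be all-or-none)", lineno)
        try:
            tok = Token(cols[0], int(cols[1]), int(cols[2]), pos=cols[3], chunk=cols[4])
        except ValueError as exc:
            raise FormatError(str(exc), lineno) from None
        cur_rows.append((tok, cols[5] if row_has_label else None))
    close_doc()

    annset = AnnotationSet(mentions) if has_labels else None
    return docs, annset


def write_conll(
    docs: Iterable[Document],
    path: str | Path,
    gold: Optional[AnnotationSet] = None,
) -> None:
    """Write documents in the CoNLL-style dialect; include a label column iff gold given."""
    lines: list[str] = []
    for doc in docs:
        lines.append(f"#doc {doc.doc_id} {doc.style}")
        bio = to_bio(doc, gold.for_doc(doc.doc_id)) if gold is not None else None
        for si, sent in enumerate(doc.sentences):
            for ti, tok in enumerate(sent.tokens):
                row = [tok.text, str(tok.start), str(tok.end), tok.pos, tok.chunk]
                if bio is not None:
                    row.append(bio[si].labels[ti])
                lines.append("\t".join(row))
            lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Lexicon-based document selection
# ---------------------------------------------------------------------------


def select_documents(docs: Iterable[Document], lexicon: Iterable[str]) -> list[Document]:
    """Keep documents mentioning at least one target-disease term.

    Single-word entries (acronyms like ``CRF``) must match a whole token,
    case-insensitively; multiword terms (``renal insufficiency``) match as
    substrings of the text.  Order is preserved.
    """
    terms = [t.strip() for t in lexicon if t.strip()]
    if not terms:
        raise ValueError("empty selection lexicon")
    single = {t.lower() for t in terms if " " not in t}
    multi = [t.lower() for t in terms if " " in t]
    selected = []
    for doc in docs:
        token_set = {t.text.lower() for t in doc.tokens()}
        low = doc.text.lower()
        if (single & token_set) or any(m in low for m in multi):
            selected.append(doc)
    return selected
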