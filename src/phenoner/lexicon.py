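"""Gazetteer tagger: dictionary lookup with semantic-type filtering.

This is the dictionary baseline of the toolkit: a term list mapping surface
terms to semantic types, scanned over documents by greedy longest match.
Only entries whose semantic type is in the allowed set produce mentions,
mirroring how concept taggers are restricted to the disorder semantic group
when extracting phenotypes.  Matching is deliberately literal: misspelled
tokens ("aneamia" for "anaemia") and multiword expressions absent from the
dictionary are missed — properties of dictionary baselines this module is
meant to exhibit, not to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .docmodel import FormatError, Document, EntityMention


@dataclass
class Lexicon:
    """Term → semantic-type entries, indexed by first token for scanning."""

    entries: list[tuple[str, str]]
    allowed_semtypes: Optional[frozenset[str]] = None  # None = all allowed
    _index: dict[str, list[tuple[tuple[str, ...], str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for term, semtype in self.entries:
            if not term.strip():
                raise ValueError("empty lexicon term")
            toks = tuple(term.lower().split())
            self._index.setdefault(toks[0], []).append((toks, semtype))
        # longest candidate first within each bucket; ties keep file order
        for bucket in self._index.values():
            bucket.sort(key=lambda e: -len(e[0]))

    def restrict(self, allowed_semtypes: Iterable[str]) -> "Lexicon":
        return Lexicon(list(self.entries), frozenset(allowed_semtypes))


def load_lexicon(path: str | Path, allowed_semtypes: Optional[Iterable[str]] = None) -> Lexicon:
    """Load a TSV lexicon: ``term<TAB>semtype`` per line."""
    entries: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2 or not cols[0].strip() or not cols[1].strip():
            raise FormatError("expected 'term<TAB>semtype'", lineno)
        entries.append((cols[0].strip(), cols[1].strip()))
    if not entries:
        raise FormatError(f"lexicon file {path} has no entries")
    return Lexicon(entries, frozenset(allowed_semtypes) if allowed_semtypes is not None else None)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lines = [f"{term}\t{semtype}" for term, semtype in lexicon.entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def tag_with_lexicon(
    doc: Document,
    lexicon: Lexicon,
    class_map: Optional[dict[str, str]] = None,
    default_label: str = "SignSymptom",
) -> list[EntityMention]:
    """Greedy longest-match scan; sets ``Token.sem`` on matched tokens.

    ``class_map`` maps semantic types to phenotype classes; unmapped allowed
    types fall back to ``default_label``.  Output mentions never overlap.
    """
    class_map = class_map or {}
    mentions: list[EntityMention] = []
    for sent in doc.sentences:
        toks = sent.tokens
        i = 0
        while i < len(toks):
            bucket = lexicon._index.get(toks[i].text.lower(), [])
            hit: Optional[tuple[int, str]] = None
            for entry_toks, semtype in bucket:
                if lexicon.allowed_semtypes is not None and semtype not in lexicon.allowed_semtypes:
                    continue
                n = len(entry_toks)
                if i + n <= len(toks) and all(
                    toks[i + k].text.lower() == entry_toks[k] for k in range(n)
                ):
                    hit = (n, semtype)
                    break  # buckets are sorted longest-first
            if hit is None:
                i += 1
                continue
            n, semtype = hit
            for k in range(n):
                toks[i + k].sem = semtype
            label = class_map.get(semtype, default_label)
            s, e = toks[i].start, toks[i + n - 1].end
            mentions.append(EntityMention(doc.doc_id, s, e, label, doc.text[s:e]))
            i += n
    return mentions
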