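"""Shared feature extraction for all sequence labelers.

All three labelers consume the same binary indicator features so their
comparison is a fair one: bag-of-words token identities, POS and chunk tags
in a symmetric context window, a compressed word-shape class, and affix
features drawn from a registry of prefixes/suffixes (lengths two to five)
compiled from the tokens inside gold training mentions.  The registry turns
productive morphology — *hyper-* in "hypertension", *-emia* in "lipidemia"
and "anemia" — into look-up features without an open affix vocabulary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from .docmodel import AnnotationSet, Document, Sentence, Token

log = logging.getLogger(__name__)

AFFIX_MIN_LEN = 2
AFFIX_MAX_LEN = 5


@dataclass
class AffixRegistry:
    """Prefixes/suffixes of length 2..5 harvested from gold mention tokens."""

    prefixes: set[str] = field(default_factory=set)
    suffixes: set[str] = field(default_factory=set)
    min_len: int = AFFIX_MIN_LEN
    max_len: int = AFFIX_MAX_LEN

    def add_token(self, text: str) -> None:
        t = text.lower()
        for n in range(self.min_len, min(self.max_len, len(t)) + 1):
            self.prefixes.add(t[:n])
            self.suffixes.add(t[-n:])

    def token_prefixes(self, text: str) -> list[str]:
        t = text.lower()
        return [t[:n] for n in range(self.min_len, min(self.max_len, len(t)) + 1) if t[:n] in self.prefixes]

    def token_suffixes(self, text: str) -> list[str]:
        t = text.lower()
        return [t[-n:] for n in range(self.min_len, min(self.max_len, len(t)) + 1) if t[-n:] in self.suffixes]


def compile_affix_registry(gold: AnnotationSet, docs: Iterable[Document]) -> AffixRegistry:
    """Collect all affixes of tokens covered by gold mentions.

    A token counts as covered when it overlaps a mention by at least one
    character.  An empty gold set yields an empty registry with a warning.
    """
    registry = AffixRegistry()
    any_mention = False
    for doc in docs:
        mentions = gold.for_doc(doc.doc_id)
        if not mentions:
            continue
        any_mention = True
        for tok in doc.tokens():
            if any(tok.start < m.end and tok.end > m.start for m in mentions):
                registry.add_token(tok.text)
    if not any_mention:
        log.warning("affix registry compiled from an empty gold set")
    return registry


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families to emit and how wide the context window is."""

    use_bow: bool = True
    use_pos: bool = True
    use_chunk: bool = True
    use_affix: bool = True
    use_shape: bool = True
    window: int = 2

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def word_shape(text: str) -> str:
    """Compressed character-class pattern: 'Hypertension' -> 'Xx', '10mg' -> 'dx'."""
    out = []
    for ch in text:
        cls = "X" if ch.isupper() else "x" if ch.islower() else "d" if ch.isdigit() else "p"
        if not out or out[-1] != cls:
            out.append(cls)
    return "".join(out)


BOS = "<s>"
EOS = "</s>"


def extract_features(
    sentence: Sentence,
    i: int,
    config: FeatureConfig,
    registry: Optional[AffixRegistry] = None,
) -> dict[str, int]:
    """Binary indicator features for position ``i`` of a sentence.

    Deterministic in its inputs; positions off the sentence edge emit
    boundary markers so window features stay well-defined everywhere.
    Affix features fire at the focus position only, and only for registry
    members.
    """
    if not (0 <= i < len(sentence.tokens)):
        raise IndexError(f"position {i} outside sentence of length {len(sentence.tokens)}")
    if config.use_affix and registry is None:
        raise ValueError("use_affix requires an AffixRegistry")
    feats: dict[str, int] = {}
    for off in range(-config.window, config.window + 1):
        j = i + off
        if 0 <= j < len(sentence.tokens):
            tok = sentence.tokens[j]
            word, pos, chunk, shape = tok.text.lower(), tok.pos, tok.chunk, word_shape(tok.text)
        else:
            word = pos = chunk = shape = BOS if j < 0 else EOS
        if config.use_bow:
            feats[f"bow[{off}]={word}"] = 1
        if config.use_pos:
            feats[f"pos[{off}]={pos}"] = 1
        if config.use_chunk:
            feats[f"chunk[{off}]={chunk}"] = 1
        if config.use_shape:
            feats[f"shape[{off}]={shape}"] = 1
    if config.use_affix:
        focus = sentence.tokens[i].text
        for p in registry.token_prefixes(focus):
            feats[f"prefix={p}"] = 1
        for s in registry.token_suffixes(focus):
            feats[f"suffix={s}"] = 1
    return feats
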