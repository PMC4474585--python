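"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from phenoner.docmodel import Document, Sentence, Token


def build_sentence(words_pos, start: int = 0, index: int = 0) -> Sentence:
    """Sentence from (word, pos) pairs, tokens separated by single spaces."""
    tokens = []
    pos_cursor = start
    for w, p in words_pos:
        tokens.append(Token(w, pos_cursor, pos_cursor + len(w), pos=p))
        pos_cursor += len(w) + 1
    return Sentence(tokens, index=index)


def build_doc(sentences_spec, doc_id: str = "d1", style: str = "discharge") -> Document:
    """Document from a list of sentences, each a list of (word, pos) pairs."""
    sentences = []
    cursor = 0
    parts = []
    for i, words_pos in enumerate(sentences_spec):
        sent = build_sentence(words_pos, start=cursor, index=i)
        sentences.append(sent)
        parts.append(" ".join(w for w, _ in words_pos))
        cursor = sent.end + 1
    return Document(doc_id, "\n".join(parts) + "\n", style=style, sentences=sentences)


@pytest.fixture
def tiny_doc() -> Document:
    return build_doc(
        [
            [("heart", "NN"), ("is", "VBZ"), ("enlarged", "VBN"), (".", ".")],
            [("no", "DT"), ("chest", "NN"), ("pain", "NN"), (".", ".")],
        ]
    )
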