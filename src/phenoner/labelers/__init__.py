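"""Sequence labelers over BIO tags: feature-augmented HMM, MEMM, linear-chain CRF."""

from __future__ import annotations

from typing import Optional, Union

from ..docmodel import Document, EntityMention, Sentence, SequenceExample, from_bio
from .base import (
    ConvergenceError,
    bio_tags,
    lattice_score,
    load_model,
    save_model,
    transition_masks,
    viterbi_path,
)
from .crf import CrfModel, train_crf
from .hmm import HmmModel, train_hmm
from .memm import MemmModel, train_memm

Model = Union[HmmModel, MemmModel, CrfModel]

TRAINERS = {"hmm": train_hmm, "memm": train_memm, "crf": train_crf}


def viterbi_decode(model: Model, sentence: Sentence) -> list[str]:
    """Best BIO tag path for one sentence under any of the three models."""
    return model.decode(sentence)


def predict(model: Model, doc: Document) -> list[EntityMention]:
    """Decode every sentence and convert tag runs back into mentions."""
    mentions: list[EntityMention] = []
    for sent in doc.sentences:
        tags = model.decode(sent)
        ex = SequenceExample(sent.tokens, tags)
        mentions.extend(from_bio(ex, doc.doc_id, text=doc.text))
    return mentions


__all__ = [
    "ConvergenceError",
    "CrfModel",
    "HmmModel",
    "MemmModel",
    "Model",
    "TRAINERS",
    "bio_tags",
    "lattice_score",
    "load_model",
    "predict",
    "save_model",
    "train_crf",
    "train_hmm",
    "train_memm",
    "transition_masks",
    "viterbi_decode",
    "viterbi_path",
]
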