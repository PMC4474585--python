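"""Shared machinery for the sequence labelers: tag set, Viterbi, serialization.

Every labeler reduces decoding to the same lattice form: a vector of scores
for the first position and, for each later position, a matrix of scores for
(previous label, label) pairs.  :func:`viterbi_path` finds an argmax path
over that lattice; ties are broken toward the lexicographically smallest
label because the tag list is kept sorted and ``argmax`` returns the first
maximum.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from ..docmodel import LABELS

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: Additive penalty for transitions that are structurally illegal in BIO.
NEG_INF = -1.0e30


class ConvergenceError(RuntimeError):
    """Raised when an optimizer stops above its gradient-norm tolerance."""


def bio_tags(labels: Sequence[str] = LABELS) -> list[str]:
    """The 9-tag BIO expansion of the phenotype classes, sorted."""
    tags = ["O"] + [f"{p}-{c}" for c in labels for p in ("B", "I")]
    return sorted(tags)


def transition_masks(tags: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(init_ok, trans_ok) boolean masks enforcing valid BIO structure.

    ``I-x`` may not start a sequence and may only follow ``B-x``/``I-x``.
    """
    k = len(tags)
    init_ok = np.array([not t.startswith("I-") for t in tags])
    trans_ok = np.ones((k, k), dtype=bool)
    for j, t in enumerate(tags):
        if not t.startswith("I-"):
            continue
        cls = t[2:]
        for i, p in enumerate(tags):
            if p not in (f"B-{cls}", f"I-{cls}"):
                trans_ok[i, j] = False
    return init_ok, trans_ok


def viterbi_path(score0: np.ndarray, scores: np.ndarray) -> list[int]:
    """Argmax path over a lattice.

    ``score0``: (K,) scores of labels at position 0.
    ``scores``: (T-1, K, K) scores of (previous, current) label pairs.
    Returns label indices of length T = scores.shape[0] + 1.
    """
    t_total = scores.shape[0] + 1
    delta = score0.astype(float).copy()
    back = np.empty((t_total - 1, score0.shape[0]), dtype=np.int64)
    for t in range(1, t_total):
        m = delta[:, None] + scores[t - 1]
        back[t - 1] = np.argmax(m, axis=0)
        delta = np.max(m, axis=0)
    path = [int(np.argmax(delta))]
    for t in range(t_total - 2, -1, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path


def lattice_score(score0: np.ndarray, scores: np.ndarray, path: Sequence[int]) -> float:
    """Score of a label path under the same lattice viterbi_path searches."""
    total = float(score0[path[0]])
    for t in range(1, len(path)):
        total += float(scores[t - 1, path[t - 1], path[t]])
    return total


def save_model(model, path: str | Path) -> None:
    payload = model.to_dict()
    payload["format_version"] = FORMAT_VERSION
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path):
    """Load any serialized labeler; verifies version and feature-config hash."""
    from .hmm import HmmModel
    from .memm import MemmModel
    from .crf import CrfModel

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')!r}")
    kinds = {"hmm": HmmModel, "memm": MemmModel, "crf": CrfModel}
    kind = payload.get("model_type")
    if kind not in kinds:
        raise ValueError(f"unknown model type {kind!r}")
    model = kinds[kind].from_dict(payload)
    if model.config.config_hash() != payload.get("config_hash"):
        raise ValueError("feature-config hash mismatch: model was trained with a different config")
    return model
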