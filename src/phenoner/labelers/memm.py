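"""Maximum-entropy Markov model: local multinomial logistic steps.

Each position is classified by an L2-penalized maximum-entropy model over
(observation features ∪ one previous-label indicator); the first position
conditions on a synthetic START label.  The per-position objective is the
mean conditional negative log-likelihood

    J(W) = -(1/N) Σ_i log P(y_i | x_i, y_{i-1}) + (λ/2N) ||W||²

which is smooth and strictly convex, so the L-BFGS optimum is unique.
Training fails loudly (with the final gradient norm) if the optimizer stops
above the gradient tolerance.

MEMMs normalize each step locally, which is exactly what exposes them to
the label-bias problem: probability mass is renormalized among a state's
outgoing transitions, so states with few successors absorb mass regardless
of the observations.  The model is kept faithful to that behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

from ..docmodel import Sentence, SequenceExample
from ..features import AffixRegistry, FeatureConfig, extract_features
from .base import NEG_INF, ConvergenceError, bio_tags, transition_masks, viterbi_path

START = "<START>"


def _prev_feature(label: str) -> str:
    return f"prev={label}"


@dataclass
class MemmModel:
    labels: list[str]
    feat_vocab: dict[str, int]
    weights: np.ndarray  # (F, K)
    lam: float
    config: FeatureConfig
    registry: Optional[AffixRegistry] = None

    def _obs_indices(self, sentence: Sentence) -> list[list[int]]:
        rows = []
        for i in range(len(sentence.tokens)):
            feats = extract_features(sentence, i, self.config, self.registry)
            rows.append([self.feat_vocab[f] for f in feats if f in self.feat_vocab])
        return rows

    def lattice(self, sentence: Sentence) -> tuple[np.ndarray, np.ndarray]:
        """Log conditional distributions arranged for Viterbi, BIO-masked."""
        k = len(self.labels)
        rows = self._obs_indices(sentence)
        t_len = len(rows)
        base = np.zeros((t_len, k))
        for t, idxs in enumerate(rows):
            if idxs:
                base[t] = self.weights[idxs].sum(axis=0)
        prev_rows = np.zeros((k + 1, k))  # one extra row for START
        for p, lab in enumerate(self.labels + [START]):
            f = self.feat_vocab.get(_prev_feature(lab))
            if f is not None:
                prev_rows[p] = self.weights[f]
        init_ok, trans_ok = transition_masks(self.labels)
        logits0 = base[0] + prev_rows[k]
        score0 = logits0 - logsumexp(logits0)
        score0 = np.where(init_ok, score0, NEG_INF)
        scores = np.empty((t_len - 1, k, k))
        for t in range(1, t_len):
            logits = base[t][None, :] + prev_rows[:k]  # (K prev, K)
            cond = logits - logsumexp(logits, axis=1, keepdims=True)
            scores[t - 1] = np.where(trans_ok, cond, NEG_INF)
        return score0, scores

    def decode(self, sentence: Sentence) -> list[str]:
        if not sentence.tokens:
            return []
        score0, scores = self.lattice(sentence)
        return [self.labels[i] for i in viterbi_path(score0, scores)]

    def to_dict(self) -> dict:
        return {
            "model_type": "memm",
            "labels": self.labels,
            "feat_vocab": list(self.feat_vocab.keys()),
            "weights": self.weights.tolist(),
            "lam": self.lam,
            "feature_config": self.config.__dict__,
            "config_hash": self.config.config_hash(),
            "registry": {
                "prefixes": sorted(self.registry.prefixes),
                "suffixes": sorted(self.registry.suffixes),
            }
            if self.registry is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemmModel":
        reg = d.get("registry")
        return cls(
            labels=list(d["labels"]),
            feat_vocab={f: i for i, f in enumerate(d["feat_vocab"])},
            weights=np.asarray(d["weights"]),
            lam=float(d["lam"]),
            config=FeatureConfig(**d["feature_config"]),
            registry=AffixRegistry(set(reg["prefixes"]), set(reg["suffixes"])) if reg else None,
        )


def train_memm(
    examples: Sequence[SequenceExample],
    config: FeatureConfig = FeatureConfig(),
    registry: Optional[AffixRegistry] = None,
    lam: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> MemmModel:
    """Fit the local maxent classifier by L-BFGS on the convex objective."""
    if not examples:
        raise ValueError("empty training set")
    labels = bio_tags()
    lidx = {s: i for i, s in enumerate(labels)}
    k = len(labels)

    feat_vocab: dict[str, int] = {}
    rows: list[list[int]] = []
    targets: list[int] = []
    for ex in examples:
        sent = Sentence(ex.tokens)
        prev = START
        for i, lab in enumerate(ex.labels):
            feats = extract_features(sent, i, config, registry)
            feats[_prev_feature(prev)] = 1
            idxs = []
            for f in feats:
                if f not in feat_vocab:
                    feat_vocab[f] = len(feat_vocab)
                idxs.append(feat_vocab[f])
            rows.append(idxs)
            targets.append(lidx[lab])
            prev = lab

    n, f_size = len(rows), len(feat_vocab)
    indptr = np.cumsum([0] + [len(r) for r in rows])
    indices = np.concatenate([np.asarray(r, dtype=np.int32) for r in rows])
    x = sp.csr_matrix(
        (np.ones(len(indices)), indices, indptr), shape=(n, f_size)
    )
    y = np.asarray(targets)
    y_onehot = sp.csr_matrix(
        (np.ones(n), (np.arange(n), y)), shape=(n, k)
    )

    def objective(w_flat: np.ndarray) -> tuple[float, np.ndarray]:
        w = w_flat.reshape(f_size, k)
        logits = x @ w
        lse = logsumexp(logits, axis=1)
        nll = (lse.sum() - logits[np.arange(n), y].sum()) / n
        p = np.exp(logits - lse[:, None])
        grad = (x.T @ (p - y_onehot.toarray())) / n + (lam / n) * w
        loss = nll + 0.5 * lam / n * float(np.sum(w * w))
        return loss, grad.ravel()

    res = scipy.optimize.minimize(
        objective,
        np.zeros(f_size * k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-12, "gtol": tol / 10},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > tol:
        raise ConvergenceError(
            f"MEMM training stopped after {res.nit} iterations with gradient norm "
            f"{grad_norm:.2e} > tolerance {tol:.0e}"
        )
    return MemmModel(
        labels=labels,
        feat_vocab=feat_vocab,
        weights=res.x.reshape(f_size, k),
        lam=lam,
        config=config,
        registry=registry,
    )
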