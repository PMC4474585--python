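"""Linear-chain conditional random field.

Globally normalized sequence model over the 9-tag BIO space:

    P(y | x) ∝ exp( Σ_t  w_obs·f(x, t, y_t) + w_trans[y_{t-1}, y_t] )

with a dedicated START row for the first transition.  Training minimizes
the mean negative conditional log-likelihood plus an L2 penalty; gradients
come from forward-backward marginals and the convex optimization is
delegated to L-BFGS.  Observation features are the shared
:func:`~phenoner.features.extract_features` layer, identical to the MEMM's,
so differences between the two models isolate global vs. local
normalization (the label-bias axis).  Transitions are left soft: invalid
BIO continuations are merely discouraged by the data, and any stray ``I-``
tag is repaired downstream by the BIO decoder.
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
from .base import ConvergenceError, bio_tags, viterbi_path


@dataclass
class CrfModel:
    labels: list[str]
    feat_vocab: dict[str, int]
    w_obs: np.ndarray  # (F, K)
    w_trans: np.ndarray  # (K+1, K); last row is START
    lam: float
    config: FeatureConfig
    registry: Optional[AffixRegistry] = None

    def _emissions(self, sentence: Sentence) -> np.ndarray:
        k = len(self.labels)
        emis = np.zeros((len(sentence.tokens), k))
        for t in range(len(sentence.tokens)):
            feats = extract_features(sentence, t, self.config, self.registry)
            idxs = [self.feat_vocab[f] for f in feats if f in self.feat_vocab]
            if idxs:
                emis[t] = self.w_obs[idxs].sum(axis=0)
        return emis

    def lattice(self, sentence: Sentence) -> tuple[np.ndarray, np.ndarray]:
        emis = self._emissions(sentence)
        k = len(self.labels)
        score0 = self.w_trans[k] + emis[0]
        scores = self.w_trans[:k][None, :, :] + emis[1:, None, :]
        return score0, scores

    def decode(self, sentence: Sentence) -> list[str]:
        if not sentence.tokens:
            return []
        score0, scores = self.lattice(sentence)
        return [self.labels[i] for i in viterbi_path(score0, scores)]

    def to_dict(self) -> dict:
        return {
            "model_type": "crf",
            "labels": self.labels,
            "feat_vocab": list(self.feat_vocab.keys()),
            "w_obs": self.w_obs.tolist(),
            "w_trans": self.w_trans.tolist(),
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
    def from_dict(cls, d: dict) -> "CrfModel":
        reg = d.get("registry")
        return cls(
            labels=list(d["labels"]),
            feat_vocab={f: i for i, f in enumerate(d["feat_vocab"])},
            w_obs=np.asarray(d["w_obs"]),
            w_trans=np.asarray(d["w_trans"]),
            lam=float(d["lam"]),
            config=FeatureConfig(**d["feature_config"]),
            registry=AffixRegistry(set(reg["prefixes"]), set(reg["suffixes"])) if reg else None,
        )


def _forward_backward(emis: np.ndarray, trans: np.ndarray, start: np.ndarray):
    """Log-space forward/backward; returns (logZ, unary marginals, pairwise marginals)."""
    t_len, k = emis.shape
    alpha = np.empty((t_len, k))
    alpha[0] = start + emis[0]
    for t in range(1, t_len):
        alpha[t] = emis[t] + logsumexp(alpha[t - 1][:, None] + trans, axis=0)
    beta = np.zeros((t_len, k))
    for t in range(t_len - 2, -1, -1):
        beta[t] = logsumexp(trans + (emis[t + 1] + beta[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(alpha[-1]))
    unary = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((k + 1, k))
    pairwise[k] = unary[0]
    for t in range(1, t_len):
        m = alpha[t - 1][:, None] + trans + (emis[t] + beta[t])[None, :] - log_z
        pairwise[:k] += np.exp(m)
    return log_z, unary, pairwise


def train_crf(
    examples: Sequence[SequenceExample],
    config: FeatureConfig = FeatureConfig(),
    registry: Optional[AffixRegistry] = None,
    lam: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> CrfModel:
    """Fit by L-BFGS on the mean penalized negative log-likelihood."""
    if not examples:
        raise ValueError("empty training set")
    labels = bio_tags()
    lidx = {s: i for i, s in enumerate(labels)}
    k = len(labels)

    feat_vocab: dict[str, int] = {}
    sent_rows: list[list[list[int]]] = []
    sent_targets: list[np.ndarray] = []
    for ex in examples:
        if not ex.tokens:
            continue
        sent = Sentence(ex.tokens)
        rows = []
        for i in range(len(ex.tokens)):
            feats = extract_features(sent, i, config, registry)
            idxs = []
            for f in feats:
                if f not in feat_vocab:
                    feat_vocab[f] = len(feat_vocab)
                idxs.append(feat_vocab[f])
            rows.append(idxs)
        sent_rows.append(rows)
        sent_targets.append(np.asarray([lidx[lab] for lab in ex.labels]))

    f_size = len(feat_vocab)
    n = sum(len(r) for r in sent_rows)
    flat_rows = [r for rows in sent_rows for r in rows]
    indptr = np.cumsum([0] + [len(r) for r in flat_rows])
    indices = np.concatenate([np.asarray(r, dtype=np.int32) for r in flat_rows])
    x = sp.csr_matrix((np.ones(len(indices)), indices, indptr), shape=(n, f_size))
    bounds = np.cumsum([0] + [len(r) for r in sent_rows])
    y_flat = np.concatenate(sent_targets)
    y_onehot = sp.csr_matrix((np.ones(n), (np.arange(n), y_flat)), shape=(n, k)).toarray()

    # gold transition counts are constant across iterations
    gold_trans = np.zeros((k + 1, k))
    for tgt in sent_targets:
        gold_trans[k, tgt[0]] += 1
        for a, b in zip(tgt[:-1], tgt[1:]):
            gold_trans[a, b] += 1

    n_params = f_size * k + (k + 1) * k

    def objective(w_flat: np.ndarray) -> tuple[float, np.ndarray]:
        w_obs = w_flat[: f_size * k].reshape(f_size, k)
        w_trans = w_flat[f_size * k:].reshape(k + 1, k)
        emis_all = x @ w_obs
        trans, start = w_trans[:k], w_trans[k]
        nll = 0.0
        marg = np.empty_like(emis_all)
        exp_trans = np.zeros((k + 1, k))
        for s in range(len(sent_rows)):
            lo, hi = bounds[s], bounds[s + 1]
            emis = emis_all[lo:hi]
            tgt = sent_targets[s]
            log_z, unary, pairwise = _forward_backward(emis, trans, start)
            gold_score = start[tgt[0]] + emis[np.arange(hi - lo), tgt].sum()
            if hi - lo > 1:
                gold_score += trans[tgt[:-1], tgt[1:]].sum()
            nll += log_z - gold_score
            marg[lo:hi] = unary
            exp_trans += pairwise
        grad_obs = (x.T @ (marg - y_onehot)) / n + (lam / n) * w_obs
        grad_trans = (exp_trans - gold_trans) / n + (lam / n) * w_trans
        loss = nll / n + 0.5 * lam / n * float(np.sum(w_flat * w_flat))
        return loss, np.concatenate([np.asarray(grad_obs).ravel(), grad_trans.ravel()])

    res = scipy.optimize.minimize(
        objective,
        np.zeros(n_params),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-12, "gtol": tol / 10},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > tol:
        raise ConvergenceError(
            f"CRF training stopped after {res.nit} iterations with gradient norm "
            f"{grad_norm:.2e} > tolerance {tol:.0e}"
        )
    w_obs = res.x[: f_size * k].reshape(f_size, k)
    w_trans = res.x[f_size * k:].reshape(k + 1, k)
    return CrfModel(
        labels=labels,
        feat_vocab=feat_vocab,
        w_obs=w_obs,
        w_trans=w_trans,
        lam=lam,
        config=config,
        registry=registry,
    )
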