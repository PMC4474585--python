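"""Feature-augmented hidden Markov model.

A classical HMM emits one symbol per state; clinical NER wants several
observation streams at once (word identity, POS, chunk, shape, affixes).
This model integrates them by factorizing the emission naive-Bayes style:
the per-state emission probability is the product over feature families of
an add-α smoothed categorical, so

    P(obs_t | s) = Π_f P(value_f(t) | s)

Each family contributes one categorical value per token; affix families use
the longest registry prefix/suffix the token bears.  Transitions and the
initial distribution are add-α smoothed maximum-likelihood counts.  Decoding
hard-disallows transitions that would produce invalid BIO output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..docmodel import Sentence, SequenceExample
from ..features import AffixRegistry, FeatureConfig, word_shape
from .base import NEG_INF, bio_tags, transition_masks, viterbi_path

log = logging.getLogger(__name__)


def hmm_observations(
    sentence: Sentence, i: int, config: FeatureConfig, registry: Optional[AffixRegistry]
) -> dict[str, str]:
    """One categorical value per enabled feature family for position i."""
    tok = sentence.tokens[i]
    obs: dict[str, str] = {}
    if config.use_bow:
        obs["word"] = tok.text.lower()
    if config.use_pos:
        obs["pos"] = tok.pos
    if config.use_chunk:
        obs["chunk"] = tok.chunk
    if config.use_shape:
        obs["shape"] = word_shape(tok.text)
    if config.use_affix:
        if registry is None:
            raise ValueError("use_affix requires an AffixRegistry")
        prefixes = registry.token_prefixes(tok.text)
        suffixes = registry.token_suffixes(tok.text)
        obs["prefix"] = max(prefixes, key=len) if prefixes else "-"
        obs["suffix"] = max(suffixes, key=len) if suffixes else "-"
    return obs


@dataclass
class HmmModel:
    states: list[str]
    alpha: float
    log_init: np.ndarray  # (K,)
    log_trans: np.ndarray  # (K, K)
    # family -> (vocab value->index, (K, V) log probs, (K,) log prob of unseen)
    families: dict[str, tuple[dict[str, int], np.ndarray, np.ndarray]]
    seen: np.ndarray  # (K,) bool: state observed in training
    config: FeatureConfig
    registry: Optional[AffixRegistry] = None

    def lattice(self, sentence: Sentence) -> tuple[np.ndarray, np.ndarray]:
        """Decoding lattice: init+emission vector and transition+emission matrices."""
        k = len(self.states)
        t_len = len(sentence.tokens)
        emis = np.zeros((t_len, k))
        for t in range(t_len):
            obs = hmm_observations(sentence, t, self.config, self.registry)
            for fam, value in obs.items():
                vocab, logp, log_unseen = self.families[fam]
                idx = vocab.get(value)
                emis[t] += logp[:, idx] if idx is not None else log_unseen
        init_ok, trans_ok = transition_masks(self.states)
        reachable = self.seen
        score0 = self.log_init + emis[0]
        score0 = np.where(init_ok & reachable, score0, NEG_INF)
        scores = np.empty((t_len - 1, k, k))
        for t in range(1, t_len):
            m = self.log_trans + emis[t][None, :]
            scores[t - 1] = np.where(trans_ok & reachable[None, :], m, NEG_INF)
        return score0, scores

    def decode(self, sentence: Sentence) -> list[str]:
        if not sentence.tokens:
            return []
        score0, scores = self.lattice(sentence)
        return [self.states[i] for i in viterbi_path(score0, scores)]

    def to_dict(self) -> dict:
        return {
            "model_type": "hmm",
            "states": self.states,
            "alpha": self.alpha,
            "log_init": self.log_init.tolist(),
            "log_trans": self.log_trans.tolist(),
            "families": {
                fam: {
                    "vocab": list(vocab.keys()),
                    "log_prob": logp.tolist(),
                    "log_unseen": lu.tolist(),
                }
                for fam, (vocab, logp, lu) in self.families.items()
            },
            "seen": self.seen.tolist(),
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
    def from_dict(cls, d: dict) -> "HmmModel":
        reg = d.get("registry")
        return cls(
            states=list(d["states"]),
            alpha=float(d["alpha"]),
            log_init=np.asarray(d["log_init"]),
            log_trans=np.asarray(d["log_trans"]),
            families={
                fam: (
                    {v: i for i, v in enumerate(f["vocab"])},
                    np.asarray(f["log_prob"]),
                    np.asarray(f["log_unseen"]),
                )
                for fam, f in d["families"].items()
            },
            seen=np.asarray(d["seen"], dtype=bool),
            config=FeatureConfig(**d["feature_config"]),
            registry=AffixRegistry(set(reg["prefixes"]), set(reg["suffixes"])) if reg else None,
        )


def train_hmm(
    examples: Sequence[SequenceExample],
    config: FeatureConfig = FeatureConfig(),
    registry: Optional[AffixRegistry] = None,
    alpha: float = 0.1,
) -> HmmModel:
    """Smoothed maximum-likelihood estimation of all probability tables."""
    if not examples:
        raise ValueError("empty training set")
    states = bio_tags()
    sidx = {s: i for i, s in enumerate(states)}
    k = len(states)

    init_counts = np.zeros(k)
    trans_counts = np.zeros((k, k))
    state_totals = np.zeros(k)
    fam_counts: dict[str, dict[str, np.ndarray]] = {}

    for ex in examples:
        sent = Sentence(ex.tokens)
        prev = None
        for t, lab in enumerate(ex.labels):
            s = sidx[lab]
            state_totals[s] += 1
            if prev is None:
                init_counts[s] += 1
            else:
                trans_counts[prev, s] += 1
            prev = s
            for fam, value in hmm_observations(sent, t, config, registry).items():
                fam_counts.setdefault(fam, {}).setdefault(value, np.zeros(k))[s] += 1

    unseen_states = [states[i] for i in range(k) if state_totals[i] == 0]
    if unseen_states:
        log.warning("labels absent from training are unreachable at decode: %s", unseen_states)

    log_init = np.log(init_counts + alpha) - np.log(init_counts.sum() + alpha * k)
    log_trans = np.log(trans_counts + alpha) - np.log(
        trans_counts.sum(axis=1, keepdims=True) + alpha * k
    )

    families: dict[str, tuple[dict[str, int], np.ndarray, np.ndarray]] = {}
    for fam, value_counts in fam_counts.items():
        vocab = {v: i for i, v in enumerate(sorted(value_counts))}
        v_size = len(vocab)
        counts = np.zeros((k, v_size))
        for v, per_state in value_counts.items():
            counts[:, vocab[v]] = per_state
        denom = np.log(state_totals + alpha * (v_size + 1))[:, None]
        logp = np.log(counts + alpha) - denom
        log_unseen = np.log(alpha) - denom[:, 0]
        families[fam] = (vocab, logp, log_unseen)

    return HmmModel(
        states=states,
        alpha=alpha,
        log_init=log_init,
        log_trans=log_trans,
        families=families,
        seen=state_totals > 0,
        config=config,
        registry=registry,
    )
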