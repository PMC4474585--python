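"""Sequence labelers: estimation correctness, decoding optimality, round trips."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phenoner.docmodel import SequenceExample, Token
from phenoner.features import AffixRegistry, FeatureConfig, extract_features
from phenoner.labelers import (
    CrfModel,
    HmmModel,
    MemmModel,
    bio_tags,
    lattice_score,
    load_model,
    predict,
    save_model,
    train_crf,
    train_hmm,
    train_memm,
    viterbi_path,
)
from phenoner.labelers.memm import START, _prev_feature

from conftest import build_doc, build_sentence

BOW_ONLY = FeatureConfig(use_bow=True, use_pos=False, use_chunk=False,
                         use_affix=False, use_shape=False, window=0)

TAGS = bio_tags()


def example(words, labels):
    sent = build_sentence([(w, "NN") for w in words])
    return SequenceExample(sent.tokens, labels)


def exhaustive_best_score(score0, scores) -> float:
    """Max path score by brute-force enumeration of every label sequence."""
    k = score0.shape[0]
    t = scores.shape[0] + 1
    paths = np.array(list(itertools.product(range(k), repeat=t)), dtype=np.int8)
    total = score0[paths[:, 0].astype(int)].astype(float)
    for step in range(1, t):
        total += scores[step - 1, paths[:, step - 1].astype(int), paths[:, step].astype(int)]
    return float(total.max())


class TestHmmEstimation:
    """Smoothed MLE weights verified by hand arithmetic on a 6-token corpus."""

    def setup_method(self):
        self.examples = [
            example(["a", "b", "a"], ["O", "B-Cause", "O"]),
            example(["a", "b", "b"], ["O", "B-Cause", "I-Cause"]),
        ]
        self.model = train_hmm(self.examples, BOW_ONLY, alpha=0.1)
        self.idx = {s: i for i, s in enumerate(self.model.states)}

    def test_initial_distribution(self):
        # both sequences start in O: (2 + 0.1) / (2 + 0.1 * 9)
        assert math.exp(self.model.log_init[self.idx["O"]]) == pytest.approx(2.1 / 2.9)

    def test_transition_rows(self):
        i = self.idx
        trans = np.exp(self.model.log_trans)
        assert trans[i["O"], i["B-Cause"]] == pytest.approx(2.1 / 2.9)
        assert trans[i["B-Cause"], i["O"]] == pytest.approx(1.1 / 2.9)
        assert trans[i["B-Cause"], i["I-Cause"]] == pytest.approx(1.1 / 2.9)

    def test_emission_counts(self):
        vocab, logp, log_unseen = self.model.families["word"]
        i = self.idx
        # O emitted "a" 3 times out of 3 O-tokens; vocabulary size 2 (+1 unseen)
        assert math.exp(logp[i["O"], vocab["a"]]) == pytest.approx(3.1 / 3.3)
        assert math.exp(logp[i["B-Cause"], vocab["b"]]) == pytest.approx(2.1 / 2.3)
        assert math.exp(log_unseen[i["O"]]) == pytest.approx(0.1 / 3.3)

    def test_probability_tables_normalize(self):
        assert np.exp(self.model.log_init).sum() == pytest.approx(1.0, abs=1e-9)
        for row in np.exp(self.model.log_trans):
            assert row.sum() == pytest.approx(1.0, abs=1e-9)
        for vocab, logp, log_unseen in self.model.families.values():
            totals = np.exp(logp).sum(axis=1) + np.exp(log_unseen)
            assert np.allclose(totals, 1.0, atol=1e-9)

    def test_all_outside_training_decodes_all_outside(self):
        model = train_hmm([example(["a", "b"], ["O", "O"])], BOW_ONLY)
        sent = build_sentence([("q", "NN"), ("r", "NN"), ("s", "NN")])
        assert model.decode(sent) == ["O", "O", "O"]

    def test_training_is_reproducible(self):
        again = train_hmm(self.examples, BOW_ONLY, alpha=0.1)
        assert np.array_equal(again.log_trans, self.model.log_trans)
        assert np.array_equal(again.log_init, self.model.log_init)


class TestMemmEstimation:
    def test_single_class_training_predicts_that_class(self):
        model = train_memm([example(["a", "b"], ["O", "O"])], BOW_ONLY, lam=1.0)
        sent = build_sentence([("a", "NN"), ("z", "NN")])
        assert model.decode(sent) == ["O", "O"]

    def test_learned_probabilities_match_empirical_frequencies(self):
        """With identical inputs and near-zero penalty, the maxent conditional
        must converge to the empirical label distribution (closed form)."""
        examples = [example(["x"], ["B-Cause"])] * 3 + [example(["x"], ["O"])]
        model = train_memm(examples, BOW_ONLY, lam=1e-6)
        sent = build_sentence([("x", "NN")])
        score0, _ = model.lattice(sent)
        probs = np.exp(score0)
        i = {s: j for j, s in enumerate(model.labels)}
        assert probs[i["B-Cause"]] == pytest.approx(0.75, abs=1e-2)
        assert probs[i["O"]] == pytest.approx(0.25, abs=1e-2)

    def test_optimum_verified_by_independent_objective(self):
        """The trained weights minimize an independently coded objective:
        perturbing them in random directions never lowers it (convexity)."""
        examples = [
            example(["a", "b"], ["O", "B-Cause"]),
            example(["a", "a"], ["O", "O"]),
        ]
        lam = 0.5
        model = train_memm(examples, BOW_ONLY, lam=lam)

        def objective(weights) -> float:
            total, n = 0.0, 0
            for ex in examples:
                prev = START
                for tok, lab in zip(ex.tokens, ex.labels):
                    feats = [f"bow[0]={tok.text.lower()}", _prev_feature(prev)]
                    idxs = [model.feat_vocab[f] for f in feats if f in model.feat_vocab]
                    logits = [sum(weights[i][k] for i in idxs) for k in range(len(model.labels))]
                    z = math.log(sum(math.exp(v) for v in logits))
                    total += z - logits[model.labels.index(lab)]
                    n += 1
                    prev = lab
            penalty = 0.5 * lam / n * sum(v * v for row in weights for v in row)
            return total / n + penalty

        base = objective(model.weights.tolist())
        rng = np.random.default_rng(0)
        for _ in range(10):
            direction = rng.normal(size=model.weights.shape)
            perturbed = model.weights + 1e-3 * direction
            assert objective(perturbed.tolist()) >= base - 1e-10


class TestCrf:
    def _separable_corpus(self):
        examples = []
        for _ in range(8):
            examples.append(example(["see", "edema", "today"], ["O", "B-SignSymptom", "O"]))
            examples.append(example(["has", "hypertension", "now"], ["O", "B-RiskFactor", "O"]))
            examples.append(example(["plan", "rest", "soon"], ["O", "O", "O"]))
        return examples

    def test_separable_corpus_fits_exactly(self):
        model = train_crf(self._separable_corpus(), BOW_ONLY, lam=0.1)
        held_out = [
            (["see", "edema", "now"], ["O", "B-SignSymptom", "O"]),
            (["has", "hypertension", "today"], ["O", "B-RiskFactor", "O"]),
        ]
        for words, want in held_out:
            assert model.decode(build_sentence([(w, "NN") for w in words])) == want

    def test_training_is_reproducible(self):
        corpus = self._separable_corpus()
        a = train_crf(corpus, BOW_ONLY)
        b = train_crf(corpus, BOW_ONLY)
        assert np.array_equal(a.w_obs, b.w_obs)
        assert np.array_equal(a.w_trans, b.w_trans)


class TestLabelBias:
    def test_branch_corpus_memm_not_better_than_crf(self):
        """On an imbalanced branch structure (same mention onset, different
        continuations) the locally normalized MEMM cannot outperform the
        globally normalized CRF."""
        corpus = []
        for _ in range(9):
            corpus.append(example(["alpha", "gamma", "end"], ["B-RiskFactor", "I-RiskFactor", "O"]))
        for _ in range(3):
            corpus.append(example(["alpha", "beta", "end"], ["B-Cause", "I-Cause", "O"]))
        test = [
            example(["alpha", "beta", "end"], ["B-Cause", "I-Cause", "O"]),
            example(["alpha", "gamma", "end"], ["B-RiskFactor", "I-RiskFactor", "O"]),
        ]
        memm = train_memm(corpus, BOW_ONLY, lam=1.0)
        crf = train_crf(corpus, BOW_ONLY, lam=0.1)

        def accuracy(model):
            hits = total = 0
            for ex in test:
                got = model.decode(build_sentence([(t.text, t.pos) for t in ex.tokens]))
                hits += sum(g == w for g, w in zip(got, ex.labels))
                total += len(ex.labels)
            return hits / total

        assert accuracy(memm) <= accuracy(crf)


class TestViterbiAgainstEnumeration:
    """Decoded best-path scores equal exhaustive enumeration for all families."""

    def _random_sentence(self, rng, length):
        words = ["a", "b", "c", "d"]
        return build_sentence([(words[rng.integers(4)], "NN") for _ in range(length)])

    def _random_hmm(self, rng):
        k = len(TAGS)
        vocab = {w: i for i, w in enumerate(["a", "b", "c", "d"])}
        logp = np.log(rng.dirichlet(np.ones(5), size=k))  # 4 words + unseen
        return HmmModel(
            states=TAGS, alpha=0.1,
            log_init=np.log(rng.dirichlet(np.ones(k))),
            log_trans=np.log(rng.dirichlet(np.ones(k), size=k)),
            families={"word": (vocab, logp[:, :4], logp[:, 4])},
            seen=np.ones(k, dtype=bool),
            config=BOW_ONLY,
        )

    def _random_discriminative(self, rng, cls):
        feat_names = [f"bow[0]={w}" for w in ["a", "b", "c", "d"]]
        prev_names = [_prev_feature(lab) for lab in TAGS + [START]]
        if cls is MemmModel:
            vocab = {f: i for i, f in enumerate(feat_names + prev_names)}
            return MemmModel(
                labels=TAGS, feat_vocab=vocab,
                weights=rng.normal(size=(len(vocab), len(TAGS))),
                lam=1.0, config=BOW_ONLY,
            )
        vocab = {f: i for i, f in enumerate(feat_names)}
        return CrfModel(
            labels=TAGS, feat_vocab=vocab,
            w_obs=rng.normal(size=(len(vocab), len(TAGS))),
            w_trans=rng.normal(size=(len(TAGS) + 1, len(TAGS))),
            lam=0.1, config=BOW_ONLY,
        )

    @pytest.mark.parametrize("family", ["hmm", "memm", "crf"])
    def test_decode_score_is_global_optimum(self, family):
        rng = np.random.default_rng(17)
        for trial in range(4):
            for length in (1, 2, 3, 4, 5):
                if family == "hmm":
                    model = self._random_hmm(rng)
                elif family == "memm":
                    model = self._random_discriminative(rng, MemmModel)
                else:
                    model = self._random_discriminative(rng, CrfModel)
                sent = self._random_sentence(rng, length)
                score0, scores = model.lattice(sent)
                path = viterbi_path(score0, scores)
                decoded = lattice_score(score0, scores, path)
                assert decoded == pytest.approx(
                    exhaustive_best_score(score0, scores), rel=1e-12
                ), f"{family} length {length} trial {trial}"

    def test_length_six_case(self):
        rng = np.random.default_rng(23)
        model = self._random_discriminative(rng, CrfModel)
        sent = self._random_sentence(rng, 6)
        score0, scores = model.lattice(sent)
        decoded = lattice_score(score0, scores, viterbi_path(score0, scores))
        assert decoded == pytest.approx(exhaustive_best_score(score0, scores), rel=1e-12)

    def test_trained_hmm_decode_is_optimal(self):
        model = train_hmm(
            [example(["a", "b", "a"], ["O", "B-Cause", "O"])], BOW_ONLY
        )
        sent = build_sentence([("a", "NN"), ("b", "NN"), ("c", "NN"), ("a", "NN")])
        score0, scores = model.lattice(sent)
        decoded = lattice_score(score0, scores, viterbi_path(score0, scores))
        assert decoded == pytest.approx(exhaustive_best_score(score0, scores), rel=1e-12)

    def test_empty_sentence_decodes_empty(self):
        from phenoner.docmodel import Sentence

        model = train_hmm([example(["a"], ["O"])], BOW_ONLY)
        assert model.decode(Sentence([])) == []


class TestSerialization:
    @pytest.mark.parametrize("trainer", [train_hmm, train_memm, train_crf])
    def test_save_load_preserves_decoding(self, trainer, tmp_path):
        registry = AffixRegistry({"hy", "hyp"}, {"ia", "mia"})
        config = FeatureConfig(window=1)
        examples = [
            example(["has", "hypertension"], ["O", "B-RiskFactor"]),
            example(["no", "anemia"], ["O", "B-NonTraditionalRiskFactor"]),
        ]
        model = trainer(examples, config, registry)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        sent = build_sentence([("has", "NN"), ("hypertension", "NN")])
        assert loaded.decode(sent) == model.decode(sent)

    def test_tampered_config_hash_rejected(self, tmp_path):
        import json

        model = train_hmm([example(["a"], ["O"])], BOW_ONLY)
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        payload["feature_config"]["window"] = 5  # hash no longer matches
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="hash mismatch"):
            load_model(path)


class TestPredict:
    def test_predict_equals_manual_pipeline(self):
        from phenoner.docmodel import from_bio

        examples = [
            example(["has", "edema"], ["O", "B-SignSymptom"]),
            example(["all", "well"], ["O", "O"]),
            example(["all", "good"], ["O", "O"]),
        ]
        model = train_hmm(examples, BOW_ONLY)
        doc = build_doc([[("has", "NN"), ("edema", "NN")], [("all", "DT"), ("well", "JJ")]])
        direct = predict(model, doc)
        manual = []
        for sent in doc.sentences:
            tags = model.decode(sent)
            manual.extend(from_bio(SequenceExample(sent.tokens, tags), doc.doc_id, text=doc.text))
        assert direct == manual
        assert [m.text for m in direct] == ["edema"]
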