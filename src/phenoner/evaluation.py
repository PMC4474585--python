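"""Span-matching evaluation, inter-annotator agreement, and experiment harness.

Two matching modes are scored, per phenotype class and aggregated:

* **exact** — a prediction is correct only if document, boundaries and
  label all equal a gold mention;
* **relaxed** — a prediction is correct if it shares at least one character
  with a same-label gold mention.  Relaxed true positives are counted
  separately on the gold side (recall) and the prediction side (precision),
  the standard partial-match convention that keeps many-to-one overlaps
  well-defined.

Inter-annotator agreement uses the same scorer with one annotator's set
treated as gold, since chance-corrected coefficients like Cohen's kappa are
undefined when the universe of annotatable items is open-ended.

Three aggregate rows are always reported — micro (pooled counts), macro
(unweighted class mean) and weighted (gold-support weighted) — with F
defined row-wise as the harmonic mean of that row's precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .docmodel import (
    LABELS,
    AnnotationSet,
    Document,
    EntityMention,
    to_bio,
)

MODES = ("exact", "relaxed")


@dataclass(frozen=True)
class ClassScore:
    """P/R/F plus the raw counts they were computed from.

    ``tp_pred`` is the precision numerator, ``tp_gold`` the recall
    numerator; they coincide in exact mode.
    """

    precision: float
    recall: float
    f1: float
    tp_pred: int
    tp_gold: int
    pred_n: int
    gold_n: int

    @property
    def support(self) -> int:
        return self.gold_n


def _score(tp_pred: int, tp_gold: int, pred_n: int, gold_n: int) -> ClassScore:
    p = tp_pred / pred_n if pred_n else 0.0
    r = tp_gold / gold_n if gold_n else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return ClassScore(p, r, f, tp_pred, tp_gold, pred_n, gold_n)


def _prf_row(p: float, r: float) -> tuple[float, float, float]:
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


@dataclass
class EvalReport:
    mode: str
    per_class: dict[str, ClassScore]
    micro: ClassScore = field(init=False)
    macro: tuple[float, float, float] = field(init=False)
    weighted: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        cs = self.per_class
        self.micro = _score(
            sum(c.tp_pred for c in cs.values()),
            sum(c.tp_gold for c in cs.values()),
            sum(c.pred_n for c in cs.values()),
            sum(c.gold_n for c in cs.values()),
        )
        self.macro = _prf_row(
            float(np.mean([c.precision for c in cs.values()])),
            float(np.mean([c.recall for c in cs.values()])),
        )
        total = sum(c.support for c in cs.values())
        if total:
            self.weighted = _prf_row(
                sum(c.precision * c.support for c in cs.values()) / total,
                sum(c.recall * c.support for c in cs.values()) / total,
            )
        else:
            self.weighted = (0.0, 0.0, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label, c in self.per_class.items():
            rows.append((label, c.precision, c.recall, c.f1, c.support))
        rows.append(("micro", self.micro.precision, self.micro.recall, self.micro.f1, self.micro.support))
        rows.append(("macro", *self.macro, self.micro.support))
        rows.append(("weighted", *self.weighted, self.micro.support))
        return pd.DataFrame(rows, columns=["class", "precision", "recall", "f1", "support"])

    def format_table(self) -> str:
        df = self.to_dataframe()
        return df.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def span_prf(
    gold: AnnotationSet,
    pred: Sequence[EntityMention],
    mode: str = "exact",
) -> EvalReport:
    """Score predictions against gold in one matching mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    for m in list(pred) + list(gold.mentions):
        if m.label not in LABELS:
            raise ValueError(f"unknown label {m.label!r}")

    per_class: dict[str, ClassScore] = {}
    for label in LABELS:
        g = [m for m in gold.mentions if m.label == label]
        p = [m for m in pred if m.label == label]
        if mode == "exact":
            gset = {(m.doc_id, m.start, m.end) for m in g}
            pset = {(m.doc_id, m.start, m.end) for m in p}
            tp = len(gset & pset)
            per_class[label] = _score(tp, tp, len(p), len(g))
        else:
            tp_gold = sum(1 for gm in g if any(gm.overlaps(pm) for pm in p))
            tp_pred = sum(1 for pm in p if any(pm.overlaps(gm) for gm in g))
            per_class[label] = _score(tp_pred, tp_gold, len(p), len(g))
    return EvalReport(mode, per_class)


def iaa(set_a: AnnotationSet, set_b: AnnotationSet, mode: str = "exact") -> EvalReport:
    """Inter-annotator agreement: F-score with ``set_a`` as gold."""
    return span_prf(set_a, set_b.mentions, mode)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    seed: int
    train: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    folds: list[list[str]] = field(default_factory=list)


def train_test_split(docs: Sequence[Document], ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Document-level random split; train size = round(ratio * N)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = [d.doc_id for d in docs]
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_train = int(round(ratio * len(ids)))
    return SplitPlan(seed=seed, train=sorted(order[:n_train]), test=sorted(order[n_train:]))


def kfold(docs: Sequence[Document], k: int = 5, seed: int = 0) -> SplitPlan:
    """Document-level k folds whose sizes differ by at most one."""
    ids = [d.doc_id for d in docs]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available documents")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    base, rem = divmod(len(ids), k)
    folds, pos = [], 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        folds.append(sorted(order[pos:pos + size]))
        pos += size
    return SplitPlan(seed=seed, folds=folds)


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    method: str  # rules | lexicon | hmm | memm | crf
    regime: str = "holdout"  # holdout | kfold | cross-type
    seed: int = 0
    ratio: float = 0.8
    k: int = 5
    features: "FeatureConfig | None" = None
    rules: Optional[list] = None
    lexicon: Optional[object] = None
    class_map: Optional[dict[str, str]] = None
    trainer_kwargs: dict = field(default_factory=dict)


@dataclass
class ConditionResult:
    name: str
    reports: dict[str, EvalReport]  # mode -> report
    train_ids: list[str]
    test_ids: list[str]
    predictions: list[EntityMention]


LEARNED_METHODS = ("hmm", "memm", "crf")


def _subset(gold: AnnotationSet, ids: set[str]) -> AnnotationSet:
    return AnnotationSet([m for m in gold.mentions if m.doc_id in ids], gold.annotator_id)


def fit_and_predict(
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    gold: AnnotationSet,
    config: ExperimentConfig,
) -> list[EntityMention]:
    """Train (if the method learns) on train_docs, predict on test_docs."""
    from .features import FeatureConfig, compile_affix_registry
    from .labelers import TRAINERS, predict
    from .lexicon import tag_with_lexicon
    from .rules import apply_ruleset

    if config.method == "rules":
        if not config.rules:
            raise ValueError("rules method requires a rule set")
        return [m for d in test_docs for m in apply_ruleset(config.rules, d)]
    if config.method == "lexicon":
        if config.lexicon is None:
            raise ValueError("lexicon method requires a lexicon")
        return [
            m
            for d in test_docs
            for m in tag_with_lexicon(d, config.lexicon, class_map=config.class_map)
        ]
    if config.method not in LEARNED_METHODS:
        raise ValueError(f"unknown method {config.method!r}")

    feat_config = config.features or FeatureConfig()
    train_gold = _subset(gold, {d.doc_id for d in train_docs})
    registry = compile_affix_registry(train_gold, train_docs)
    examples = [
        ex for d in train_docs for ex in to_bio(d, train_gold.for_doc(d.doc_id))
    ]
    model = TRAINERS[config.method](
        examples, feat_config, registry, **config.trainer_kwargs
    )
    return [m for d in test_docs for m in predict(model, d)]


def _evaluate(
    name: str,
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    gold: AnnotationSet,
    config: ExperimentConfig,
) -> ConditionResult:
    preds = fit_and_predict(train_docs, test_docs, gold, config)
    test_gold = _subset(gold, {d.doc_id for d in test_docs})
    reports = {mode: span_prf(test_gold, preds, mode) for mode in MODES}
    return ConditionResult(
        name=name,
        reports=reports,
        train_ids=[d.doc_id for d in train_docs],
        test_ids=[d.doc_id for d in test_docs],
        predictions=preds,
    )


def pool_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Pool raw per-class counts across conditions (e.g., folds) and rescore."""
    if not reports:
        raise ValueError("nothing to pool")
    mode = reports[0].mode
    if any(r.mode != mode for r in reports):
        raise ValueError("cannot pool reports of different modes")
    per_class = {}
    for label in LABELS:
        per_class[label] = _score(
            sum(r.per_class[label].tp_pred for r in reports),
            sum(r.per_class[label].tp_gold for r in reports),
            sum(r.per_class[label].pred_n for r in reports),
            sum(r.per_class[label].gold_n for r in reports),
        )
    return EvalReport(mode, per_class)


def run_experiment(
    docs: Sequence[Document],
    gold: AnnotationSet,
    config: ExperimentConfig,
) -> dict[str, ConditionResult]:
    """Execute one split regime end-to-end and score every condition.

    Regimes: ``holdout`` (random 80/20 by document), ``kfold`` (k conditions
    plus a count-pooled summary), ``cross-type`` (train on one text style,
    test on the other, both directions).
    """
    if not docs:
        raise ValueError("no documents supplied")
    by_id = {d.doc_id: d for d in docs}
    results: dict[str, ConditionResult] = {}

    if config.regime == "holdout":
        plan = train_test_split(docs, ratio=config.ratio, seed=config.seed)
        results["holdout"] = _evaluate(
            "holdout",
            [by_id[i] for i in plan.train],
            [by_id[i] for i in plan.test],
            gold,
            config,
        )
    elif config.regime == "kfold":
        plan = kfold(docs, k=config.k, seed=config.seed)
        fold_results = []
        for f, test_ids in enumerate(plan.folds, 1):
            train_ids = [i for fold in plan.folds for i in fold if i not in set(test_ids)]
            res = _evaluate(
                f"fold{f}",
                [by_id[i] for i in train_ids],
                [by_id[i] for i in test_ids],
                gold,
                config,
            )
            results[res.name] = res
            fold_results.append(res)
        pooled = {
            mode: pool_reports([r.reports[mode] for r in fold_results]) for mode in MODES
        }
        results["pooled"] = ConditionResult(
            "pooled", pooled, [], [d.doc_id for d in docs],
            [m for r in fold_results for m in r.predictions],
        )
    elif config.regime == "cross-type":
        discharge = [d for d in docs if d.style == "discharge"]
        article = [d for d in docs if d.style == "article"]
        if not discharge or not article:
            raise ValueError("cross-type regime needs documents of both styles")
        results["discharge_to_article"] = _evaluate(
            "discharge_to_article", discharge, article, gold, config
        )
        results["article_to_discharge"] = _evaluate(
            "article_to_discharge", article, discharge, gold, config
        )
    else:
        raise ValueError(f"unknown regime {config.regime!r}")
    return results


def comparison_table(results: dict[str, ConditionResult]) -> pd.DataFrame:
    """One row per condition: micro P/R/F in both modes."""
    rows = []
    for name, res in results.items():
        row = {"condition": name}
        for mode in MODES:
            m = res.reports[mode].micro
            row.update({
                f"{mode}_p": m.precision, f"{mode}_r": m.recall, f"{mode}_f": m.f1,
            })
        rows.append(row)
    return pd.DataFrame(rows)
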