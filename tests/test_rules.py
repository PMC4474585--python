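"""Rule language: parsing, matching semantics, conflict resolution."""

from __future__ import annotations

import numpy as np
import pytest

from phenoner.docmodel import LABELS, Sentence
from phenoner.rules import (
    Constraint,
    Rule,
    RuleParseError,
    TokenSpec,
    apply_ruleset,
    format_rule,
    load_rules,
    match_rule,
    parse_rule,
    spec_matches,
)

from conftest import build_doc, build_sentence

EXAMPLE_RULE = (
    'SignSymptom => [syn=NN|NNP]{1,3}, [sem=beverb]?, '
    '[syn=VBN|JJ, token!="normal"|"regular"|"stable"]'
)


class TestParsing:
    def test_example_rule_structure(self):
        rule = parse_rule(EXAMPLE_RULE)
        assert rule.label == "SignSymptom"
        assert [(s.min_count, s.max_count) for s in rule.specs] == [(1, 3), (0, 1), (1, 1)]
        first = rule.specs[0].constraints[0]
        assert (first.attribute, first.negated, first.values) == ("syn", False, ("NN", "NNP"))
        neg = rule.specs[2].constraints[1]
        assert neg.negated and neg.values == ("normal", "regular", "stable")

    @pytest.mark.parametrize(
        "line",
        [
            "Cause => [token=x",  # unbalanced bracket
            "Cause => [bogus=x]",  # unknown attribute
            "Cause => [token=]",  # empty value
            "Cause => [token=x]{3,1}",  # m > n
            "Nope => [token=x]",  # unknown label
            "Cause [token=x]",  # missing arrow
            "Cause => [token=x]?, [token=y]{0,2}",  # could match empty sequence
        ],
    )
    def test_malformed_rules_rejected_with_column(self, line):
        with pytest.raises(RuleParseError, match="column"):
            parse_rule(line)

    def test_parse_format_parse_is_identity_on_random_rules(self):
        rng = np.random.default_rng(0)
        words = ["NN", "VBN", "JJ", "pain", "heart", "beverb", "x-ray", "q v", "a|b"]
        for _ in range(200):
            specs = []
            for _ in range(rng.integers(1, 4)):
                constraints = []
                for _ in range(rng.integers(1, 3)):
                    values = tuple(
                        words[i] for i in rng.choice(len(words), size=rng.integers(1, 3))
                    )
                    attr = ("token", "syn", "sem", "orth")[rng.integers(4)]
                    constraints.append(Constraint(attr, bool(rng.integers(2)), values))
                kind = rng.integers(3)
                if kind == 0:
                    mn, mx = 1, 1
                elif kind == 1:
                    mn, mx = 0, 1
                else:
                    mn = int(rng.integers(1, 3))
                    mx = mn + int(rng.integers(0, 3))
                specs.append(TokenSpec(tuple(constraints), mn, mx))
            if all(s.min_count == 0 for s in specs):
                specs[0] = TokenSpec(specs[0].constraints, 1, max(1, specs[0].max_count))
            rule = Rule(LABELS[rng.integers(4)], tuple(specs), rule_id="r", source_line=1)
            reparsed = parse_rule(format_rule(rule), rule_id="r", source_line=1)
            assert reparsed == rule

    def test_load_rules_skips_comments_and_reports_line(self, tmp_path):
        p = tmp_path / "r.rules"
        p.write_text("# comment\n\n" + EXAMPLE_RULE + "\nCause => [token=x\n")
        with pytest.raises(RuleParseError, match="line 4"):
            load_rules(p)


class TestSpecMatching:
    def setup_method(self):
        rule = parse_rule(EXAMPLE_RULE)
        self.final_spec = rule.specs[2]

    def test_participle_token_satisfies_spec(self):
        sent = build_sentence([("enlarged", "VBN")])
        assert spec_matches(self.final_spec, sent.tokens[0])

    def test_excluded_literal_fails_despite_pos(self):
        sent = build_sentence([("normal", "JJ")])
        assert not spec_matches(self.final_spec, sent.tokens[0])

    def test_token_literals_case_insensitive(self):
        spec = parse_rule("Cause => [token=Heart]").specs[0]
        sent = build_sentence([("HEART", "NN")])
        assert spec_matches(spec, sent.tokens[0])

    def test_missing_sem_fails_eq_passes_neq(self):
        eq = parse_rule("Cause => [sem=dsyn]").specs[0]
        neq = parse_rule("Cause => [sem!=dsyn]").specs[0]
        sent = build_sentence([("pain", "NN")])  # sem is None
        assert not spec_matches(eq, sent.tokens[0])
        assert spec_matches(neq, sent.tokens[0])


class TestWorkedExamples:
    """The documented behavior of the noun + be + participle/adjective rule."""

    RULE = parse_rule(EXAMPLE_RULE)

    @pytest.mark.parametrize(
        "words,expect_match",
        [
            ([("heart", "NN"), ("is", "VBZ"), ("enlarged", "VBN")], True),
            ([("abdomen", "NN"), ("was", "VBD"), ("distended", "VBN")], True),
            ([("leg", "NN"), ("is", "VBZ"), ("swollen", "VBN")], True),
            ([("leg", "NN"), ("swollen", "VBN")], True),  # optional be absent
            ([("abdomen", "NN"), ("is", "VBZ"), ("benign", "JJ")], True),  # known FP
            ([("chest", "NN"), ("is", "VBZ"), ("normal", "JJ")], False),
            ([("heart", "NN"), ("is", "VBZ"), ("regular", "JJ")], False),
        ],
    )
    def test_phrase(self, words, expect_match):
        sent = build_sentence(words)
        matches = match_rule(self.RULE, sent)
        if expect_match:
            assert len(matches) == 1
            assert (matches[0].start_token, matches[0].end_token) == (0, len(words))
        else:
            assert matches == []

    def test_compound_noun_iterated(self):
        sent = build_sentence([("chest", "NN"), ("pain", "NN"), ("was", "VBD"), ("severe", "JJ")])
        matches = match_rule(self.RULE, sent)
        assert len(matches) == 1
        assert matches[0].end_token == 4


def _window_matches(rule: Rule, tokens, i: int, j: int) -> bool:
    """Independent oracle: can the rule consume exactly tokens[i:j]?"""

    def consume(spec_idx: int, pos: int) -> bool:
        if spec_idx == len(rule.specs):
            return pos == j
        spec = rule.specs[spec_idx]
        for count in range(spec.min_count, spec.max_count + 1):
            if pos + count > j:
                break
            if all(spec_matches(spec, tokens[pos + c]) for c in range(count)):
                if consume(spec_idx + 1, pos + count):
                    return True
            else:
                break
        return False

    return i < j and consume(0, i)


def _oracle_matches(rule: Rule, sent: Sentence):
    """Leftmost-longest via exhaustive window enumeration."""
    out = []
    i = 0
    n = len(sent.tokens)
    while i < n:
        best = None
        for j in range(n, i, -1):
            if _window_matches(rule, sent.tokens, i, j):
                best = j
                break
        if best is None:
            i += 1
        else:
            out.append((i, best))
            i = best
    return out


class TestMatcherAgainstOracle:
    def test_random_sentences_and_rules(self):
        rng = np.random.default_rng(1)
        pos_tags = ["NN", "NNP", "VBN", "JJ", "VBZ", "DT"]
        words = ["heart", "pain", "is", "normal", "big", "the", "leg"]
        for trial in range(150):
            n_tokens = int(rng.integers(1, 11))
            sent = build_sentence(
                [
                    (words[rng.integers(len(words))], pos_tags[rng.integers(len(pos_tags))])
                    for _ in range(n_tokens)
                ]
            )
            specs = []
            for _ in range(rng.integers(1, 5)):
                attr = ("token", "syn")[rng.integers(2)]
                pool = words if attr == "token" else pos_tags
                values = tuple(pool[i] for i in rng.choice(len(pool), size=rng.integers(1, 3)))
                mn = int(rng.integers(0, 3))
                mx = mn + int(rng.integers(0 if mn else 1, 3))
                specs.append(TokenSpec((Constraint(attr, bool(rng.integers(2)), values),), mn, max(mx, 1)))
            if all(s.min_count == 0 for s in specs):
                specs[0] = TokenSpec(specs[0].constraints, 1, max(1, specs[0].max_count))
            rule = Rule("Cause", tuple(specs), rule_id="r", source_line=1)
            got = [(m.start_token, m.end_token) for m in match_rule(rule, sent)]
            assert got == _oracle_matches(rule, sent), f"trial {trial}"

    def test_relaxing_negative_constraint_is_monotone(self):
        """Dropping a != constraint can only grow the match set."""
        rng = np.random.default_rng(2)
        strict = parse_rule(EXAMPLE_RULE)
        relaxed_spec = TokenSpec(strict.specs[2].constraints[:1], 1, 1)
        relaxed = Rule(strict.label, strict.specs[:2] + (relaxed_spec,), "r", 1)
        words = [("heart", "NN"), ("is", "VBZ"), ("normal", "JJ"), ("enlarged", "VBN"), ("leg", "NN")]
        for _ in range(100):
            n = int(rng.integers(1, 8))
            sent = build_sentence([words[rng.integers(len(words))] for _ in range(n)])
            for i in range(n):
                for j in range(i + 1, n + 1):
                    if _window_matches(strict, sent.tokens, i, j):
                        assert _window_matches(relaxed, sent.tokens, i, j)


class TestApplyRuleset:
    def test_empty_ruleset_gives_no_mentions(self, tiny_doc):
        assert apply_ruleset([], tiny_doc) == []

    def test_nested_spans_keep_longer(self):
        doc = build_doc([[("chest", "NN"), ("pain", "NN")]])
        short = parse_rule("Cause => [token=chest]", source_line=1)
        long = parse_rule("SignSymptom => [token=chest], [token=pain]", source_line=2)
        mentions = apply_ruleset([short, long], doc)
        assert len(mentions) == 1
        assert mentions[0].label == "SignSymptom"
        assert mentions[0].text == "chest pain"

    def test_tie_broken_by_source_line(self):
        doc = build_doc([[("pain", "NN")]])
        r1 = parse_rule("Cause => [token=pain]", source_line=5)
        r2 = parse_rule("SignSymptom => [token=pain]", source_line=3)
        mentions = apply_ruleset([r1, r2], doc)
        assert [m.label for m in mentions] == ["SignSymptom"]

    def test_output_is_overlap_free_on_synthetic_corpus(self):
        from pathlib import Path

        from phenoner.synthetic import GeneratorConfig, generate_corpus

        rules_path = Path(__file__).parent.parent / "src" / "phenoner" / "data" / "starter.rules"
        rules = load_rules(rules_path)
        docs, _ = generate_corpus(GeneratorConfig(n_docs=10, seed=5))
        for doc in docs:
            mentions = apply_ruleset(rules, doc)
            for a, b in zip(mentions, mentions[1:]):
                assert a.end <= b.start
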