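"""Synthetic annotated corpora in two clinical text styles.

The real corpora this toolkit targets — discharge summaries from an EHR
challenge and full-text cardiology articles — sit behind data-use
agreements, so every component here is exercised on generated documents
that emulate the structural properties that matter to the methods:

* two text styles: telegraphic *discharge* text under all-caps section
  headers, and full-sentence *article* prose;
* four phenotype classes with style-skewed class mixes (discharge text is
  sign/symptom-heavy; article text leans toward causes and kidney-related
  non-traditional risk factors);
* roughly 10% of non-mention tokens misspelled by single-character edits in
  the discharge style, matching the error rate reported for EHR narrative
  (mentions themselves are left intact unless explicitly requested);
* generator-assigned gold POS and chunk tags, so no external tagger is
  needed anywhere in the pipeline;
* a simulated second annotator whose disagreements are modifier-boundary
  perturbations (e.g. "significant left atrial dilation" vs. "left atrial
  dilation"), the dominant disagreement pattern in double-annotated
  clinical corpora.

What the generator does not emulate: real clinical vocabulary breadth,
abbreviation ambiguity, negation/uncertainty scoping, or discontinuous
mentions.  Scores on this corpus characterize the implementations, not
expected performance on real text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .docmodel import (
    LABELS,
    AnnotationSet,
    Document,
    EntityMention,
    Sentence,
    Token,
    validate_document,
)

# ---------------------------------------------------------------------------
# Closed vocabularies: mention phrases with per-token POS
# ---------------------------------------------------------------------------

Phrase = tuple[tuple[str, str], ...]  # ((word, pos), ...)

#: POS tags for every word a mention phrase can contain (default NN).
_WORD_POS = {
    "shortness": "NN", "of": "IN", "left": "JJ", "atrial": "JJ", "significant": "JJ",
    "paroxysmal": "JJ", "nocturnal": "JJ", "productive": "JJ", "peripheral": "JJ",
    "pulmonary": "JJ", "elevated": "JJ", "jugular": "JJ", "venous": "JJ", "lower": "JJ",
    "extremity": "NN", "palpitations": "NNS", "rales": "NNS", "crackles": "NNS",
    "coronary": "JJ", "ischemic": "JJ", "valvular": "JJ", "hypertensive": "JJ",
    "myocardial": "JJ", "acute": "JJ", "dilated": "VBN", "aortic": "JJ", "severe": "JJ",
    "mitral": "JJ", "ventricular": "JJ", "renal": "JJ", "chronic": "JJ", "worsened": "VBN",
    "decreased": "VBN", "end": "NN", "stage": "NN", "serum": "NN", "uncontrolled": "JJ",
    "vascular": "JJ",
}

#: Mention phrases per class.  Deliberately ambiguous at the token level —
#: "disease", "elevated", "acute", "atrial", "left" each occur in more than
#: one class — so that class identity requires context, as in real text.
_PHRASE_STRINGS: dict[str, list[str]] = {
    "SignSymptom": [
        "chest pain", "shortness of breath", "dyspnea", "edema", "fatigue",
        "orthopnea", "palpitations", "cough", "nausea", "peripheral edema",
        "left atrial dilation", "significant left atrial dilation", "dizziness",
        "paroxysmal nocturnal dyspnea", "productive cough", "pulmonary edema",
        "elevated jugular venous pressure", "lower extremity swelling", "rales",
        "chest tightness", "syncope", "crackles",
    ],
    "Cause": [
        "coronary artery disease", "myocardial infarction", "atrial fibrillation",
        "cardiomyopathy", "ischemic heart disease", "aortic stenosis",
        "valvular heart disease", "dilated cardiomyopathy", "mitral regurgitation",
        "left ventricular dysfunction", "acute myocardial infarction",
        "hypertensive heart disease", "severe aortic stenosis", "ischemic cardiomyopathy",
    ],
    "RiskFactor": [
        "hypertension", "diabetes mellitus", "hyperlipidemia", "obesity", "smoking",
        "hypercholesterolemia", "diabetes", "tobacco use", "alcohol abuse",
        "uncontrolled hypertension", "peripheral vascular disease",
    ],
    "NonTraditionalRiskFactor": [
        "renal insufficiency", "proteinuria", "anemia", "elevated creatinine",
        "chronic kidney disease", "worsened renal function", "hematuria", "dysuria",
        "renal failure", "acute renal failure", "end stage renal disease",
        "chronic renal insufficiency", "decreased renal function", "microalbuminuria",
        "elevated serum creatinine",
    ],
}


def _phrase(words: str) -> Phrase:
    return tuple((w, _WORD_POS.get(w, "NN")) for w in words.split())


MENTION_PHRASES: dict[str, list[Phrase]] = {
    label: [_phrase(p) for p in phrases] for label, phrases in _PHRASE_STRINGS.items()
}

#: Modifiers that become part of the gold span when drawn (compositional
#: mention variants: "recurrent chest pain", "progressive renal failure"...).
#: Shared across all four classes, so a mention's first token is frequently
#: class-ambiguous on its own.
IN_SPAN_MODIFIERS: list[tuple[str, str]] = [
    ("mild", "JJ"), ("moderate", "JJ"), ("recurrent", "JJ"), ("progressive", "JJ"),
    ("intermittent", "JJ"), ("worsening", "VBG"),
]

#: Probability that a generated mention carries an in-span modifier.
IN_SPAN_MODIFIER_P = 0.3

#: Free modifiers occasionally placed before a mention (not part of gold);
#: disjoint from the in-span modifier vocabulary so span boundaries stay
#: learnable, and adjacent to mentions so the simulated second annotator
#: has something to disagree about.
MODIFIERS = [("new", "JJ"), ("ongoing", "JJ"), ("persistent", "JJ"), ("known", "JJ")]

# Sentence templates: "{m}" marks a mention slot, "{mod}" an optional free
# modifier in front of the following slot; other items are (word, pos).
DISCHARGE_TEMPLATES = [
    [("patient", "NN"), ("reports", "VBZ"), "{mod}", "{m}", (".", ".")],
    ["{mod}", "{m}", ("noted", "VBN"), ("on", "IN"), ("admission", "NN"), (".", ".")],
    [("no", "DT"), "{m}", ("on", "IN"), ("exam", "NN"), (".", ".")],
    [("history", "NN"), ("of", "IN"), "{m}", (".", ".")],
    [("she", "PRP"), ("denies", "VBZ"), "{m}", (".", ".")],
    [("exam", "NN"), ("reveals", "VBZ"), "{mod}", "{m}", (".", ".")],
    ["{m}", ("and", "CC"), "{m}", ("present", "JJ"), (".", ".")],
    [("continued", "VBD"), ("treatment", "NN"), ("for", "IN"), "{m}", (".", ".")],
]
DISCHARGE_FILLERS = [
    [("vital", "JJ"), ("signs", "NNS"), ("stable", "JJ"), (".", ".")],
    [("medications", "NNS"), ("continued", "VBD"), (".", ".")],
    [("follow", "VB"), ("up", "RP"), ("in", "IN"), ("clinic", "NN"), (".", ".")],
    [("tolerating", "VBG"), ("oral", "JJ"), ("intake", "NN"), (".", ".")],
]
DISCHARGE_HEADERS = [
    "HISTORY OF PRESENT ILLNESS:",
    "PAST MEDICAL HISTORY:",
    "PHYSICAL EXAMINATION:",
    "HOSPITAL COURSE:",
    "LABORATORY DATA:",
]

ARTICLE_TEMPLATES = [
    [("The", "DT"), ("association", "NN"), ("between", "IN"), "{m}", ("and", "CC"), "{m}",
     ("remains", "VBZ"), ("unclear", "JJ"), (".", ".")],
    [("Patients", "NNS"), ("with", "IN"), "{mod}", "{m}", ("often", "RB"), ("develop", "VBP"),
     "{m}", (".", ".")],
    [("We", "PRP"), ("observed", "VBD"), "{mod}", "{m}", ("in", "IN"), ("the", "DT"),
     ("cohort", "NN"), (".", ".")],
    [("Previous", "JJ"), ("studies", "NNS"), ("linked", "VBD"), "{m}", ("to", "TO"),
     ("adverse", "JJ"), ("outcomes", "NNS"), (".", ".")],
    ["{m}", ("was", "VBD"), ("associated", "VBN"), ("with", "IN"), ("increased", "JJ"),
     ("mortality", "NN"), (".", ".")],
]
ARTICLE_FILLERS = [
    [("Further", "JJ"), ("research", "NN"), ("is", "VBZ"), ("needed", "VBN"), (".", ".")],
    [("The", "DT"), ("cohort", "NN"), ("was", "VBD"), ("followed", "VBN"), ("for", "IN"),
     ("two", "CD"), ("years", "NNS"), (".", ".")],
]

#: Style-specific class mixes over (Cause, RiskFactor, SignSymptom, NonTraditionalRiskFactor).
DEFAULT_CLASS_MIX = {
    "discharge": {"Cause": 0.15, "RiskFactor": 0.20, "SignSymptom": 0.55, "NonTraditionalRiskFactor": 0.10},
    "article": {"Cause": 0.30, "RiskFactor": 0.20, "SignSymptom": 0.15, "NonTraditionalRiskFactor": 0.35},
}

DEFAULT_MISSPELL_RATE = {"discharge": 0.10, "article": 0.0}


@dataclass
class GeneratorConfig:
    n_docs: int
    style: str = "discharge"
    seed: int = 0
    mentions_per_doc: float = 6.0
    class_mix: Optional[dict[str, float]] = None
    misspell_rate: Optional[float] = None  # None -> style default
    misspell_mentions: bool = False
    annotator_noise: float = 0.2

    def __post_init__(self) -> None:
        if self.n_docs <= 0:
            raise ValueError("n_docs must be positive")
        if self.style not in DEFAULT_CLASS_MIX:
            raise ValueError(f"unknown style {self.style!r}")
        mix = self.class_mix or DEFAULT_CLASS_MIX[self.style]
        if set(mix) != set(LABELS) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must cover the four classes and sum to 1")
        if self.misspell_rate is not None and not 0 <= self.misspell_rate <= 1:
            raise ValueError("misspell_rate must be in [0, 1]")
        if not 0 <= self.annotator_noise <= 1:
            raise ValueError("annotator_noise must be in [0, 1]")

    @property
    def effective_class_mix(self) -> dict[str, float]:
        return self.class_mix or DEFAULT_CLASS_MIX[self.style]

    @property
    def effective_misspell_rate(self) -> float:
        if self.misspell_rate is not None:
            return self.misspell_rate
        return DEFAULT_MISSPELL_RATE[self.style]


def closed_vocabulary() -> set[str]:
    """Every unperturbed word form the generator can emit (lowercased).

    Useful for measuring the realized misspelling rate: an eligible token
    outside this set must have been perturbed.
    """
    vocab: set[str] = set()
    for phrases in MENTION_PHRASES.values():
        for phrase in phrases:
            vocab.update(w.lower() for w, _ in phrase)
    for w, _ in MODIFIERS + IN_SPAN_MODIFIERS:
        vocab.add(w.lower())
    for template in (
        DISCHARGE_TEMPLATES + DISCHARGE_FILLERS + ARTICLE_TEMPLATES + ARTICLE_FILLERS
    ):
        for item in template:
            if isinstance(item, tuple):
                vocab.add(item[0].lower())
    for header in DISCHARGE_HEADERS:
        vocab.update(w.lower() for w in header[:-1].split())
    vocab.add(":")
    return vocab


def _misspell(word: str, rng: np.random.Generator) -> str:
    """One random single-character edit; alphabetic words of length >= 3 only."""
    if len(word) < 3 or not word.isalpha():
        return word
    op = rng.integers(4)
    i = int(rng.integers(1, len(word)))  # keep the first character
    letters = "abcdefghijklmnopqrstuvwxyz"
    if op == 0:  # substitute
        repl = letters[int(rng.integers(26))]
        if repl == word[i]:
            repl = letters[(letters.index(repl) + 1) % 26]
        return word[:i] + repl + word[i + 1:]
    if op == 1:  # delete
        return word[:i] + word[i + 1:]
    if op == 2:  # insert
        return word[:i] + letters[int(rng.integers(26))] + word[i:]
    if i == len(word) - 1:  # transpose needs a right neighbor
        i -= 1
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def _sample_phrase(label: str, rng: np.random.Generator) -> Phrase:
    """Zipf-skewed phrase choice with optional compositional in-span modifier."""
    phrases = MENTION_PHRASES[label]
    weights = 1.0 / np.arange(1, len(phrases) + 1)
    weights /= weights.sum()
    phrase = phrases[int(rng.choice(len(phrases), p=weights))]
    if rng.random() < IN_SPAN_MODIFIER_P and phrase[0][1] not in ("JJ", "VBN", "VBG"):
        phrase = (IN_SPAN_MODIFIERS[int(rng.integers(len(IN_SPAN_MODIFIERS)))],) + phrase
    return phrase


def _build_sentence_tokens(
    template: list,
    labels_iter: list[str],
    rng: np.random.Generator,
    misspell_rate: float,
    misspell_mentions: bool,
) -> list[tuple[str, str, str, Optional[str]]]:
    """Returns (word, pos, chunk, mention-marker) rows; marker is 'B'/'I' + label."""
    rows: list[tuple[str, str, str, Optional[str]]] = []
    pending_mod = False
    for item in template:
        if item == "{mod}":
            if rng.random() < 0.4:
                w, p = MODIFIERS[int(rng.integers(len(MODIFIERS)))]
                if rng.random() < misspell_rate:
                    w = _misspell(w, rng)
                rows.append((w, p, "B-NP", None))
            continue
        if item == "{m}":
            label = labels_iter.pop(0)
            phrase = _sample_phrase(label, rng)
            for k, (w, p) in enumerate(phrase):
                if misspell_mentions and rng.random() < misspell_rate:
                    w = _misspell(w, rng)
                chunk = "B-NP" if k == 0 else "I-NP"
                rows.append((w, p, chunk, ("B-" if k == 0 else "I-") + label))
            continue
        w, p = item
        if rng.random() < misspell_rate:
            w = _misspell(w, rng)
        chunk = "B-NP" if p.startswith("NN") else "O"
        rows.append((w, p, chunk, None))
    return rows


def _count_slots(template: list) -> int:
    return sum(1 for item in template if item == "{m}")


def generate_corpus(config: GeneratorConfig) -> tuple[list[Document], AnnotationSet]:
    """Generate documents plus a gold annotation set; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    mix = config.effective_class_mix
    classes = list(LABELS)
    probs = np.array([mix[c] for c in classes])
    rate = config.effective_misspell_rate
    templates = DISCHARGE_TEMPLATES if config.style == "discharge" else ARTICLE_TEMPLATES
    fillers = DISCHARGE_FILLERS if config.style == "discharge" else ARTICLE_FILLERS

    docs: list[Document] = []
    mentions: list[EntityMention] = []
    for d in range(config.n_docs):
        doc_id = f"{config.style}-{d:04d}"
        n_mentions = int(rng.poisson(config.mentions_per_doc))
        labels_left = [classes[i] for i in rng.choice(len(classes), size=n_mentions, p=probs)]

        sentence_rows: list[tuple[str, list]] = []  # ("header"|"sent", rows)
        if config.style == "discharge":
            sentence_rows.append(("header", DISCHARGE_HEADERS[0]))
        sent_count = 0
        while labels_left:
            candidates = [t for t in templates if _count_slots(t) <= len(labels_left)]
            template = candidates[int(rng.integers(len(candidates)))]
            rows = _build_sentence_tokens(
                template, labels_left, rng, rate, config.misspell_mentions
            )
            sentence_rows.append(("sent", rows))
            sent_count += 1
            if config.style == "discharge" and sent_count % 4 == 0 and labels_left:
                header = DISCHARGE_HEADERS[(sent_count // 4) % len(DISCHARGE_HEADERS)]
                sentence_rows.append(("header", header))
        for _ in range(int(rng.integers(1, 3))):
            filler = fillers[int(rng.integers(len(fillers)))]
            rows = _build_sentence_tokens(filler, [], rng, rate, config.misspell_mentions)
            sentence_rows.append(("sent", rows))

        # lay out the text and build the token layer with gold offsets
        text_parts: list[str] = []
        pos_cursor = 0
        sentences: list[Sentence] = []
        for kind, payload in sentence_rows:
            if kind == "header":
                header_tokens = []
                words = payload[:-1].split() + [":"]
                for k, w in enumerate(words):
                    if k > 0 and w != ":":
                        text_parts.append(" ")
                        pos_cursor += 1
                    start = pos_cursor
                    text_parts.append(w)
                    pos_cursor += len(w)
                    header_tokens.append(
                        Token(w, start, pos_cursor, pos=":" if w == ":" else "NN", chunk="O")
                    )
                sentences.append(Sentence(header_tokens, index=len(sentences)))
            else:
                toks: list[Token] = []
                for k, (w, p, chunk, marker) in enumerate(payload):
                    if k > 0 and w != ".":
                        text_parts.append(" ")
                        pos_cursor += 1
                    start = pos_cursor
                    text_parts.append(w)
                    pos_cursor += len(w)
                    toks.append(Token(w, start, pos_cursor, pos=p, chunk=chunk))
                sentences.append(Sentence(toks, index=len(sentences)))
                # mention spans from the markers
                run_start = run_label = None
                for tok, (_, _, _, marker) in zip(toks, payload):
                    if marker and marker.startswith("B-"):
                        if run_start is not None:
                            mentions.append(
                                EntityMention(doc_id, run_start, prev_end, run_label, "")
                            )
                        run_start, run_label = tok.start, marker[2:]
                    elif marker is None and run_start is not None:
                        mentions.append(EntityMention(doc_id, run_start, prev_end, run_label, ""))
                        run_start = run_label = None
                    prev_end = tok.end
                if run_start is not None:
                    mentions.append(EntityMention(doc_id, run_start, prev_end, run_label, ""))
            text_parts.append("\n")
            pos_cursor += 1

        text = "".join(text_parts)
        doc = Document(doc_id, text, style=config.style, sentences=sentences)
        validate_document(doc)
        docs.append(doc)

    # fill in mention surfaces from the final text (dedupe identical spans)
    by_doc = {d.doc_id: d for d in docs}
    final: list[EntityMention] = []
    seen = set()
    for m in mentions:
        key = (m.doc_id, m.start, m.end, m.label)
        if key in seen:
            continue
        seen.add(key)
        text = by_doc[m.doc_id].text
        final.append(EntityMention(m.doc_id, m.start, m.end, m.label, text[m.start:m.end]))
    return docs, AnnotationSet(final, annotator_id="gold")


def simulate_second_annotator(
    gold: AnnotationSet,
    docs: list[Document],
    noise: float = 0.2,
    seed: int = 0,
) -> AnnotationSet:
    """Perturb mention boundaries the way a second human annotator would.

    With probability ``noise`` a mention's span is shrunk by its leading
    token, extended over an adjacent preceding modifier, or (rarely)
    dropped; labels are always preserved.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_doc = {d.doc_id: d for d in docs}
    out: list[EntityMention] = []
    for m in sorted(gold.mentions, key=lambda m: (m.doc_id, m.start, m.end, m.label)):
        doc = by_doc[m.doc_id]
        if rng.random() >= noise:
            out.append(m)
            continue
        sent = next(
            (s for s in doc.sentences if s.start <= m.start and m.end <= s.end), None
        )
        toks = [t for t in sent.tokens if t.start < m.end and t.end > m.start] if sent else []
        u = rng.random()
        new = None
        if u < 0.45 and len(toks) >= 2:  # shrink: drop the leading modifier token
            new = (toks[1].start, m.end)
        elif u < 0.90 and sent is not None:  # extend over a preceding modifier
            idx = sent.tokens.index(toks[0]) if toks else -1
            if idx > 0 and sent.tokens[idx - 1].pos in ("JJ", "VBG", "VBN"):
                new = (sent.tokens[idx - 1].start, m.end)
        else:  # drop the mention entirely
            continue
        if new is None:
            out.append(m)
            continue
        s, e = new
        cand = EntityMention(m.doc_id, s, e, m.label, doc.text[s:e])
        if any(
            (c.doc_id, c.start, c.end, c.label) == (cand.doc_id, cand.start, cand.end, cand.label)
            for c in out
        ):
            out.append(m)  # avoid exact duplicates in the perturbed set
        else:
            out.append(cand)
    return AnnotationSet(out, annotator_id="annotator2")


def write_corpus(
    docs: list[Document],
    gold: AnnotationSet,
    outdir: str | Path,
    config: Optional[GeneratorConfig] = None,
    second: Optional[AnnotationSet] = None,
) -> None:
    """Standard corpus layout: text/*.txt, ann/*.ann, conll/*.tsv, manifest.json."""
    from .docmodel import write_conll, write_standoff

    outdir = Path(outdir)
    for sub in ("text", "ann", "conll"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    if second is not None:
        (outdir / "ann2").mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_standoff(doc, gold.for_doc(doc.doc_id), outdir / "text" / f"{doc.doc_id}.txt",
                       outdir / "ann" / f"{doc.doc_id}.ann")
        write_conll([doc], outdir / "conll" / f"{doc.doc_id}.tsv", gold=gold)
        if second is not None:
            write_standoff(doc, second.for_doc(doc.doc_id), outdir / "text" / f"{doc.doc_id}.txt",
                           outdir / "ann2" / f"{doc.doc_id}.ann")
    manifest = {"n_docs": len(docs)}
    if config is not None:
        manifest.update(asdict(config))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def default_benchmark(
    seed: int = 0, n_docs: int = 250, ratio: float = 0.8, style: str = "discharge"
) -> tuple[list[Document], list[Document], AnnotationSet]:
    """The default labeling benchmark: 80/20 document split of a generated corpus."""
    from .evaluation import train_test_split

    config = GeneratorConfig(n_docs=n_docs, style=style, seed=seed)
    docs, gold = generate_corpus(config)
    plan = train_test_split(docs, ratio=ratio, seed=seed)
    by_id = {d.doc_id: d for d in docs}
    return [by_id[i] for i in plan.train], [by_id[i] for i in plan.test], gold
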