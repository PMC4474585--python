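# phenoner

Phenotype named-entity recognition for congestive-heart-failure (CHF) text.

Clinical phenotypes — the observable manifestations of disease — are
scattered through free text: hospital discharge summaries written in
telegraphic, abbreviation-heavy prose, and full-sentence scientific
articles.  `phenoner` extracts mentions of four phenotype classes from such
text:

| class | meaning |
|---|---|
| `Cause` | a medical problem contributing to the occurrence of CHF |
| `RiskFactor` | a condition raising the chance of developing CHF |
| `SignSymptom` | an observable manifestation reported by the patient |
| `NonTraditionalRiskFactor` | kidney-function abnormalities elevating CHF risk |

Three families of extractors share one document model and one evaluation
protocol:

* **Token-pattern rules** — a declarative pattern language over token
  attributes (`token`, `syn` = POS, `sem`, `orth`), with alternation,
  negation, optionality (`?`) and bounded iteration (`{m,n}`).  Example:

  ```
  SignSymptom => [syn=NN|NNP]{1,3}, [sem=beverb]?, [syn=VBN|JJ, token!="normal"|"regular"|"stable"]
  ```

  matches "heart is enlarged", "abdomen was distended", "leg swollen" —
  and, as documented, the false positive "abdomen is benign" — while the
  `token!=` exclusion filters normal findings ("chest is normal").

* **Dictionary lookup** — a gazetteer (term → semantic type) applied by
  greedy longest match with semantic-type filtering, the classic
  dictionary baseline with its classic failure modes (misspellings missed,
  multiword expressions fragmented).

* **BIO sequence labeling** — mentions are encoded as per-token
  Begin/Inside/Outside tags and decoded by Viterbi under three models
  sharing one feature layer (windowed bag-of-words, POS, chunk, word
  shape, and an affix registry of prefixes/suffixes of lengths 2–5
  harvested from gold training mentions):
  - a feature-augmented **HMM** whose emission factorizes naive-Bayes
    style across feature families, P(obs|s) = Πf P(vf|s), with add-α
    smoothing;
  - a **MEMM** (local maximum-entropy steps conditioned on the previous
    label; exhibits the label-bias problem by construction);
  - a linear-chain **CRF** (globally normalized, trained by L-BFGS on the
    penalized conditional log-likelihood with forward–backward gradients).

Evaluation reports precision/recall/F per class and micro/macro/weighted
aggregates under **exact** matching (boundaries and label identical) and
**relaxed** matching (same-label spans need only overlap).  The same
scorer measures inter-annotator agreement (IAA) as an F-score with one
annotator taken as gold — appropriate when the universe of annotatable
items is open-ended and chance-corrected coefficients are undefined.

Because real clinical corpora of this kind sit behind data-use agreements,
the package ships a **synthetic corpus generator** that emulates the
properties the methods care about: two text styles, style-skewed class
mixes, ~10% single-character misspellings of filler tokens in the EHR
style, generator-assigned POS/chunk tags, and a simulated second annotator
whose disagreements are modifier-boundary perturbations ("significant left
atrial dilation" vs "left atrial dilation").

## Worked example

```python
from phenoner import (
    GeneratorConfig, generate_corpus, simulate_second_annotator,
    ExperimentConfig, run_experiment, iaa,
)

docs, gold = generate_corpus(GeneratorConfig(n_docs=250, seed=0))
results = run_experiment(docs, gold, ExperimentConfig(method="crf", regime="holdout", seed=0))
report = results["holdout"].reports["exact"]
print(report.format_table())

second = simulate_second_annotator(gold, docs, noise=0.2, seed=1)
print("IAA exact  ", round(iaa(gold, second, "exact").micro.f1, 3))
print("IAA relaxed", round(iaa(gold, second, "relaxed").micro.f1, 3))
```

prints (seed 0):

```
                   class  precision  recall    f1  support
                   Cause      1.000   1.000 1.000       49
              RiskFactor      1.000   1.000 1.000       66
             SignSymptom      1.000   1.000 1.000      166
NonTraditionalRiskFactor      1.000   1.000 1.000       32
                   micro      1.000   1.000 1.000      313
                   macro      1.000   1.000 1.000      313
                weighted      1.000   1.000 1.000      313
IAA exact   0.921
IAA relaxed 0.99
```

The CRF recovers the planted test-set mentions essentially perfectly on
the default benchmark; the simulated annotator's boundary perturbations
depress exact agreement well below relaxed agreement, as expected when
disagreements are about modifier inclusion rather than existence.

The same workflows are available from the shell:

```bash
phenoner generate --n 250 --style discharge --seed 0 --out corpus/ --second-annotator
phenoner experiment --corpus corpus/ --method crf --regime holdout --seed 0
phenoner agree --ann-a a.tsv --ann-b b.tsv --mode both
```

## Layout

```
src/phenoner/
  docmodel.py     documents, mentions, BIO coding, standoff + CoNLL I/O
  rules.py        token-pattern rule parser and matcher
  lexicon.py      gazetteer tagger with semantic-type filtering
  features.py     shared feature extraction incl. the affix registry
  labelers/       HMM, MEMM, linear-chain CRF and shared Viterbi
  evaluation.py   exact/relaxed scorer, IAA, splits, experiment harness
  synthetic.py    two-style annotated corpus generator
  cli.py          `phenoner` command-line entry points
  data/           starter rule pack and a small disorder lexicon
```

See `docs/methods.md` for modeling details, parameter defaults, and known
limitations.
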