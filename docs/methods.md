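# Methods

This note documents the models and procedures implemented in `phenoner`,
the defaults they use, and what the synthetic benchmark does and does not
establish.

## Document model and conventions

All character offsets are 0-based and end-exclusive; every mention surface
must equal its document slice, which the standoff reader enforces line by
line.  Tokenization of raw text splits on whitespace and then peels
leading/trailing punctuation into single-character tokens; sentence
boundaries fall at newlines (telegraphic EHR lists), at `.?!` followed by
whitespace and an uppercase letter, and around all-caps section headers
("HISTORY OF PRESENT ILLNESS:"), which form their own sentences.  This
tokenizer exists so the package is self-contained; pre-tagged CoNLL-style
input (token, start, end, POS, chunk, optional BIO label) bypasses it
entirely, and the synthetic generator emits its own gold tags, so no
external POS tagger is required anywhere.

Mentions are projected to BIO tags per sentence.  Two policies are worth
stating because annotated corpora leave them open:

* **Boundary snapping.**  A mention whose character boundaries fall inside
  a token is snapped outward to token boundaries, with a logged warning:
  annotators mark character spans, sequence labelers need token alignment,
  and outward snapping never discards annotated material.
* **BIO repair.**  When decoding tags back to mentions, an `I-` tag
  without a compatible predecessor is treated as `B-`.  Generative and
  locally normalized decoders cannot emit such sequences here (illegal
  transitions are hard-masked), but the CRF's transitions are soft, so the
  repair guarantees well-formed output for all models.

Mentions are contiguous and non-overlapping; discontinuous spans are out
of scope.

## Rule engine

Rules are one per line, `LABEL => spec, spec, ...`, each spec a bracketed
conjunction of attribute constraints with optional quantifier (`?` or
`{m,n}`).  Attributes: `token` (surface, case-insensitive), `syn` (POS,
case-sensitive), `sem` (semantic type; the pseudo-type `beverb` is
satisfied by a closed list of *be* forms so the canonical pattern works
without any lexicon), `orth` (coarse orthographic class).  Matching is
leftmost-longest per sentence: at each start position every iterator
expansion is explored with backtracking, the longest successful span wins,
and scanning resumes after it, so a single rule never yields overlapping
matches.  Across rules, conflicts are resolved by earlier start, then
longer span, then lower source line — a deterministic total order that
makes rule packs reproducible.  The shipped starter pack contains the
documented worked pattern plus a few variants for the bundled vocabulary;
it is a demonstration pack, not a reconstruction of any production rule
set.

## Dictionary baseline

The gazetteer maps terms to semantic types and is applied by greedy
longest match, left to right, case-insensitively, with mentions emitted
only for allowed semantic types (mirroring how concept taggers are
restricted to disorder-group types for phenotype work).  There is
deliberately no fuzzy matching and no variant generation: missing a
misspelled term ("aneamia") and fragmenting an out-of-dictionary multiword
expression ("worsened renal function" → "renal function") are properties
of dictionary baselines this module exists to exhibit.

## Shared features

All sequence labelers consume the same binary indicator features so that
model comparisons isolate the model class:

* token identity, POS, chunk and compressed word shape at every offset in
  a symmetric window (default ±2; boundary positions emit `<s>`/`</s>`);
* affix features at the focus position only: each prefix/suffix of length
  2–5 of the token that appears in the **affix registry**, the set of
  affixes harvested from all tokens inside gold training mentions.  The
  registry is a closed look-up list — affixes outside it never fire — so
  productive clinical morphology (*hyper-*, *-emia*) generalizes to unseen
  words without an open feature space.

## Labelers

The label space is the 9-tag BIO expansion of the four classes, kept
sorted so that argmax ties break toward the lexicographically smallest
tag and decoding is deterministic.

**HMM.**  Transitions and initial probabilities are add-α smoothed counts
(α = 0.1).  A classical HMM emits one symbol; to integrate several
observation streams the emission factorizes naive-Bayes style across
feature families (word, POS, chunk, shape, longest registry prefix and
suffix), each an add-α smoothed categorical with an explicit unseen-value
floor — every table row sums to one within 1e-9, which the tests assert.
The emission uses the focus token only; context enters through
transitions.  States absent from training are masked unreachable at
decode time, with a warning at training time.

**MEMM.**  One multinomial logistic model over labels conditioned on the
shared features plus a previous-label indicator (synthetic START at the
first position).  The objective is the mean per-position negative
conditional log-likelihood plus (λ/2n)‖W‖², λ = 1.0 — the same optimum as
the conventional sum-form objective, but with a scale-free convergence
contract: training raises an error reporting the final gradient
infinity-norm if L-BFGS stops above 1e-4.  Local per-position
normalization is retained deliberately; it is what exposes the label-bias
problem the model family is known for.

**CRF.**  Linear-chain, globally normalized, with observation weights over
the same shared features and a (K+1)×K transition block including a START
row.  Training minimizes the mean penalized negative log-likelihood
(λ = 0.1, max 200 L-BFGS iterations) with gradients from forward–backward
marginals computed in log space.  Transitions stay soft (see BIO repair
above).  The convex optimization is delegated to scipy's L-BFGS; the model,
objective and gradients are implemented here.

Decoding for all three models reduces to one lattice form (scores for the
first position plus per-step previous×current score matrices) searched by
a single Viterbi routine, which the tests check against exhaustive path
enumeration on small instances for all three families.

Models serialize to versioned JSON containing the feature configuration
and its hash; loading refuses a file whose stored hash does not match its
embedded configuration, so a model can never silently be decoded with the
wrong feature layer.

## Evaluation and agreement

Exact matching requires identical (document, boundaries, label); relaxed
matching requires a same-label overlap of at least one character, with
true positives counted separately on the gold side (recall) and prediction
side (precision) — the standard partial-match convention that keeps
many-to-one overlaps well-defined and makes "adding a correct prediction
never lowers recall" a theorem.  Label agreement is required in relaxed
mode too; without it, relaxed scores would not decompose by class.  Three
aggregates are always reported — micro (pooled counts), macro (unweighted
class mean), weighted (gold-support weighted) — because published tables
are often ambiguous about which aggregate a summary row is; every row's F
is the harmonic mean of that row's P and R, and zero-denominator cells are
0 with support shown.  IAA is the same scorer with one annotator as gold;
F is symmetric under swapping annotators (precision and recall exchange),
which the tests verify.

Splits are document-level: an 80/20 holdout (train size = round(0.8·N)),
k-fold with fold sizes differing by at most one, and a cross-text-type
regime (train on one style, test on the other, both directions).  All
splits are reproducible from their seed.

## Synthetic corpus generator

The generator is the package's test bed, emulating the structural
properties of a double-annotated two-style phenotype corpus:

* **Styles.**  Discharge documents: all-caps section headers with short
  telegraphic sentences.  Article documents: full sentences.  Default
  class mixes are style-skewed — sign/symptom-heavy for discharge text
  (0.55), cause- and kidney-factor-heavy for articles (0.30/0.35) —
  matching the qualitative contrast between EHR narratives and the
  cardiology literature.
* **Mentions.**  Drawn from closed per-class phrase vocabularies with
  Zipf-skewed frequencies, plus compositional in-span modifiers
  ("recurrent", "progressive", …; probability 0.3) shared across classes.
  The sharing is intentional: tokens like "disease", "elevated", "acute"
  and the modifiers occur in several classes, so class identity requires
  context rather than memorization.  Mention counts per document are
  Poisson (mean 6).
* **Noise.**  Non-mention alphabetic filler tokens of length ≥ 3 are
  misspelled by one random single-character edit with probability 0.10 in
  the discharge style (0 for articles), matching the error rate reported
  for EHR narrative text.  Mentions are never misspelled by default (a
  separate flag enables it), so labeler recovery floors are stable.
* **Second annotator.**  With a configurable noise probability a mention
  is shrunk by its leading token, extended over an adjacent free modifier,
  or occasionally dropped — labels preserved.  This reproduces the
  dominant real-world disagreement pattern (modifier inclusion), including
  the canonical "significant left atrial dilation" / "left atrial
  dilation" pair.

What the generator does **not** emulate: real vocabulary breadth,
abbreviation ambiguity, negation and uncertainty scoping, section-specific
semantics, discontinuous mentions.  Passing tests on this corpus
establishes that the implementations are correct and well-behaved, not
that their absolute scores transfer to real clinical text — on the default
benchmark (200 training / 50 test discharge documents) the planted
structure is learnable enough that the CRF reaches micro-F ≈ 1.0 and the
HMM ≈ 0.99, far above what heterogeneous real corpora allow.

## Problem sizes

The default benchmark used by the test suite and the acceptance script is
250 discharge documents (80/20 split); the pooled cross-validation corpus
is 80 discharge + 40 article documents with 5 folds.  These sizes give
stable scores (≈1,500 and ≈900 gold mentions respectively) while keeping
a full run of suite plus script to a few minutes on one CPU.

## Known limitations

* The rule language has no lookahead/lookbehind beyond the token sequence
  and no rule learning.
* The dictionary module does no concept normalization (no CUI mapping).
* The MEMM/CRF convergence contract assumes the default optimizer
  tolerances; extremely large λ or degenerate single-class corpora
  converge trivially, while pathological feature collisions could in
  principle exhaust the iteration cap, which raises rather than returning
  a half-trained model.
* Cross-seed variance on the synthetic benchmark is small but real; the
  qualitative model ranking (CRF ≥ HMM ≥ MEMM) holds at the default seed
  and in most seeds tested, but individual seeds can invert the small
  HMM/MEMM gap.
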