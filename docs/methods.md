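# Methods

`ontoextend` implements a semi-automatic ontology-extension method for
domain ontologies whose classes are easy to find in text by their labels
and synonyms (the motivating case is the Human Disease Ontology applied to
biomedical full-text articles). The premise is distributional: terms that
name classes of the same kind occur in similar lexical contexts, so a
context embedding of a term (or of a class, once its mentions are
normalized to its identifier) carries enough signal to decide (a) whether
an unseen term belongs to the ontology's domain at all, and (b) under
which high-level superclass a class belongs.

## The two workflows

**Label-based (term discovery).** Build a dictionary from all labels and
synonyms of the ontology's classes. Train skip-gram embeddings on the raw
(preprocessed) corpus. Use the in-vocabulary dictionary terms as positive
examples and a uniform random sample of the remaining vocabulary as
negatives (equal in number by default), train the classifier, and score
every non-dictionary vocabulary token. High-scoring tokens are candidate
new labels or synonyms for curator review.

**Annotation-based (subclass-axiom discovery).** Annotate class mentions
in the corpus with a greedy longest-match dictionary annotator, replace
every matched span by the class identifier, and train skip-gram on the
normalized stream so each class gets its own context vector. Labels for
supervised training come from the reflexive-transitive is_a closure: given
an ordered list of superclasses, each class is labeled with the first
listed superclass among its ancestors, or "other". Classes labeled
"other" whose embedding the trained model assigns to a listed superclass
become candidate subclass axioms.

## Model components and defaults

- **Preprocessing.** Lowercasing, removal of ASCII punctuation except
  intra-word hyphens (clinical terms like "limb-shaking" must survive as
  one token), whitespace tokenization, and a small bundled English
  stop-word list (configurable by file). Dictionary keys pass through the
  same pipeline, so matching is token-to-token.
- **Annotation.** Greedy longest-match left-to-right; matches never
  overlap; an ambiguous surface form carries all its class identifiers,
  and normalization resolves it to the lexicographically smallest one
  (logged). Coordinates are token-level, 0-based, half-open.
- **Embeddings.** Skip-gram with 5 negative samples per positive pair,
  drawn from the unigram^0.75 distribution. Defaults: 100 dimensions,
  symmetric window 5, minimum count 5 — the conventional word2vec
  settings. Input vectors start uniform in ±0.5/dim and context vectors
  at zero, so the initial predictive distribution is exactly uniform.
  Gradients are accumulated per mini-batch (2048 pairs) and applied with
  Adagrad (learning rate 0.1): with batched updates a frequent token can
  contribute hundreds of stale gradients per batch, and Adagrad's
  per-element normalization keeps that step bounded where plain
  accumulation diverges. Training is single-threaded and bit-reproducible
  per seed. The window is fixed (no random shrinking) and no frequent-word
  subsampling is applied; windows do not cross document boundaries.
- **Objective oracle.** The exact training criterion — the corpus-average
  log softmax probability of each context token given its center, over
  all pairs within the window — is implemented by full enumeration and
  used to verify the trainer: at the uniform start it equals −log |V|
  exactly, and trained vectors must beat it. It is quadratic in the
  vocabulary and intended for test-scale vocabularies (≲200).
- **Classifier.** A single-hidden-layer network: sigmoid hidden layer
  (default 200 units; the grid 10/50/100/200 is exercised by the
  benchmark driver), softmax output with one unit per label (the binary
  task is a 2-way softmax), cross-entropy loss, full-batch Adam (learning
  rate 0.01, 300 epochs), Xavier initialization from a seeded generator.
  Datasets here are hundreds of items with ~100 features, so full-batch
  training is cheap and exactly reproducible.
- **Evaluation.** Stratified 20% holdout plus stratified 10-fold
  cross-validation on the remaining 80%; fold metrics are computed on the
  held-in validation folds and the headline numbers on the untouched
  holdout. Per-label precision/recall/F and one-vs-rest ROC/AUC come from
  scikit-learn; multi-class summaries are macro averages (a documented
  choice — micro averaging would weight the "other" bucket heavily). A
  label absent from one side of a one-vs-rest split gets AUC 0.5 by
  convention so macro averaging stays total.
- **Suggestions.** New-term suggestions score all non-dictionary
  vocabulary tokens and keep those at or above a probability threshold
  (default 0.5); subclass-axiom suggestions are emitted only for classes
  outside every listed superclass, and never propose an edge already
  entailed by the closure. Reports are sorted by score, ties broken by
  token, so files are byte-reproducible.

## Reasoning

Only the OBO flat-file subset (id, name, synonym, is_a, is_obsolete) is
parsed, and reasoning is the reflexive-transitive closure over asserted
is_a edges. For a named-class hierarchy this is what superclass
partitioning consumes; classes whose placement is entailed only through
logical definitions (equivalence axioms, existential restrictions) would
need a full EL reasoner and may be partitioned differently here. Classes
under several listed superclasses are resolved by list order and logged;
obsolete terms are dropped and `alt_id` is ignored.

## The synthetic study conditions

Real-scale inputs (a reference disease ontology and ~10^6 full-text
articles) are neither shippable nor necessary to test the machinery, so a
generator produces conditions with known ground truth. Its ontology has
one root, `n_superclasses` children (default 4) and `classes_per_superclass`
leaves (default 40), each leaf carrying one label and 2 synonyms; the
second synonym is the two-token form "synonym label", whose component
tokens are themselves dictionary terms — this plants nested-prefix cases
that exercise the longest-match rule, and keeps every corpus token either
a dictionary term, a context word, or background. Each leaf is mentioned
18 times (6 per surface form, comfortably above the embedding min_count
of 5), flanked by 5 context tokens per side drawn from its superclass's
geometric-decay multinomial (decay 0.93 over 50 words) with probability
`context_mix`, else from a uniform background of 300 words; background
filler (10 tokens per background word) keeps a realistic negative pool.
Mention windows and filler are shuffled into documents of 20 such units.
`context_mix=1` is the separable benchmark (the pipeline must reach
holdout macro F ≥ 0.9 and macro AUC ≥ 0.95); `context_mix=0` is the null
benchmark (identical context distributions; macro AUC must average within
[0.4, 0.6] over seeds — a single 32-item holdout has sampling noise of
~0.05, so the band is assessed on the mean).

What the generator does *not* emulate: real syntax, polysemy and
disease/phenotype ambiguity, inflectional term variants, frequency skew
across classes, and multi-parent leaves. Passing the synthetic benchmarks
therefore shows the pipeline is correct and sensitive to context signal,
not that real-corpus performance will match.

**Recovery challenges.** `plant_challenges` removes one single-token
synonym from the ontology (the corpus keeps mentioning it) and deletes one
is_a edge in another superclass. The held-out synonym must rank in the top
5% of new-term candidates; the deleted edge must return as the top
subclass-axiom suggestion. Two scale-driven choices: (1) the orphaned
class is the sole "other" item and cannot be stratified into 10 folds, so
the pipeline drops labels thinner than the fold count from the *training*
set (logged) while the suggestion step still scores them directly from
ontology + embedding; (2) the held-out synonym is excluded from negative
sampling in the recovery driver — in a realistic vocabulary the chance of
drawing one specific unseen term as a negative is negligible, whereas in a
~500-token pool it would be drawn often and the experiment would measure
sampling luck instead of ranking ability.

## Reproducibility

Every stochastic step takes a seed; a run configuration's single seed fans
out deterministically to per-stage seeds (embedding, negative sampling,
splitting, classifier). A pipeline run writes a manifest with SHA-256
checksums of every artifact; identical config + seed reproduces identical
checksums. Problem sizes used by the shipped benchmarks (generator
defaults above; 30-epoch toy corpora for oracle checks; 100 random DAGs of
≤50 nodes for the closure check) were chosen so the whole suite runs on a
single CPU in minutes.

## Known limitations

- Dictionary matching has no term-variant expansion (plurals,
  inflections); a surface form must match token-for-token.
- The closure-based stand-in for a reasoner misses entailments through
  defined classes (see Reasoning above).
- The skip-gram trainer is a mini-batch approximation of the classical
  per-pair update; it is validated against the exact objective oracle on
  small vocabularies rather than against a reference implementation.
- Multi-word dictionary entries participate in annotation and
  normalization, but only single-token forms can be positives in the
  label-based workflow (an n-token surface form has no single vector).
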