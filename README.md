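# ontoextend

Semi-automatic extension of domain ontologies from text corpora.

Biomedical ontologies such as the Human Disease Ontology are curated by
hand, and keeping their labels, synonyms, and subclass axioms in step with
the literature is slow. `ontoextend` implements a machine-learning
pipeline that helps curators do this: it uses the ontology's existing
labels and synonyms as seeds, represents every term by the lexical context
it occurs in, and trains a shallow neural classifier to (a) find corpus
terms that behave like ontology terms but are missing from the ontology
(candidate labels/synonyms), and (b) place classes under high-level
superclasses they are not yet asserted under (candidate subclass axioms).
It is aimed at ontology engineers and text-mining researchers.

## Method

Given an ontology *O* (OBO flat file: `id`, `name`, `synonym`, `is_a`) and
a corpus *T* (directory of UTF-8 text files):

1. **Dictionary.** Every label and synonym of every non-obsolete class
   becomes a normalized surface form mapping to its class id(s).
2. **Concept recognition.** A greedy longest-match annotator finds
   mentions; in the *annotation-based* workflow every matched span is
   replaced by the class identifier, so classes become vocabulary items.
3. **Context embeddings.** Skip-gram with negative sampling learns a
   vector V(w) for every vocabulary item w (word or class identifier) by
   maximizing the average log probability of context tokens within a
   window c around each center token,

       (1/K) Σₖ Σ_{−c≤j≤c, j≠0} log p(w_{k+j} | w_k),

   with the conventional defaults: 100 dimensions, window 5, minimum
   count 5. An exact full-softmax implementation of this objective is
   included as a test oracle for the trainer.
4. **Classification.** A single-hidden-layer network (sigmoid hidden
   layer, default 200 units; softmax output) is trained on the
   embeddings — either labels/synonyms vs. random vocabulary (binary), or
   superclass membership labels derived from the reflexive-transitive
   `is_a` closure (multi-class, k listed superclasses + "other").
   Evaluation uses a stratified 20% holdout plus 10-fold stratified
   cross-validation, reporting per-label F-score and ROC AUC with macro
   averages.
5. **Suggestions.** Non-dictionary tokens scoring above a threshold are
   proposed as new terms; "other"-labeled classes predicted into a listed
   superclass are proposed as subclass axioms. Both reports are ranked
   TSVs for curator review.

A bundled synthetic generator produces ontology + corpus fixtures with
planted class-specific context distributions, placement logs, and
recovery challenges (held-out synonyms, deleted `is_a` edges), so the
entire pipeline is testable without any external download. See
`docs/methods.md` for modeling details and limitations.

## Worked example

Generate a synthetic benchmark with one planted challenge — a synonym
removed from the ontology while the corpus keeps mentioning it — and run
both workflows:

```sh
ontoextend synth --out scratch/demo --seed 1 --synonym-holdouts 1
ontoextend run --config scratch/demo/config.json
```

where `config.json` is

```json
{
  "ontology_path": "scratch/demo/ontology.obo",
  "corpus_path": "scratch/demo/corpus",
  "out_dir": "scratch/demo/run",
  "workflow": "both",
  "scheme_name": "supergroups",
  "scheme_superclasses": ["SYN:0000001", "SYN:0000002",
                          "SYN:0000003", "SYN:0000004"],
  "seed": 1
}
```

The run prints its stage counts:

```
annotation_based.items   160     # embedded class identifiers
annotation_based.labels  4       # superclass scheme labels
annotations              2874    # recognized mentions
classes                  165     # 1 root + 4 superclasses + 160 leaves
dictionary_terms         484     # labels + synonyms (one held out)
documents                158
label_based.items        638     # binary dataset (positives + negatives)
label_based.suggestions  1
tokens                   35643
```

The binary holdout evaluation (`eval_binary.tsv`) shows macro F 0.992 and
macro AUC 0.996, and the single new-term suggestion
(`suggestions_new_terms.tsv`) is exactly the planted challenge:

```
token    kind      predicted_label  score     current_status
syn0q32  new_term  positive         0.997144  not_in_ontology
```

i.e. the synonym that was held out of the dictionary is recovered from
context alone with probability 0.997. The superclass report
(`eval_supergroups.tsv`) scores 1.0 on every label, and
`suggestions_axioms.tsv` is empty because no class sits outside the
scheme. Every run directory also contains the embeddings (word2vec text
format), datasets, model weights (JSON), ROC point files, and a
`manifest.json` with checksums: re-running the same config + seed
reproduces identical checksums.

`ontoextend benchmark --out table.tsv` runs the four-experiment ×
four-hidden-size grid (binary, two partial superclass schemes, combined)
and writes one F/AUC column pair per hidden size in {10, 50, 100, 200}.

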