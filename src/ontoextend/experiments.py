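"""End-to-end benchmark experiments on the synthetic study conditions.

These drivers wire the full pipeline together on generator output: build
the dictionary, annotate and (for the annotation-based workflow) normalize
the corpus, train embeddings, build the supervised dataset, cross-validate
the classifier, and score suggestions.  They back both the test suite and
the benchmark/acceptance entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ann import ANNConfig, CVResult, HIDDEN_SIZE_GRID, cross_validate, train_ann
from .datasets import (
    OTHER_LABEL,
    SplitConfig,
    build_binary_dataset,
    build_superclass_dataset,
    drop_thin_labels,
    split as split_dataset,
)
from .embeddings import EmbeddingConfig, EmbeddingMatrix, train_skipgram
from .ontology import Ontology, build_term_dictionary
from .suggest import rank_candidates, suggest_subclass_axioms
from .synthetic import (
    ChallengeLog,
    CorpusBundle,
    SyntheticSpec,
    generate_corpus,
    generate_ontology,
    plant_challenges,
    super_id,
)
from .text import AnnotatedCorpus, annotate_corpus, normalize_mentions


@dataclass
class SyntheticRun:
    """Generator output plus the artifacts shared by the experiments."""

    spec: SyntheticSpec
    ontology: Ontology
    truth: dict[str, str]
    corpus: CorpusBundle
    challenge: ChallengeLog | None = None


def make_run(spec: SyntheticSpec,
             synonym_holdouts: int = 0,
             axiom_deletions: int = 0) -> SyntheticRun:
    ontology, truth = generate_ontology(spec)
    corpus = generate_corpus(ontology, truth, spec)
    challenge = None
    if synonym_holdouts or axiom_deletions:
        ontology, challenge = plant_challenges(
            ontology, spec,
            n_synonym_holdouts=synonym_holdouts,
            n_axiom_deletions=axiom_deletions)
    return SyntheticRun(spec=spec, ontology=ontology, truth=truth,
                        corpus=corpus, challenge=challenge)


def plain_embedding(run: SyntheticRun,
                    cfg: EmbeddingConfig | None = None) -> EmbeddingMatrix:
    """Embedding of the raw (non-normalized) token stream."""
    cfg = cfg or EmbeddingConfig(seed=run.spec.seed + 11)
    corpus = AnnotatedCorpus(documents=run.corpus.as_documents())
    return train_skipgram(corpus, cfg)


def normalized_embedding(run: SyntheticRun,
                         cfg: EmbeddingConfig | None = None,
                         ) -> EmbeddingMatrix:
    """Embedding of the mention-normalized stream (class ids in vocab)."""
    cfg = cfg or EmbeddingConfig(seed=run.spec.seed + 11)
    dictionary = build_term_dictionary(run.ontology)
    annotated = annotate_corpus(run.corpus.as_documents(), dictionary)
    return train_skipgram(normalize_mentions(annotated), cfg)


def scheme_superclasses(spec: SyntheticSpec) -> list[str]:
    return [super_id(si) for si in range(spec.n_superclasses)]


def annotation_benchmark(spec: SyntheticSpec,
                         ann_cfg: ANNConfig | None = None,
                         scheme: list[str] | None = None) -> CVResult:
    """Annotation-based workflow end to end: returns the CV result whose
    holdout report carries the benchmark macro F and AUC."""
    run = make_run(spec)
    emb = normalized_embedding(run)
    scheme = scheme or scheme_superclasses(spec)
    ds = build_superclass_dataset(emb, run.ontology, scheme)
    split_cfg = SplitConfig(seed=spec.seed + 13)
    cfg = ann_cfg or ANNConfig(seed=spec.seed + 17)
    return cross_validate(ds, cfg, split_cfg)


def null_benchmark(spec: SyntheticSpec | None = None, seed: int = 0,
                   ) -> CVResult:
    """Same run with context_mix=0: class contexts are statistically
    identical, so performance must stay at chance."""
    spec = spec or SyntheticSpec()
    return annotation_benchmark(replace(spec, context_mix=0.0, seed=seed))


def synonym_recovery(spec: SyntheticSpec) -> tuple[float, int]:
    """Label-based recovery of a synonym held out of the dictionary.

    Returns (rank fraction of the held-out token among all non-dictionary
    candidates, candidate count); rank fraction 0 means best.  The held-out
    token is excluded from negative sampling: at the full-corpus scale this
    experiment emulates, the vocabulary outnumbers the negative sample by
    orders of magnitude and the chance of drawing one specific unseen term
    is negligible, whereas at synthetic scale it would dominate the outcome.
    """
    run = make_run(spec, synonym_holdouts=1)
    assert run.challenge is not None
    held_out = run.challenge.held_out_synonyms[0][1]
    emb = plain_embedding(run)
    dictionary = build_term_dictionary(run.ontology)
    ds = build_binary_dataset(emb, dictionary, neg_ratio=1.0,
                              seed=run.spec.seed + 12)
    keep = np.array([t != held_out for t in ds.tokens])
    if not keep.all():
        ds = ds.subset(keep)
    train, _, _ = split_dataset(ds, SplitConfig(seed=spec.seed + 13))
    model = train_ann(train, ANNConfig(seed=spec.seed + 17))
    ranked = rank_candidates(model, emb, dictionary)
    tokens = [t for t, _ in ranked]
    if held_out not in tokens:
        return 1.0, len(tokens)
    return tokens.index(held_out) / len(tokens), len(tokens)


def axiom_recovery(spec: SyntheticSpec) -> tuple[bool, list]:
    """Annotation-based recovery of a deleted is_a edge.

    The deleted edge pushes its class into the "other" bucket, which is
    dropped from training (it is too thin to stratify); the trained
    superclass model then scores the orphaned class.  Returns whether the
    top subclass-axiom suggestion restores exactly the deleted edge, plus
    the suggestion list.
    """
    run = make_run(spec, axiom_deletions=1)
    assert run.challenge is not None
    child, parent = run.challenge.deleted_edges[0]
    emb = normalized_embedding(run)
    scheme = scheme_superclasses(spec)
    split_cfg = SplitConfig(seed=spec.seed + 13)
    ds = build_superclass_dataset(emb, run.ontology, scheme)
    ds, _ = drop_thin_labels(ds, min_members=split_cfg.n_folds)
    train, _, _ = split_dataset(ds, split_cfg)
    model = train_ann(train, ANNConfig(seed=spec.seed + 17))
    suggestions = suggest_subclass_axioms(model, run.ontology, scheme, emb)
    ok = bool(suggestions
              and suggestions[0].token == child
              and suggestions[0].predicted_label == parent)
    return ok, suggestions


@dataclass
class BenchmarkRow:
    experiment: str
    n_labels: int
    hidden_size: int
    macro_f: float
    macro_auc: float
    n_fold_reports: int


def run_benchmark_suite(spec: SyntheticSpec | None = None,
                        hidden_sizes: tuple[int, ...] = HIDDEN_SIZE_GRID,
                        ) -> list[BenchmarkRow]:
    """The four-experiment x hidden-size grid on the synthetic benchmark.

    Experiments: the binary term/other task on the plain embedding, two
    partial superclass schemes (listed supers + "other"), and the combined
    scheme listing every superclass.  Each cell is a full stratified-CV +
    holdout evaluation; the reported numbers are holdout macro F / AUC.
    """
    spec = spec or SyntheticSpec()
    run = make_run(spec)
    emb_plain = plain_embedding(run)
    emb_norm = normalized_embedding(run)
    dictionary = build_term_dictionary(run.ontology)
    supers = scheme_superclasses(spec)
    half = max(1, len(supers) // 2)
    datasets = {
        "binary": build_binary_dataset(emb_plain, dictionary,
                                       seed=spec.seed + 12),
        "groupA": build_superclass_dataset(emb_norm, run.ontology,
                                           supers[:half]),
        "groupB": build_superclass_dataset(emb_norm, run.ontology,
                                           supers[half:]),
        "combined": build_superclass_dataset(emb_norm, run.ontology, supers),
    }
    split_cfg = SplitConfig(seed=spec.seed + 13)
    rows: list[BenchmarkRow] = []
    for name, ds in datasets.items():
        for h in hidden_sizes:
            cv = cross_validate(
                ds, ANNConfig(hidden_size=h, seed=spec.seed + 17), split_cfg)
            rows.append(BenchmarkRow(
                experiment=name,
                n_labels=len(ds.label_names),
                hidden_size=h,
                macro_f=cv.holdout_report.macro_f,
                macro_auc=cv.holdout_report.macro_auc,
                n_fold_reports=len(cv.fold_reports)))
    return rows


def benchmark_table(rows: list[BenchmarkRow]) -> str:
    """Render the grid as a TSV with one row per experiment and one F/AUC
    column pair per hidden size (the conventional results-table shape)."""
    sizes = sorted({r.hidden_size for r in rows})
    header = ["experiment", "n_labels"]
    for h in sizes:
        header += [f"f_h{h}", f"auc_h{h}"]
    lines = ["\t".join(header)]
    experiments = list(dict.fromkeys(r.experiment for r in rows))
    for exp in experiments:
        sub = {r.hidden_size: r for r in rows if r.experiment == exp}
        row = [exp, str(sub[sizes[0]].n_labels)]
        for h in sizes:
            row += [f"{sub[h].macro_f:.4f}", f"{sub[h].macro_auc:.4f}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
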