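"""Run orchestration: both workflows end-to-end from a JSON configuration.

A run reads an OBO ontology and a text corpus, executes the requested
workflow(s), and writes every intermediate artifact (dictionary,
annotations, embeddings, datasets, models, evaluation reports, ROC points,
suggestions) into an output directory together with a manifest recording
the configuration, the per-stage seeds, item counts, and a checksum of
every file — so identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .ann import ANNConfig, cross_validate
from .datasets import (
    SplitConfig,
    build_binary_dataset,
    build_superclass_dataset,
    drop_thin_labels,
    split as split_dataset,
    write_dataset_tsv,
)
from .embeddings import EmbeddingConfig, save_word2vec_text, train_skipgram
from .ontology import (
    build_term_dictionary,
    load_ontology,
    subclass_closure,
    write_closure_tsv,
)
from .suggest import (
    suggest_new_terms,
    suggest_subclass_axioms,
    write_report,
)
from .text import (
    AnnotatedCorpus,
    DEFAULT_STOPWORDS,
    annotate_corpus,
    load_stopwords,
    normalize_mentions,
    read_corpus,
    write_annotations_tsv,
)

logger = logging.getLogger(__name__)

WORKFLOWS = ("label_based", "annotation_based", "both")


@dataclass
class RunConfig:
    """Everything a run needs; one seed fans out to per-stage seeds."""

    ontology_path: str
    corpus_path: str
    out_dir: str
    workflow: str = "both"
    scheme_name: str = "scheme"
    scheme_superclasses: list[str] = field(default_factory=list)
    other_label: str = "other"
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    suggestion_threshold: float = 0.5
    neg_ratio: float = 1.0
    stopwords_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"workflow must be one of {WORKFLOWS}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        for key, sub in (("embedding", EmbeddingConfig),
                         ("ann", ANNConfig), ("split", SplitConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def stage_seeds(self) -> dict[str, int]:
        return {"embedding": self.seed + 1, "negatives": self.seed + 2,
                "split": self.seed + 3, "ann": self.seed + 4}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run(cfg: RunConfig) -> Path:
    """Execute the configured workflow(s); returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    counts: dict[str, int] = {}
    stage = "load_ontology"
    try:
        ontology = load_ontology(cfg.ontology_path)
        counts["classes"] = len(ontology)

        stage = "build_dictionary"
        dictionary = build_term_dictionary(ontology)
        counts["dictionary_terms"] = dictionary.term_count
        counts["dictionary_classes"] = dictionary.class_count
        with open(out / "dictionary.tsv", "w", encoding="utf-8") as fh:
            fh.write("surface\tclass_ids\n")
            for key in sorted(dictionary.entries):
                fh.write(f"{key}\t"
                         f"{','.join(sorted(dictionary.entries[key]))}\n")

        stage = "read_corpus"
        stopwords = (load_stopwords(cfg.stopwords_path)
                     if cfg.stopwords_path else DEFAULT_STOPWORDS)
        documents = read_corpus(cfg.corpus_path, stopwords=stopwords)
        counts["documents"] = len(documents)
        counts["tokens"] = sum(len(d) for d in documents)

        emb_cfg = EmbeddingConfig(**{**cfg.embedding.__dict__,
                                     "seed": seeds["embedding"]})
        split_cfg = SplitConfig(**{**cfg.split.__dict__,
                                   "seed": seeds["split"]})
        ann_cfg = ANNConfig(**{**cfg.ann.__dict__, "seed": seeds["ann"]})

        if cfg.workflow in ("label_based", "both"):
            stage = "label_based.embedding"
            corpus = AnnotatedCorpus(documents=documents)
            emb = train_skipgram(corpus, emb_cfg)
            counts["label_based.vocab"] = len(emb)
            save_word2vec_text(emb, out / "embedding_words.w2v")

            stage = "label_based.dataset"
            ds = build_binary_dataset(emb, dictionary, cfg.neg_ratio,
                                      seed=seeds["negatives"])
            counts["label_based.items"] = len(ds)

            stage = "label_based.cross_validate"
            cv = cross_validate(ds, ann_cfg, split_cfg)
            _, _, tagged = split_dataset(ds, split_cfg)
            write_dataset_tsv(tagged, out / "dataset_binary.tsv")
            cv.holdout_report.to_tsv(out / "eval_binary.tsv")
            cv.holdout_report.roc_to_csv(out / "roc_binary")
            cv.model.save(out / "model_binary.json")
            logger.info("label_based holdout macro_f=%.3f macro_auc=%.3f",
                        cv.holdout_report.macro_f,
                        cv.holdout_report.macro_auc)

            stage = "label_based.suggest"
            terms = suggest_new_terms(cv.model, emb, dictionary,
                                      cfg.suggestion_threshold)
            counts["label_based.suggestions"] = len(terms)
            write_report(terms, out / "suggestions_new_terms.tsv")

        if cfg.workflow in ("annotation_based", "both"):
            stage = "annotation_based.annotate"
            annotated = annotate_corpus(documents, dictionary, stopwords)
            counts["annotations"] = len(annotated.annotations)
            write_annotations_tsv(annotated.annotations,
                                  out / "annotations.tsv")

            stage = "annotation_based.normalize"
            normalized = normalize_mentions(annotated)

            stage = "annotation_based.embedding"
            emb = train_skipgram(normalized, emb_cfg)
            counts["annotation_based.vocab"] = len(emb)
            save_word2vec_text(emb, out / "embedding_classes.w2v")

            stage = "annotation_based.dataset"
            if not cfg.scheme_superclasses:
                raise ValueError("annotation_based workflow needs "
                                 "scheme_superclasses")
            ds = build_superclass_dataset(emb, ontology,
                                          cfg.scheme_superclasses,
                                          cfg.other_label)
            ds, dropped = drop_thin_labels(ds, split_cfg.n_folds)
            counts["annotation_based.items"] = len(ds)
            counts["annotation_based.labels"] = len(ds.label_names)
            counts["annotation_based.dropped_labels"] = len(dropped)

            stage = "annotation_based.cross_validate"
            cv = cross_validate(ds, ann_cfg, split_cfg)
            _, _, tagged = split_dataset(ds, split_cfg)
            write_dataset_tsv(tagged, out / f"dataset_{cfg.scheme_name}.tsv")
            cv.holdout_report.to_tsv(out / f"eval_{cfg.scheme_name}.tsv")
            cv.holdout_report.roc_to_csv(out / f"roc_{cfg.scheme_name}")
            cv.model.save(out / f"model_{cfg.scheme_name}.json")
            logger.info("annotation_based holdout macro_f=%.3f "
                        "macro_auc=%.3f", cv.holdout_report.macro_f,
                        cv.holdout_report.macro_auc)

            stage = "annotation_based.closure"
            write_closure_tsv(subclass_closure(ontology),
                              out / "closure.tsv")

            stage = "annotation_based.suggest"
            axioms = suggest_subclass_axioms(cv.model, ontology,
                                             cfg.scheme_superclasses, emb,
                                             cfg.other_label)
            counts["annotation_based.suggestions"] = len(axioms)
            write_report(axioms, out / "suggestions_axioms.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "manifest"
    files = {p.name if p.parent == out else f"{p.parent.name}/{p.name}":
             _sha256(p)
             for p in sorted(out.rglob("*"))
             if p.is_file() and p.name != "manifest.json"}
    manifest = {
        "config": _config_dict(cfg),
        "stage_seeds": seeds,
        "counts": counts,
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
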