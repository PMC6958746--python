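"""Supervised datasets built from embeddings and ontology seeds.

The binary ("label-based") dataset takes in-vocabulary dictionary terms as
positives and a uniform random sample of the remaining vocabulary as
negatives.  The superclass ("annotation-based") dataset takes embedded class
identifiers with labels from the superclass partition.  Splitting is a
stratified holdout plus stratified k-fold assignment over the train part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .embeddings import EmbeddingMatrix
from .ontology import Ontology, TermDictionary, partition_by_superclasses

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "positive"
OTHER_LABEL = "other"


@dataclass
class SplitConfig:
    """Holdout fraction and fold count for evaluation."""

    holdout_fraction: float = 0.2
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class LabeledDataset:
    """Feature/label pairs keyed by token, with split and fold tags.

    ``split_tags[i]`` is "train" or "test"; ``folds[i]`` is the fold index
    for train items and -1 for test items (or everywhere before splitting).
    """

    tokens: list[str]
    features: np.ndarray
    labels: list[str]
    label_names: list[str]
    split_tags: list[str] = field(default_factory=list)
    folds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if len(self.features) != n or len(self.labels) != n:
            raise ValueError("tokens/features/labels length mismatch")
        unknown = set(self.labels) - set(self.label_names)
        if unknown:
            raise ValueError(f"labels outside label_names: {unknown}")
        if not self.split_tags:
            self.split_tags = ["train"] * n
        if not self.folds:
            self.folds = [-1] * n

    def __len__(self) -> int:
        return len(self.tokens)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            tokens=[self.tokens[i] for i in idx],
            features=self.features[idx],
            labels=[self.labels[i] for i in idx],
            label_names=list(self.label_names),
            split_tags=[self.split_tags[i] for i in idx],
            folds=[self.folds[i] for i in idx],
        )

    def train_part(self) -> "LabeledDataset":
        return self.subset(np.array([t == "train" for t in self.split_tags]))

    def test_part(self) -> "LabeledDataset":
        return self.subset(np.array([t == "test" for t in self.split_tags]))

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def build_binary_dataset(emb: EmbeddingMatrix,
                         dictionary: TermDictionary,
                         neg_ratio: float = 1.0,
                         seed: int = 0) -> LabeledDataset:
    """Positives = in-vocabulary dictionary terms; negatives = a uniform
    random sample (without replacement) of the non-seed vocabulary.

    Multi-word dictionary entries contribute only if their full surface form
    survived tokenization as a single vocabulary token (e.g. hyphenated);
    otherwise the entry is skipped and counted in a log line.
    """
    seeds: list[str] = []
    skipped_multiword = 0
    seen: set[str] = set()
    for key in sorted(dictionary.entries):
        if " " in key:
            skipped_multiword += 1
            continue
        if key in emb and key not in seen:
            seen.add(key)
            seeds.append(key)
    if skipped_multiword:
        logger.info("binary dataset: %d multi-word entries not embeddable "
                    "as single tokens; skipped", skipped_multiword)
    if not seeds:
        raise ValueError("no dictionary term is present in the vocabulary")
    pool = sorted(set(emb.vocab) - set(seeds) - set(dictionary.entries))
    n_neg = round(neg_ratio * len(seeds))
    if len(pool) < n_neg:
        raise ValueError(
            f"cannot sample {n_neg} negatives from {len(pool)} "
            f"non-seed vocabulary tokens"
        )
    rng = np.random.default_rng(seed)
    negatives = [pool[i] for i in rng.choice(len(pool), n_neg, replace=False)]
    tokens = seeds + negatives
    labels = [POSITIVE_LABEL] * len(seeds) + [OTHER_LABEL] * len(negatives)
    feats = np.stack([emb.get_vector(t) for t in tokens])
    return LabeledDataset(tokens=tokens, features=feats, labels=labels,
                          label_names=[POSITIVE_LABEL, OTHER_LABEL])


def build_superclass_dataset(emb: EmbeddingMatrix,
                             ontology: Ontology,
                             scheme: list[str],
                             other_label: str = OTHER_LABEL,
                             min_label_size: int | None = None,
                             ) -> LabeledDataset:
    """Embedded class identifiers labeled by their superclass partition.

    Classes whose identifier did not reach the embedding vocabulary are
    skipped and counted.  A label with fewer members than ``min_label_size``
    raises by default (recommending fold reduction); the pipeline may
    instead pass ``min_label_size=None`` handling thinning itself via
    :func:`drop_thin_labels`.
    """
    partition = partition_by_superclasses(ontology, scheme, other_label)
    tokens: list[str] = []
    labels: list[str] = []
    skipped = 0
    for cid in sorted(ontology.classes):
        if cid in emb:
            tokens.append(cid)
            labels.append(partition[cid])
        else:
            skipped += 1
    if skipped:
        logger.info("superclass dataset: %d classes absent from the "
                    "embedding vocabulary; skipped", skipped)
    if not tokens:
        raise ValueError("no ontology class identifier is in the vocabulary")
    feats = np.stack([emb.get_vector(t) for t in tokens])
    names = [s for s in scheme if s in set(labels)]
    if other_label in set(labels):
        names.append(other_label)
    ds = LabeledDataset(tokens=tokens, features=feats, labels=labels,
                        label_names=names)
    if min_label_size is not None:
        thin = {l: c for l, c in ds.label_counts().items()
                if c < min_label_size}
        if thin:
            raise ValueError(
                f"labels with fewer than {min_label_size} members: {thin}; "
                f"reduce the number of folds or drop these labels"
            )
    return ds


def drop_thin_labels(ds: LabeledDataset, min_members: int,
                     ) -> tuple[LabeledDataset, dict[str, int]]:
    """Remove items of labels with fewer than ``min_members`` members.

    Returns the reduced dataset and a map of dropped label -> member count.
    """
    counts = ds.label_counts()
    dropped = {l: c for l, c in counts.items() if c < min_members}
    if not dropped:
        return ds, {}
    mask = np.array([lab not in dropped for lab in ds.labels])
    out = ds.subset(mask)
    out.label_names = [l for l in ds.label_names if l not in dropped]
    logger.info("dropped thin labels: %s", dropped)
    return out, dropped


def split(ds: LabeledDataset, cfg: SplitConfig,
          ) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified holdout plus stratified fold assignment on the train part.

    Returns (train, test, full-with-tags); the third carries split tags and
    fold indices for every item.  Deterministic for a fixed seed.
    """
    y = np.asarray(ds.labels)
    counts = ds.label_counts()
    min_needed = cfg.n_folds
    idx = np.arange(len(ds))
    try:
        train_idx, test_idx = train_test_split(
            idx, test_size=cfg.holdout_fraction, stratify=y,
            random_state=cfg.seed)
    except ValueError as exc:
        thin = min(counts, key=counts.get)
        raise ValueError(
            f"stratified holdout impossible; thinnest label {thin!r} has "
            f"{counts[thin]} members") from exc
    y_train = y[train_idx]
    for lab, c in zip(*np.unique(y_train, return_counts=True)):
        if c < min_needed:
            raise ValueError(
                f"label {lab!r} has {c} training members, fewer than "
                f"n_folds={cfg.n_folds}")
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.seed)
    fold_of = np.full(len(ds), -1, dtype=int)
    for k, (_, val) in enumerate(skf.split(train_idx, y_train)):
        fold_of[train_idx[val]] = k
    tags = np.full(len(ds), "train", dtype=object)
    tags[test_idx] = "test"
    tagged = LabeledDataset(
        tokens=list(ds.tokens), features=ds.features,
        labels=list(ds.labels), label_names=list(ds.label_names),
        split_tags=list(tags), folds=[int(f) for f in fold_of])
    return tagged.train_part(), tagged.test_part(), tagged


def write_dataset_tsv(ds: LabeledDataset, path: str | Path) -> None:
    """Export ``token<TAB>label<TAB>split<TAB>fold`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token\tlabel\tsplit\tfold\n")
        for t, lab, tag, fold in zip(ds.tokens, ds.labels,
                                     ds.split_tags, ds.folds):
            fh.write(f"{t}\t{lab}\t{tag}\t{fold}\n")
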