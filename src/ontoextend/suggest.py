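"""Ontology-extension suggestions from trained classifiers.

Two kinds of candidates are produced for curator review: vocabulary tokens
that are not dictionary terms but score high under the binary
disease-vs-other model (candidate new labels/synonyms), and classes that
sit outside every listed superclass in the ontology but whose context
embedding is classified into one of them (candidate subclass axioms).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .ann import ANNModel
from .datasets import OTHER_LABEL, POSITIVE_LABEL
from .embeddings import EmbeddingMatrix
from .ontology import Ontology, TermDictionary, partition_by_superclasses, subclass_closure


@dataclass
class ExtensionSuggestion:
    token: str
    suggestion_kind: Literal["new_term", "subclass_axiom"]
    predicted_label: str
    score: float
    current_status: Literal["not_in_ontology", "in_ontology_other_branch"]

    def sort_key(self) -> tuple[float, str]:
        return (-self.score, self.token)


def suggest_new_terms(model: ANNModel,
                      emb: EmbeddingMatrix,
                      dictionary: TermDictionary,
                      threshold: float = 0.5) -> list[ExtensionSuggestion]:
    """Score every non-dictionary vocabulary token with the binary model and
    return those at or above the threshold, best first."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    pos_idx = model.label_names.index(POSITIVE_LABEL)
    candidates = [t for t in emb.vocab if t not in dictionary]
    if not candidates:
        return []
    X = np.stack([emb.get_vector(t) for t in candidates])
    scores = model.predict_proba(X)[:, pos_idx]
    out = [
        ExtensionSuggestion(token=t, suggestion_kind="new_term",
                            predicted_label=POSITIVE_LABEL,
                            score=float(s),
                            current_status="not_in_ontology")
        for t, s in zip(candidates, scores) if s >= threshold
    ]
    out.sort(key=ExtensionSuggestion.sort_key)
    return out


def rank_candidates(model: ANNModel, emb: EmbeddingMatrix,
                    dictionary: TermDictionary) -> list[tuple[str, float]]:
    """All non-dictionary vocabulary tokens with their positive-class score,
    best first (the threshold-free view used for recovery experiments)."""
    full = suggest_new_terms(model, emb, dictionary, threshold=1e-12)
    return [(s.token, s.score) for s in full]


def suggest_subclass_axioms(model: ANNModel,
                            ontology: Ontology,
                            scheme: list[str],
                            emb: EmbeddingMatrix,
                            other_label: str = OTHER_LABEL,
                            ) -> list[ExtensionSuggestion]:
    """Propose child -> superclass axioms for out-of-scheme classes.

    A class whose partition label is ``other_label`` (it is under none of
    the listed superclasses) but whose embedding the model assigns to a
    listed superclass becomes a ``subclass_axiom`` suggestion carrying the
    model probability.  Classes already under their predicted superclass by
    closure are never suggested.
    """
    partition = partition_by_superclasses(ontology, scheme, other_label)
    closure = subclass_closure(ontology)
    candidates = [cid for cid in sorted(ontology.classes)
                  if partition[cid] == other_label and cid in emb]
    if not candidates:
        return []
    X = np.stack([emb.get_vector(c) for c in candidates])
    proba = model.predict_proba(X)
    out: list[ExtensionSuggestion] = []
    for cid, p in zip(candidates, proba):
        j = int(np.argmax(p))
        pred = model.label_names[j]
        if pred == other_label or pred not in scheme:
            continue
        if pred in closure[cid]:
            continue  # already entailed; nothing to add
        out.append(ExtensionSuggestion(
            token=cid, suggestion_kind="subclass_axiom",
            predicted_label=pred, score=float(p[j]),
            current_status="in_ontology_other_branch"))
    out.sort(key=ExtensionSuggestion.sort_key)
    return out


def write_report(suggestions: Sequence[ExtensionSuggestion],
                 path: str | Path) -> None:
    """TSV report ordered by score descending, ties broken by token."""
    ordered = sorted(suggestions, key=ExtensionSuggestion.sort_key)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token\tkind\tpredicted_label\tscore\tcurrent_status\n")
        for s in ordered:
            fh.write(f"{s.token}\t{s.suggestion_kind}\t{s.predicted_label}\t"
                     f"{s.score:.6f}\t{s.current_status}\n")


def write_obo_fragment(suggestions: Sequence[ExtensionSuggestion],
                       path: str | Path) -> None:
    """Emit accepted subclass suggestions as OBO ``is_a`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(suggestions, key=ExtensionSuggestion.sort_key):
            if s.suggestion_kind == "subclass_axiom":
                fh.write(f"[Term]\nid: {s.token}\n"
                         f"is_a: {s.predicted_label}\n\n")
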