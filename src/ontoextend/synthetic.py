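"""Synthetic ontology + corpus generator with planted ground truth.

The generator emulates the statistical premise of the real setting: terms
that name classes under the same high-level superclass occur in similar
lexical contexts.  It emits a small ontology (one root, a layer of
superclasses, leaf classes with labels and synonyms) and a corpus in which
every leaf class is mentioned a fixed number of times, each mention
surrounded by tokens drawn from its superclass-specific context
distribution (a geometric-decay multinomial over a per-superclass
vocabulary) with probability ``context_mix``, else from a uniform
background distribution.  ``context_mix=1`` gives the separable benchmark,
``context_mix=0`` the null benchmark where all contexts are statistically
identical.

Everything is reproducible per seed, and a placement log records every
planted mention span so annotation output can be checked exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ontology import Ontology, OntologyClass
from .text import Document

UNITS_PER_DOC = 20
FILLER_TOKENS_PER_BACKGROUND_WORD = 10
CONTEXT_DECAY = 0.93

ROOT_ID = "SYN:0000000"


@dataclass
class SyntheticSpec:
    """Shape and noise parameters of the synthetic study conditions.

    Defaults are sized so a full end-to-end run (annotation, embedding,
    cross-validated classification) completes in well under five minutes on
    one CPU while every surface form still clears the embedding
    ``min_count`` of 5 (18 mentions cycle over 3 surface forms, 6 each).
    """

    n_superclasses: int = 4
    classes_per_superclass: int = 40
    synonyms_per_class: int = 2
    context_vocab_per_superclass: int = 50
    background_vocab: int = 300
    mentions_per_class: int = 18
    context_mix: float = 1.0
    window_fill: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.context_mix <= 1:
            raise ValueError("context_mix must be in [0, 1]")
        if self.n_superclasses < 1 or self.classes_per_superclass < 1:
            raise ValueError("need at least one superclass and one class")
        if self.window_fill < 1:
            raise ValueError("window_fill must be >= 1")


def super_id(si: int) -> str:
    return f"SYN:{si + 1:07d}"


def leaf_id(spec: SyntheticSpec, si: int, ci: int) -> str:
    return f"SYN:{1000 + si * spec.classes_per_superclass + ci:07d}"


def _leaf_label(si: int, ci: int) -> str:
    return f"term{si}q{ci}"


def _leaf_synonyms(si: int, ci: int, count: int) -> list[str]:
    """First synonym is a single token; the second is the two-token form
    '<synonym> <label>' whose components are themselves dictionary terms
    (this plants nested-prefix cases for the longest-match annotator);
    further synonyms are single tokens again."""
    out: list[str] = []
    if count >= 1:
        out.append(f"syn{si}q{ci}")
    if count >= 2:
        out.append(f"syn{si}q{ci} {_leaf_label(si, ci)}")
    for k in range(3, count + 1):
        out.append(f"alt{k}{si}q{ci}")
    return out


def generate_ontology(spec: SyntheticSpec,
                      ) -> tuple[Ontology, dict[str, str]]:
    """Build the synthetic ontology and the ground-truth leaf -> superclass
    map (consistent with the subclass closure by construction)."""
    classes: dict[str, OntologyClass] = {
        ROOT_ID: OntologyClass(id=ROOT_ID, label="generalcondition")
    }
    truth: dict[str, str] = {}
    for si in range(spec.n_superclasses):
        sid = super_id(si)
        classes[sid] = OntologyClass(id=sid, label=f"supergroup{si}",
                                     parents={ROOT_ID})
        for ci in range(spec.classes_per_superclass):
            lid = leaf_id(spec, si, ci)
            classes[lid] = OntologyClass(
                id=lid, label=_leaf_label(si, ci),
                synonyms=set(_leaf_synonyms(si, ci, spec.synonyms_per_class)),
                parents={sid})
            truth[lid] = sid
    return Ontology(classes=classes), truth


@dataclass
class PlantedMention:
    doc_id: str
    start_token: int
    end_token: int
    surface: str
    class_id: str


@dataclass
class CorpusBundle:
    """Raw documents plus the generator's placement log."""

    documents: list[tuple[str, str]]  # (doc_id, raw text)
    placements: list[PlantedMention]

    def as_documents(self) -> list[Document]:
        """Token view (generator tokens are already clean and lowercase,
        so this equals the preprocessed view)."""
        return [Document(doc_id=d, tokens=t.split())
                for d, t in self.documents]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for doc_id, text in self.documents:
            (directory / f"{doc_id}.txt").write_text(text + "\n",
                                                     encoding="utf-8")

    def write_placement_log(self, path: str | Path) -> None:
        rows = [asdict(p) for p in self.placements]
        Path(path).write_text(json.dumps(rows, indent=0, sort_keys=True),
                              encoding="utf-8")


def _context_distribution(si: int, size: int) -> tuple[list[str], np.ndarray]:
    words = [f"ctx{si}w{j}" for j in range(size)]
    w = CONTEXT_DECAY ** np.arange(size)
    return words, w / w.sum()


def generate_corpus(ontology: Ontology, truth: dict[str, str],
                    spec: SyntheticSpec) -> CorpusBundle:
    """Plant ``mentions_per_class`` mentions of every leaf class, each
    flanked by ``window_fill`` context tokens per side, plus uniform
    background filler; shuffle the resulting units into documents."""
    rng = np.random.default_rng(spec.seed + 1)
    ctx = {super_id(si): _context_distribution(
               si, spec.context_vocab_per_superclass)
           for si in range(spec.n_superclasses)}
    bg_words = [f"bg{j:04d}" for j in range(spec.background_vocab)]

    def fill(sid: str, k: int) -> list[str]:
        out = []
        for _ in range(k):
            if spec.background_vocab and (
                    spec.context_mix < 1.0
                    and rng.random() >= spec.context_mix):
                out.append(bg_words[rng.integers(spec.background_vocab)])
            else:
                words, p = ctx[sid]
                out.append(words[rng.choice(len(words), p=p)])
        return out

    units: list[tuple[list[str], tuple[int, int, str, str] | None]] = []
    for lid in sorted(truth):
        cls = ontology.classes[lid]
        forms = [cls.label] + sorted(cls.synonyms, key=lambda s: (len(s.split()), s))
        sid = truth[lid]
        for m in range(spec.mentions_per_class):
            surface = forms[m % len(forms)]
            s_toks = surface.split()
            left = fill(sid, spec.window_fill)
            right = fill(sid, spec.window_fill)
            toks = left + s_toks + right
            span = (len(left), len(left) + len(s_toks), surface, lid)
            units.append((toks, span))

    if spec.background_vocab:
        width = 2 * spec.window_fill + 1
        n_units = math.ceil(
            FILLER_TOKENS_PER_BACKGROUND_WORD * spec.background_vocab / width)
        for _ in range(n_units):
            toks = [bg_words[i]
                    for i in rng.integers(spec.background_vocab, size=width)]
            units.append((toks, None))

    order = rng.permutation(len(units))
    documents: list[tuple[str, str]] = []
    placements: list[PlantedMention] = []
    for d0 in range(0, len(order), UNITS_PER_DOC):
        doc_id = f"doc{d0 // UNITS_PER_DOC:04d}"
        toks: list[str] = []
        for u in order[d0 : d0 + UNITS_PER_DOC]:
            unit_toks, span = units[u]
            if span is not None:
                s, e, surface, lid = span
                placements.append(PlantedMention(
                    doc_id=doc_id, start_token=len(toks) + s,
                    end_token=len(toks) + e, surface=surface, class_id=lid))
            toks.extend(unit_toks)
        documents.append((doc_id, " ".join(toks)))
    placements.sort(key=lambda p: (p.doc_id, p.start_token))
    return CorpusBundle(documents=documents, placements=placements)


@dataclass
class ChallengeLog:
    """Record of planted recovery challenges.

    ``held_out_synonyms``: (class_id, synonym, superclass) triples whose
    synonym was removed from the ontology (the corpus keeps its mentions).
    ``deleted_edges``: (child, parent) is_a edges removed before training-
    label partitioning, so the child now falls into the "other" bucket.
    """

    held_out_synonyms: list[tuple[str, str, str]] = field(default_factory=list)
    deleted_edges: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"held_out_synonyms": self.held_out_synonyms,
                   "deleted_edges": self.deleted_edges}
        Path(path).write_text(json.dumps(payload, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChallengeLog":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            held_out_synonyms=[tuple(x) for x in d["held_out_synonyms"]],
            deleted_edges=[tuple(x) for x in d["deleted_edges"]])


def plant_challenges(ontology: Ontology, spec: SyntheticSpec,
                     n_synonym_holdouts: int = 1,
                     n_axiom_deletions: int = 1,
                     ) -> tuple[Ontology, ChallengeLog]:
    """Create recovery challenges on a copy of the ontology.

    Synonym holdouts remove one single-token synonym from a designated
    class (the corpus keeps mentioning it); axiom deletions remove the
    is_a edge of a designated class in a *different* superclass, so at
    least one class per superclass stays intact and the two challenge
    kinds never collide on the same class.
    """
    if n_synonym_holdouts and spec.synonyms_per_class < 1:
        raise ValueError("synonym holdout needs synonyms_per_class >= 1")
    rng = np.random.default_rng(spec.seed + 2)
    classes = {cid: OntologyClass(id=c.id, label=c.label,
                                  synonyms=set(c.synonyms),
                                  parents=set(c.parents))
               for cid, c in ontology.classes.items()}
    log = ChallengeLog()
    for k in range(n_synonym_holdouts):
        si = k % spec.n_superclasses
        ci = int(rng.integers(spec.classes_per_superclass))
        lid = leaf_id(spec, si, ci)
        syn = f"syn{si}q{ci}"
        classes[lid].synonyms.discard(syn)
        log.held_out_synonyms.append((lid, syn, super_id(si)))
    for k in range(n_axiom_deletions):
        si = spec.n_superclasses - 1 - (k % spec.n_superclasses)
        ci = int(rng.integers(spec.classes_per_superclass))
        lid = leaf_id(spec, si, ci)
        parent = super_id(si)
        classes[lid].parents.discard(parent)
        log.deleted_edges.append((lid, parent))
    return Ontology(classes=classes), log
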