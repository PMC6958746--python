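"""Ontology loading, subclass reasoning, and term-dictionary construction.

The loader reads the OBO flat-file subset that reference ontologies such as
the Human Disease Ontology ship (``[Term]`` stanzas with ``id``, ``name``,
``synonym``, ``is_a``, ``is_obsolete``); full OWL parsing is deliberately out
of scope.  Reasoning is the reflexive-transitive closure over asserted
``is_a`` edges, which is what the named-class hierarchy of an EL ontology
reduces to for superclass partitioning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_SYNONYM_TEXT = re.compile(r'^\s*"(.*)"')


class OntologyFormatError(ValueError):
    """Raised when an OBO file cannot be parsed into a valid ontology."""


class OntologyCycleError(ValueError):
    """Raised when the asserted is_a graph contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("is_a cycle detected: " + " -> ".join(cycle + [cycle[0]]))


@dataclass
class OntologyClass:
    """A named class with its surface forms and asserted parents."""

    id: str
    label: str
    synonyms: set[str] = field(default_factory=set)
    parents: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyFormatError("class with empty id")
        if not self.label:
            raise OntologyFormatError(f"class {self.id!r} has an empty label")
        if self.id in self.parents:
            raise OntologyFormatError(f"class {self.id!r} lists itself as parent")

    @property
    def surface_forms(self) -> set[str]:
        return {self.label} | self.synonyms


@dataclass
class Ontology:
    """A set of classes connected by asserted is_a edges (acyclic)."""

    classes: dict[str, OntologyClass]

    def __post_init__(self) -> None:
        for cls in self.classes.values():
            for p in cls.parents:
                if p not in self.classes:
                    raise OntologyFormatError(
                        f"class {cls.id!r} references unknown parent {p!r}"
                    )
        cycle = _find_cycle(self.classes)
        if cycle is not None:
            raise OntologyCycleError(cycle)

    @property
    def root_ids(self) -> set[str]:
        return {c.id for c in self.classes.values() if not c.parents}

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes


@dataclass
class TermDictionary:
    """Surface-form -> class-identifier map built from labels and synonyms.

    Keys are normalized (lowercase, whitespace collapsed).  An ambiguous
    surface form shared by several classes maps to all of them.
    """

    entries: dict[str, set[str]]

    @property
    def term_count(self) -> int:
        return len(self.entries)

    @property
    def class_count(self) -> int:
        ids: set[str] = set()
        for v in self.entries.values():
            ids |= v
        return len(ids)

    def lookup(self, surface: str) -> set[str]:
        return self.entries.get(normalize_surface(surface), set())

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.entries


def normalize_surface(surface: str) -> str:
    """Lowercase and collapse internal whitespace of a dictionary key."""
    return " ".join(surface.lower().split())


def _find_cycle(classes: Mapping[str, OntologyClass]) -> list[str] | None:
    g = nx.DiGraph()
    g.add_nodes_from(classes)
    for cls in classes.values():
        for p in cls.parents:
            g.add_edge(cls.id, p)
    try:
        cycle_edges = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [u for u, _v in cycle_edges]


def _synonym_text(raw: str, stanza_id: str) -> str:
    m = _SYNONYM_TEXT.match(raw)
    if not m:
        raise OntologyFormatError(
            f"stanza {stanza_id!r}: cannot parse synonym line {raw!r}"
        )
    return m.group(1)


def load_ontology(path: str | Path) -> Ontology:
    """Load an ontology from an OBO flat file.

    Only the OBO subset (id, name, synonym of any scope, is_a, is_obsolete)
    is consumed; obsolete terms are skipped and ``alt_id`` is ignored.

    Raises
    ------
    OntologyFormatError
        On unparsable input or a stanza missing its name, naming the stanza.
    OntologyCycleError
        If the asserted is_a graph is cyclic, listing the cycle.
    """
    path = Path(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet raises various types
        raise OntologyFormatError(f"cannot parse OBO file {path}: {exc}") from exc

    classes: dict[str, OntologyClass] = {}
    for node, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            raise OntologyFormatError(f"stanza {node!r} has no name")
        synonyms = {_synonym_text(s, node) for s in data.get("synonym", [])}
        classes[node] = OntologyClass(id=node, label=name, synonyms=synonyms)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and child in classes and parent in classes:
            classes[child].parents.add(parent)
    return Ontology(classes=classes)


def subclass_closure(ontology: Ontology) -> dict[str, set[str]]:
    """Reflexive-transitive closure of asserted is_a: id -> set of ancestors.

    Every class is its own ancestor, so ``len(closure[x]) >= 1`` always and
    a root's ancestor set is exactly ``{root}``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(ontology.classes)
    for cls in ontology.classes.values():
        for p in cls.parents:
            g.add_edge(cls.id, p)
    return {c: {c} | nx.descendants(g, c) for c in ontology.classes}


def partition_by_superclasses(
    ontology: Ontology,
    supers: Iterable[str],
    other_label: str = "other",
) -> dict[str, str]:
    """Label every class with the first listed superclass among its ancestors.

    Classes under none of the listed superclasses receive ``other_label``;
    a class under several listed superclasses is resolved by list order and
    the conflict is logged.  The listed superclasses themselves are labeled
    by themselves (they are their own ancestors).
    """
    supers = list(supers)
    for s in supers:
        if s not in ontology:
            raise KeyError(f"superclass {s!r} not in ontology")
    closure = subclass_closure(ontology)
    labels: dict[str, str] = {}
    for cid, ancestors in closure.items():
        hits = [s for s in supers if s in ancestors]
        if len(hits) > 1:
            logger.info(
                "class %s is under %d listed superclasses %s; keeping %s",
                cid, len(hits), hits, hits[0],
            )
        labels[cid] = hits[0] if hits else other_label
    return labels


def build_term_dictionary(ontology: Ontology) -> TermDictionary:
    """Collect every label and synonym of every class into a TermDictionary."""
    entries: dict[str, set[str]] = {}
    for cls in ontology.classes.values():
        for surface in cls.surface_forms:
            key = normalize_surface(surface)
            if key:
                entries.setdefault(key, set()).add(cls.id)
    return TermDictionary(entries=entries)


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Serialize the ontology as an OBO flat file (deterministic order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: ontoextend-export\n")
        for cid in sorted(ontology.classes):
            cls = ontology.classes[cid]
            fh.write(f"\n[Term]\nid: {cls.id}\nname: {cls.label}\n")
            for syn in sorted(cls.synonyms):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for p in sorted(cls.parents):
                fh.write(f"is_a: {p} ! {ontology.classes[p].label}\n")


def write_closure_tsv(closure: Mapping[str, set[str]], path: str | Path) -> None:
    """Export the closure as sorted ``child<TAB>ancestor`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for child in sorted(closure):
            for anc in sorted(closure[child]):
                fh.write(f"{child}\t{anc}\n")
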