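import numpy as np
import pytest

from ontoextend.ontology import Ontology, OntologyClass
from ontoextend.synthetic import SyntheticSpec
from ontoextend.text import AnnotatedCorpus, Document


@pytest.fixture
def chain_obo(tmp_path):
    """Minimal three-term chain A is_a B is_a C, with a synonym and an
    obsolete stanza."""
    text = """format-version: 1.2

[Term]
id: DOID:A
name: alpha disease
synonym: "prediabetes" EXACT []
is_a: DOID:B ! beta disease

[Term]
id: DOID:B
name: beta disease
is_a: DOID:C ! gamma disease

[Term]
id: DOID:C
name: gamma disease

[Term]
id: DOID:OLD
name: retired disease
is_obsolete: true
"""
    p = tmp_path / "chain.obo"
    p.write_text(text, encoding="utf-8")
    return p


@pytest.fixture
def diamond_ontology():
    """A -> {B, C} -> D."""
    return Ontology(classes={
        "D": OntologyClass(id="D", label="d"),
        "B": OntologyClass(id="B", label="b", parents={"D"}),
        "C": OntologyClass(id="C", label="c", parents={"D"}),
        "A": OntologyClass(id="A", label="a", parents={"B", "C"}),
    })


@pytest.fixture
def toy_topic_corpus():
    """200-token corpus over a 6-token vocabulary with two 'topics', so a
    context model has real structure to learn."""
    rng = np.random.default_rng(0)
    blocks = (["aa", "bb", "cc"], ["dd", "ee", "ff"])
    toks: list[str] = []
    while len(toks) < 200:
        toks.extend(rng.choice(blocks[rng.random() < 0.5], size=5))
    return AnnotatedCorpus(documents=[Document("d0", toks[:200])])


@pytest.fixture(scope="session")
def small_spec():
    """Reduced synthetic conditions for fast structural tests (the
    full-size defaults are exercised by the acceptance tests)."""
    return SyntheticSpec(
        n_superclasses=2, classes_per_superclass=12, synonyms_per_class=2,
        context_vocab_per_superclass=15, background_vocab=40,
        mentions_per_class=9, window_fill=3, seed=7)
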