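"""Corpus preprocessing and dictionary-based concept recognition.

Mentions of ontology classes are found by greedy longest-match over the
preprocessed token stream (the standard dictionary-NER convention), and can
be normalized by replacing every matched span with the class identifier so
that a downstream embedding model learns one vector per class.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import TermDictionary, normalize_surface

logger = logging.getLogger(__name__)

#: Small bundled English stop-word list; replaceable via ``load_stopwords``.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an the is are was were be been being am
    of in on at to for with by from as into over under
    and or but not no nor so than then too very
    that this these those it its they them their there
    we our you your he she his her i me my""".split()
)

# ASCII punctuation is stripped except "-", which is handled separately so
# intra-word hyphens (e.g. "limb-shaking") survive as single tokens.
_PUNCT_TABLE = str.maketrans(
    {ch: " " for ch in string.punctuation if ch != "-"}
)


@dataclass
class Document:
    """A preprocessed document: an ordered token sequence."""

    doc_id: str
    tokens: list[str]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(order=True)
class Annotation:
    """A recognized class mention over a half-open token span."""

    doc_id: str
    start_token: int
    end_token: int
    surface: str
    class_ids: set[str] = field(compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start_token < self.end_token):
            raise ValueError(
                f"invalid span [{self.start_token}, {self.end_token})"
            )


@dataclass
class AnnotatedCorpus:
    """Documents plus their class-mention annotations."""

    documents: list[Document]
    annotations: list[Annotation] = field(default_factory=list)
    normalized: bool = False

    def doc(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    def token_streams(self) -> list[list[str]]:
        return [d.tokens for d in self.documents]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word list, one word per line; blank lines ignored."""
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.lower() for w in words)


def preprocess(
    raw_text: str,
    doc_id: str = "doc",
    stopwords: frozenset[str] | Iterable[str] = DEFAULT_STOPWORDS,
) -> Document:
    """Lowercase, strip punctuation, tokenize on whitespace, drop stop words.

    Hyphens between word characters are kept; all other ASCII punctuation is
    replaced by whitespace.  Empty input yields an empty Document.
    """
    stopwords = frozenset(stopwords)
    text = raw_text.lower().translate(_PUNCT_TABLE)
    tokens = []
    for tok in text.split():
        tok = tok.strip("-")  # leading/trailing hyphens are punctuation
        if tok and tok not in stopwords:
            tokens.append(tok)
    return Document(doc_id=doc_id, tokens=tokens)


def _dictionary_token_index(
    dictionary: TermDictionary,
    stopwords: frozenset[str],
) -> tuple[dict[tuple[str, ...], set[str]], int]:
    """Preprocess dictionary keys into token tuples for span matching."""
    index: dict[tuple[str, ...], set[str]] = {}
    max_len = 0
    for key, ids in dictionary.entries.items():
        toks = tuple(preprocess(key, stopwords=stopwords).tokens)
        if not toks:
            continue
        index.setdefault(toks, set()).update(ids)
        max_len = max(max_len, len(toks))
    return index, max_len


def annotate_mentions(
    doc: Document,
    dictionary: TermDictionary,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    _index: tuple[dict[tuple[str, ...], set[str]], int] | None = None,
) -> list[Annotation]:
    """Greedy longest-match left-to-right dictionary annotation.

    Dictionary keys are passed through the same preprocessing pipeline as
    documents, so matching happens token-to-token.  Matches never overlap;
    at each position the longest matching entry wins.
    """
    index, max_len = _index or _dictionary_token_index(
        dictionary, frozenset(stopwords))
    out: list[Annotation] = []
    toks = doc.tokens
    i = 0
    n = len(toks)
    while i < n:
        matched = 0
        for span in range(min(max_len, n - i), 0, -1):
            candidate = tuple(toks[i : i + span])
            ids = index.get(candidate)
            if ids:
                out.append(
                    Annotation(
                        doc_id=doc.doc_id,
                        start_token=i,
                        end_token=i + span,
                        surface=" ".join(candidate),
                        class_ids=set(ids),
                    )
                )
                matched = span
                break
        i += matched if matched else 1
    return out


def annotate_corpus(
    documents: Sequence[Document],
    dictionary: TermDictionary,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> AnnotatedCorpus:
    cached = _dictionary_token_index(dictionary, frozenset(stopwords))
    anns: list[Annotation] = []
    for d in documents:
        anns.extend(annotate_mentions(d, dictionary, stopwords,
                                      _index=cached))
    return AnnotatedCorpus(documents=list(documents), annotations=anns)


def normalize_mentions(corpus: AnnotatedCorpus) -> AnnotatedCorpus:
    """Replace each annotated span by a single class-identifier token.

    Ambiguous spans (several class ids) are resolved to the lexicographically
    smallest identifier and logged.  The result carries annotations remapped
    to the new 1-token spans and ``normalized=True``.
    """
    if corpus.normalized:
        raise ValueError("corpus is already normalized")
    by_doc: dict[str, list[Annotation]] = {}
    for a in sorted(corpus.annotations):
        by_doc.setdefault(a.doc_id, []).append(a)

    new_docs: list[Document] = []
    new_anns: list[Annotation] = []
    for d in corpus.documents:
        anns = by_doc.get(d.doc_id, [])
        toks: list[str] = []
        pos = 0
        for a in anns:
            toks.extend(d.tokens[pos : a.start_token])
            ids = sorted(a.class_ids)
            if len(ids) > 1:
                logger.info(
                    "ambiguous mention %r in %s -> keeping %s of %s",
                    a.surface, d.doc_id, ids[0], ids,
                )
            start = len(toks)
            toks.append(ids[0])
            new_anns.append(
                replace(a, start_token=start, end_token=start + 1,
                        surface=ids[0], class_ids={ids[0]})
            )
            pos = a.end_token
        toks.extend(d.tokens[pos:])
        new_docs.append(Document(doc_id=d.doc_id, tokens=toks))
    return AnnotatedCorpus(documents=new_docs, annotations=new_anns,
                           normalized=True)


def read_corpus(path: str | Path,
                stopwords: frozenset[str] = DEFAULT_STOPWORDS,
                ) -> list[Document]:
    """Read a corpus from a directory of ``.txt`` files (one document each)
    or a single file with one document per line, preprocessing each."""
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            docs.append(preprocess(f.read_text(encoding="utf-8"),
                                   doc_id=f.stem, stopwords=stopwords))
    else:
        for i, line in enumerate(
                path.read_text(encoding="utf-8").splitlines()):
            docs.append(preprocess(line, doc_id=f"line{i:05d}",
                                   stopwords=stopwords))
    return docs


def write_annotations_tsv(annotations: Sequence[Annotation],
                          path: str | Path) -> None:
    """Export annotations as ``doc_id<TAB>start<TAB>end<TAB>surface<TAB>ids``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tstart\tend\tsurface\tclass_ids\n")
        for a in sorted(annotations):
            fh.write(f"{a.doc_id}\t{a.start_token}\t{a.end_token}\t"
                     f"{a.surface}\t{','.join(sorted(a.class_ids))}\n")
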