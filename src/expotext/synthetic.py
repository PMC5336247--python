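"""Seeded synthetic corpora with controllable node-signal structure.

The generator emulates the structure of an annotated exposure-literature
corpus: for each chosen taxonomy leaf it emits abstracts whose token
distribution, MeSH descriptors and chemical lists correlate with that leaf,
plus a pool of reviewed-but-irrelevant documents drawn from background
vocabulary only.  Positive documents embed leaf-specific keywords inside
simple subject–verb–object sentence templates, so the baseline POS tagger,
parser and gazetteer produce grammatical-relation, verb-cluster and
named-entity features over the planted signal — every feature family is
exercisable end to end.

Two template modes:

* ``"svo"`` (default) — subject–verb–object sentences with verbs drawn
  mostly from the built-in verb-cluster lexicon and occasional gazetteer
  nouns.
* ``"lbow_only"`` — verb-less noun sequences in which signal keywords are
  never adjacent to each other, so the planted signal is carried by
  unigrams alone (bigram, relation, verb-cluster and entity features stay
  uninformative).

Everything is driven by one integer seed; identical specs reproduce
byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus_io import AnnotationSet, DocumentRecord
from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "SyntheticCorpusSpec",
    "generate_corpus",
    "generate_annotator_pair",
    "leaf_keywords",
    "expected_keyword_df",
]

_LEXICON_VERBS = (
    "affects",
    "increases",
    "reduces",
    "measures",
    "detects",
    "estimates",
    "alters",
    "inhibits",
    "accumulates",
    "absorbs",
)
# verbs the POS lexicon knows but the verb-cluster lexicon does not
_PLAIN_VERBS = ("shows", "reports", "describes", "suggests", "considers")

_GAZETTEER_NOUNS = (
    "hemoglobin",
    "albumin",
    "ferritin",
    "metallothionein",
    "lymphocytes",
    "erythrocytes",
)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generation parameters; defaults give a strongly separable corpus.

    ``signal_prob`` is the per-noun-slot probability that a positive
    document emits one of its leaf's keywords instead of a background
    noun.  ``multilabel_rate`` is the probability that a positive document
    carries a second leaf label (and mixes both keyword sets).
    ``mesh_rate`` / ``chem_rate`` control node-correlated metadata.
    """

    taxonomy: Taxonomy = field(default_factory=default_taxonomy)
    leaves: tuple[str, ...] | None = None
    docs_per_leaf: int = 150
    irrelevant_docs: int = 300
    keywords_per_leaf: int = 8
    signal_prob: float = 0.8
    background_vocab_size: int = 400
    sentences_per_doc: tuple[int, int] = (4, 8)
    nouns_per_sentence: tuple[int, int] = (2, 4)
    mesh_rate: float = 0.6
    chem_rate: float = 0.4
    multilabel_rate: float = 0.1
    mode: str = "svo"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal_prob", "mesh_rate", "chem_rate", "multilabel_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.docs_per_leaf < 1 or self.keywords_per_leaf < 1:
            raise ValueError("docs_per_leaf and keywords_per_leaf must be >= 1")
        if self.mode not in ("svo", "lbow_only"):
            raise ValueError(f"unknown template mode {self.mode!r}")

    def resolved_leaves(self) -> tuple[str, ...]:
        if self.leaves is None:
            return self.taxonomy.leaves()
        return tuple(self.taxonomy.resolve(leaf) for leaf in self.leaves)


def leaf_keywords(spec: SyntheticCorpusSpec) -> dict[str, list[str]]:
    """Disjoint per-leaf signal vocabularies (deterministic in the spec)."""
    return {
        leaf: [
            f"{leaf.replace('_', '')}sig{i}"
            for i in range(spec.keywords_per_leaf)
        ]
        for leaf in spec.resolved_leaves()
    }


def expected_keyword_df(spec: SyntheticCorpusSpec, n_noun_slots: int) -> float:
    """Expected fraction of positive documents containing at least one of
    their leaf's keywords: ``1 - (1 - signal_prob) ** n_noun_slots``."""
    return 1.0 - (1.0 - spec.signal_prob) ** n_noun_slots


def _background(rng: np.random.Generator, spec: SyntheticCorpusSpec) -> str:
    return f"bgword{rng.integers(spec.background_vocab_size)}"


def _noun(
    rng: np.random.Generator,
    spec: SyntheticCorpusSpec,
    keywords: Sequence[Sequence[str]],
) -> str:
    """One noun slot: keyword with prob signal_prob, else background."""
    if keywords and rng.random() < spec.signal_prob:
        pool = keywords[rng.integers(len(keywords))]
        return pool[rng.integers(len(pool))]
    if spec.mode == "svo" and rng.random() < 0.1:
        return _GAZETTEER_NOUNS[rng.integers(len(_GAZETTEER_NOUNS))]
    return _background(rng, spec)


def _sentence(
    rng: np.random.Generator,
    spec: SyntheticCorpusSpec,
    keywords: Sequence[Sequence[str]],
) -> str:
    lo, hi = spec.nouns_per_sentence
    n_nouns = int(rng.integers(lo, hi + 1))
    if spec.mode == "svo":
        n_subject = max(1, n_nouns // 2)
        subject = [_noun(rng, spec, keywords) for _ in range(n_subject)]
        obj = [
            _noun(rng, spec, keywords) for _ in range(n_nouns - n_subject)
        ] or [_background(rng, spec)]
        if rng.random() < 0.8:
            verb = _LEXICON_VERBS[rng.integers(len(_LEXICON_VERBS))]
        else:
            verb = _PLAIN_VERBS[rng.integers(len(_PLAIN_VERBS))]
        words = subject + [verb] + obj
        text = " ".join(words) + "."
        return text[0].upper() + text[1:]
    # lbow_only: a verb-less comma-separated term list, so no noun group,
    # bigram, relation, verb-cluster or entity feature can carry signal
    words = []
    for _ in range(n_nouns):
        words.append(_background(rng, spec))
        words.append(_noun(rng, spec, keywords))
    text = ", ".join(words) + "."
    return text[0].upper() + text[1:]


def generate_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[DocumentRecord], AnnotationSet]:
    """Generate records plus gold annotations (leaf labels; irrelevant
    documents carry explicit empty label sets)."""
    rng = np.random.default_rng(spec.seed)
    leaves = spec.resolved_leaves()
    keywords = leaf_keywords(spec)
    records: list[DocumentRecord] = []
    labels: dict[str, set[str]] = {}
    counter = 0

    def next_pmid() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:06d}"

    lo_s, hi_s = spec.sentences_per_doc
    for leaf in leaves:
        for _ in range(spec.docs_per_leaf):
            doc_leaves = [leaf]
            if len(leaves) > 1 and rng.random() < spec.multilabel_rate:
                others = [x for x in leaves if x != leaf]
                doc_leaves.append(others[rng.integers(len(others))])
            pools = [keywords[x] for x in doc_leaves]
            n_sent = int(rng.integers(lo_s, hi_s + 1))
            abstract = " ".join(
                _sentence(rng, spec, pools) for _ in range(n_sent)
            )
            mesh = ["Humans", f"bgmesh{rng.integers(30)}"]
            chems = []
            for x in doc_leaves:
                if rng.random() < spec.mesh_rate:
                    mesh.append(f"mesh-{x}")
                if rng.random() < spec.chem_rate:
                    chems.append(f"chem-{x}")
            pmid = next_pmid()
            records.append(
                DocumentRecord(
                    pmid=pmid,
                    title=f"Synthetic abstract {pmid}",
                    abstract=abstract,
                    mesh_terms=mesh,
                    chemicals=chems,
                    journal="Synthetic Journal of Exposure Science",
                    year=int(2000 + rng.integers(15)),
                )
            )
            labels[pmid] = set(doc_leaves)
    for _ in range(spec.irrelevant_docs):
        n_sent = int(rng.integers(lo_s, hi_s + 1))
        abstract = " ".join(_sentence(rng, spec, []) for _ in range(n_sent))
        pmid = next_pmid()
        records.append(
            DocumentRecord(
                pmid=pmid,
                title=f"Synthetic abstract {pmid}",
                abstract=abstract,
                mesh_terms=["Humans", f"bgmesh{rng.integers(30)}"],
                chemicals=[],
                journal="Synthetic Journal of Exposure Science",
                year=int(2000 + rng.integers(15)),
            )
        )
        labels[pmid] = set()
    annotations = AnnotationSet(labels=labels, annotator="synthetic-gold")
    return records, annotations


def generate_annotator_pair(
    annotations: AnnotationSet,
    disagreement_rate: float,
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
) -> AnnotationSet:
    """Second annotator: every (document, node) membership is flipped
    independently with *disagreement_rate* over the taxonomy's nodes."""
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be in [0, 1]")
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(seed)
    nodes = taxonomy.node_names
    out: dict[str, set[str]] = {}
    for pmid in annotations.labels:
        labels = set(annotations.labels[pmid])
        flips = rng.random(len(nodes)) < disagreement_rate
        for node, flip in zip(nodes, flips):
            if flip:
                labels ^= {node}
        out[pmid] = labels
    return AnnotationSet(labels=out, annotator="synthetic-second")


def make_spec(**overrides) -> SyntheticCorpusSpec:
    """Convenience constructor (``replace`` over the default spec)."""
    return replace(SyntheticCorpusSpec(), **overrides)
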