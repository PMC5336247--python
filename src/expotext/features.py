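"""Seven-family feature extraction, selection and sparse binary encoding.

Every abstract is represented by presence features from seven families:

====== =================================================================
LBOW   lemmatized bag of words — one feature per distinct lemma
NBIGRAM noun-compound bigrams — adjacent noun-tagged surface pairs,
       case-folded but *not* lemmatized ("drinking water" stays intact)
GR     lexicalized grammatical-relation patterns — for every dependency
       arc the full (relation, head, dependent) triple plus the two
       single-wildcard variants (relation, head, *) and (relation, *, dep)
NE     named entities — (entity_type, span text) pairs
VC     verb clusters — a verb lemma in the 3-level semantic verb
       hierarchy activates one bit per hierarchy level
MESH   MeSH descriptors attached to the PubMed record
CHEM   chemical-substance list attached to the PubMed record
====== =================================================================

Feature selection keeps, per taxonomy node, only features whose document
frequency in the training corpus lies within per-family ``[min_df, max_df]``
bounds; rare and ubiquitous features are both removed.  Encoded vectors are
sparse and strictly binary (presence only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus_io import DocumentRecord
from .nlp import AnnotatedDocument

__all__ = [
    "FAMILIES",
    "FeatureKey",
    "VerbClusterLexicon",
    "load_verb_cluster_lexicon",
    "FeatureThresholds",
    "FeatureVocabulary",
    "extract_lbow",
    "extract_noun_bigrams",
    "extract_gr_patterns",
    "extract_ne_features",
    "extract_verb_cluster_bits",
    "extract_metadata_features",
    "extract_all",
    "build_vocabulary",
    "encode",
    "encode_matrix",
]

FAMILIES = ("LBOW", "NBIGRAM", "GR", "NE", "VC", "MESH", "CHEM")

WILDCARD = "*"


class FeatureKey(NamedTuple):
    """One feature: a family tag plus a family-specific value tuple."""

    family: str
    value: tuple[str, ...]


class VerbClusterLexicon:
    """Verb lemma -> (level-1, level-2, level-3) semantic class ids."""

    def __init__(self, entries: Mapping[str, tuple[str, str, str]]):
        for verb, path in entries.items():
            if len(path) != 3:
                raise ValueError(
                    f"verb {verb!r} must have exactly 3 class ids, got {path!r}"
                )
        self.entries: dict[str, tuple[str, str, str]] = dict(entries)

    def __contains__(self, verb: str) -> bool:
        return verb in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, lines: Iterable[str]) -> "VerbClusterLexicon":
        entries: dict[str, tuple[str, str, str]] = {}
        for line in lines:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"bad verb-cluster line: {line!r}")
            entries[parts[0].lower()] = (parts[1], parts[2], parts[3])
        return cls(entries)


def load_verb_cluster_lexicon(path: str | None = None) -> VerbClusterLexicon:
    """Load the built-in baseline lexicon, or a user-supplied TSV
    (``verb<TAB>L1<TAB>L2<TAB>L3``, e.g. the 399-verb biomedical verb
    hierarchy if available)."""
    if path is None:
        text = (
            _importlib_resources.files("expotext.resources")
            .joinpath("verb_clusters.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return VerbClusterLexicon.from_tsv(text.splitlines())


# ----------------------------------------------------------------------
# per-family extractors

_NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS"}


def extract_lbow(doc: AnnotatedDocument) -> set[FeatureKey]:
    """One presence feature per distinct lemma of word-like tokens."""
    out = set()
    for sentence in doc.sentences:
        for tok in sentence:
            if tok.lemma and any(ch.isalpha() for ch in tok.surface):
                out.add(FeatureKey("LBOW", (tok.lemma,)))
    return out


def extract_noun_bigrams(doc: AnnotatedDocument) -> set[FeatureKey]:
    """Adjacent noun-noun surface bigrams, case-folded, never lemmatized."""
    out = set()
    for sentence in doc.sentences:
        for left, right in zip(sentence, sentence[1:]):
            if left.pos in _NOUN_TAGS and right.pos in _NOUN_TAGS:
                out.add(
                    FeatureKey(
                        "NBIGRAM",
                        (left.surface.lower(), right.surface.lower()),
                    )
                )
    return out


def extract_gr_patterns(doc: AnnotatedDocument) -> set[FeatureKey]:
    """Lexicalized triple plus the two single-wildcard variants per arc."""
    out = set()
    for arc in doc.arcs:
        head = arc.head.surface.lower()
        dep = arc.dependent.surface.lower()
        out.add(FeatureKey("GR", (arc.relation, head, dep)))
        out.add(FeatureKey("GR", (arc.relation, head, WILDCARD)))
        out.add(FeatureKey("GR", (arc.relation, WILDCARD, dep)))
    return out


def extract_ne_features(doc: AnnotatedDocument) -> set[FeatureKey]:
    """(entity_type, span text) pairs; spans kept verbatim."""
    return {
        FeatureKey("NE", (m.entity_type, m.span_text)) for m in doc.entities
    }


def extract_verb_cluster_bits(
    doc: AnnotatedDocument, lexicon: VerbClusterLexicon
) -> set[FeatureKey]:
    """Three (level, class-id) bits per in-lexicon verb lemma found."""
    out = set()
    for sentence in doc.sentences:
        for tok in sentence:
            if tok.pos.startswith("VB") and tok.lemma in lexicon:
                path = lexicon.entries[tok.lemma]
                for level, class_id in enumerate(path, start=1):
                    out.add(FeatureKey("VC", (str(level), class_id)))
    return out


def extract_metadata_features(record: DocumentRecord) -> set[FeatureKey]:
    """MESH and CHEM presence features, case-folded verbatim strings."""
    out = {FeatureKey("MESH", (m.lower(),)) for m in record.mesh_terms}
    out |= {FeatureKey("CHEM", (c.lower(),)) for c in record.chemicals}
    return out


def extract_all(
    doc: AnnotatedDocument,
    lexicon: VerbClusterLexicon | None = None,
    families: Sequence[str] = FAMILIES,
) -> frozenset[FeatureKey]:
    """Union of the requested families' features for one document."""
    if lexicon is None:
        lexicon = load_verb_cluster_lexicon()
    out: set[FeatureKey] = set()
    fams = set(families)
    if "LBOW" in fams:
        out |= extract_lbow(doc)
    if "NBIGRAM" in fams:
        out |= extract_noun_bigrams(doc)
    if "GR" in fams:
        out |= extract_gr_patterns(doc)
    if "NE" in fams:
        out |= extract_ne_features(doc)
    if "VC" in fams:
        out |= extract_verb_cluster_bits(doc, lexicon)
    if "MESH" in fams or "CHEM" in fams:
        meta = extract_metadata_features(doc.record)
        out |= {k for k in meta if k.family in fams}
    return frozenset(out)


# ----------------------------------------------------------------------
# selection + vocabulary


@dataclass(frozen=True)
class FeatureThresholds:
    """Per-family document-frequency selection bounds.

    ``min_df`` is an absolute document count (default 5).  ``max_df`` is
    either an absolute count or, if a float in (0, 1], a fraction of the
    corpus size (default 0.30 — the scale-free analogue of an absolute cap
    "larger than 100" on a few-thousand-document corpus).  Per-family
    overrides replace the defaults for that family only.
    """

    min_df: int = 5
    max_df: float = 0.30
    per_family: tuple[tuple[str, tuple[float, float]], ...] = ()

    def bounds(self, family: str, n_docs: int) -> tuple[int, int]:
        lo: float = self.min_df
        hi: float = self.max_df
        for fam, (fam_lo, fam_hi) in self.per_family:
            if fam == family:
                lo, hi = fam_lo, fam_hi
        lo_abs = int(lo) if lo >= 1 else max(1, int(np.ceil(lo * n_docs)))
        if hi <= 1 and isinstance(hi, float):
            hi_abs = int(np.floor(hi * n_docs))
        else:
            hi_abs = int(hi)
        if lo_abs < 1 or lo_abs > hi_abs:
            raise ValueError(
                f"invalid df thresholds for {family}: [{lo_abs}, {hi_abs}]"
            )
        return lo_abs, hi_abs


@dataclass
class FeatureVocabulary:
    """Ordered, per-node selected feature space.

    Features are sorted by (family, value) so the index assignment is
    deterministic; ``document_frequency`` keeps the training-corpus df of
    every retained feature.
    """

    node: str
    features: list[FeatureKey]
    document_frequency: dict[FeatureKey, int]
    thresholds: FeatureThresholds
    n_docs: int
    index: dict[FeatureKey, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {key: i for i, key in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)

    def family_counts(self) -> dict[str, int]:
        counts = {fam: 0 for fam in FAMILIES}
        for key in self.features:
            counts[key.family] += 1
        return counts

    # -- canonical JSON serialization ----------------------------------

    def to_json(self) -> str:
        payload = {
            "node": self.node,
            "n_docs": self.n_docs,
            "thresholds": {
                "min_df": self.thresholds.min_df,
                "max_df": self.thresholds.max_df,
                "per_family": [
                    [fam, list(bounds)]
                    for fam, bounds in self.thresholds.per_family
                ],
            },
            "features": [
                {
                    "family": key.family,
                    "value": list(key.value),
                    "df": self.document_frequency[key],
                }
                for key in self.features
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "FeatureVocabulary":
        payload = json.loads(text)
        thr = payload["thresholds"]
        thresholds = FeatureThresholds(
            min_df=thr["min_df"],
            max_df=thr["max_df"],
            per_family=tuple(
                (fam, tuple(bounds)) for fam, bounds in thr["per_family"]
            ),
        )
        features = []
        df = {}
        for item in payload["features"]:
            key = FeatureKey(item["family"], tuple(item["value"]))
            features.append(key)
            df[key] = item["df"]
        return cls(
            node=payload["node"],
            features=features,
            document_frequency=df,
            thresholds=thresholds,
            n_docs=payload["n_docs"],
        )


def count_document_frequency(
    featuresets: Sequence[Iterable[FeatureKey]],
) -> dict[FeatureKey, int]:
    df: dict[FeatureKey, int] = {}
    for featureset in featuresets:
        for key in set(featureset):
            df[key] = df.get(key, 0) + 1
    return df


def build_vocabulary(
    featuresets: Sequence[Iterable[FeatureKey]],
    node: str,
    thresholds: FeatureThresholds | None = None,
) -> FeatureVocabulary:
    """Select the per-node feature space by document-frequency filtering.

    *featuresets* are the per-document feature sets of the node's training
    corpus (use :func:`extract_all`).  Selection is applied separately per
    node, so each node classifier has its own feature space.
    """
    if not featuresets:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    thresholds = thresholds or FeatureThresholds()
    n_docs = len(featuresets)
    bounds = {fam: thresholds.bounds(fam, n_docs) for fam in FAMILIES}
    df = count_document_frequency(featuresets)
    kept = [
        key
        for key, count in df.items()
        if bounds[key.family][0] <= count <= bounds[key.family][1]
    ]
    kept.sort()
    return FeatureVocabulary(
        node=node,
        features=kept,
        document_frequency={key: df[key] for key in kept},
        thresholds=thresholds,
        n_docs=n_docs,
    )


# ----------------------------------------------------------------------
# encoding


def encode(
    featureset: Iterable[FeatureKey], vocab: FeatureVocabulary
) -> list[int]:
    """Sorted active indices of in-vocabulary features (binary presence)."""
    idx = vocab.index
    return sorted({idx[key] for key in featureset if key in idx})


def encode_matrix(
    featuresets: Sequence[Iterable[FeatureKey]], vocab: FeatureVocabulary
) -> sp.csr_matrix:
    """Stack documents into a sparse binary CSR matrix (docs x features)."""
    indptr = [0]
    indices: list[int] = []
    for featureset in featuresets:
        active = encode(featureset, vocab)
        indices.extend(active)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sp.csr_matrix(
        (data, np.asarray(indices, dtype=np.int32), np.asarray(indptr)),
        shape=(len(featuresets), len(vocab)),
    )
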