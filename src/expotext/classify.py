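"""Taxonomy-wide ensemble of independent binary RBF-SVM node classifiers.

One binary support-vector machine (RBF kernel) is trained per taxonomy node
on sparse binary feature vectors.  Training labels use hierarchical
propagation: an abstract annotated with a sub-node is a positive example for
every ancestor node, and reviewed-but-irrelevant abstracts (empty label
sets) are negatives for every node.  Classifiers are trained and applied
independently, so predicted label sets are mutually non-exclusive and no
hierarchy consistency is forced at prediction time (an optional post-hoc
closure flag exists for profile building).

Kernel hyperparameters (C, gamma) are tuned per node by inner k-fold
cross-validation over a grid, maximizing mean F-score; ties break toward
the smaller C, then the smaller gamma.

The central object is :class:`ExposureTaxonomyClassifier`, a scikit-learn
style estimator (``fit`` / ``predict`` / ``get_params``); the module-level
functions (:func:`train_ensemble`, :func:`predict`,
:func:`tune_hyperparameters`, :func:`assemble_training_set`) are thin
wrappers over it.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import euclidean_distances, rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as feat
from .corpus_io import AnnotationSet, DocumentRecord
from .nlp import AnnotatedDocument, TextAnnotator
from .taxonomy import Taxonomy, default_taxonomy, propagate_labels

__all__ = [
    "DegenerateTrainingError",
    "NodeModel",
    "PredictionSet",
    "ExposureTaxonomyClassifier",
    "tune_hyperparameters",
    "assemble_training_set",
    "train_ensemble",
    "predict",
    "write_predictions",
    "save_model_bundle",
    "load_model_bundle",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


class DegenerateTrainingError(ValueError):
    """Raised when a node's training labels contain a single class."""


@dataclass
class NodeModel:
    """One trained binary node classifier.

    The decision function is the standard SVM expansion
    ``f(x) = sum_i alpha_i K(sv_i, x) + b`` with an RBF kernel; a document
    is labelled positive iff ``f(x) > 0``.  Support vectors of binary
    feature vectors are stored as sorted active-index lists.
    """

    node: str
    vocabulary: feat.FeatureVocabulary
    C: float
    gamma: float
    support_indices: list[list[int]]
    dual_coef: list[float]
    intercept: float

    def _sv_matrix(self) -> sp.csr_matrix:
        indptr = [0]
        indices: list[int] = []
        for row in self.support_indices:
            indices.extend(row)
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        return sp.csr_matrix(
            (data, np.asarray(indices, dtype=np.int32), np.asarray(indptr)),
            shape=(len(self.support_indices), len(self.vocabulary)),
        )

    def decision_function(self, X: sp.spmatrix) -> np.ndarray:
        K = rbf_kernel(X, self._sv_matrix(), gamma=self.gamma)
        return K @ np.asarray(self.dual_coef) + self.intercept

    def predict(self, X: sp.spmatrix) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)


@dataclass
class PredictionSet:
    """PMID -> predicted node slugs, with raw decision values."""

    labels: dict[str, set[str]]
    decisions: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def pmids(self) -> list[str]:
        return list(self.labels)


# ----------------------------------------------------------------------
# hyperparameter tuning


def _f_score(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def _sqdist(X: sp.spmatrix) -> np.ndarray:
    """Dense pairwise squared euclidean distances between rows of X.

    Computed once per training split and shared across every node, grid
    point and inner fold: the RBF kernel is then just exp(-gamma * D).
    """
    return euclidean_distances(X, squared=True)


def tune_hyperparameters(
    X: sp.spmatrix,
    y: np.ndarray,
    grid: Sequence[tuple[float, float]] | None = None,
    inner_k: int = 5,
    seed: int = 0,
    class_weight: str | None = None,
    _D: np.ndarray | None = None,
) -> tuple[float, float]:
    """Select (C, gamma) maximizing mean inner-fold F-score.

    Deterministic given *seed*; ties break toward smaller C, then smaller
    gamma.  Raises :class:`DegenerateTrainingError` if *y* has one class.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateTrainingError(
            f"single-class training labels (class {classes[0]!r})"
        )
    if grid is None:
        grid = list(product(DEFAULT_C_GRID, DEFAULT_GAMMA_GRID))
    grid = sorted(grid)
    if len(grid) == 1:
        return grid[0]
    inner_k = min(inner_k, int(counts.min()))
    if inner_k < 2:
        # too few minority examples for inner CV: first (smallest) point
        return grid[0]
    if _D is None:
        _D = _sqdist(X)
    splitter = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    kernels: dict[float, np.ndarray] = {}
    best: tuple[float, float] | None = None
    best_score = -1.0
    for C, gamma in grid:
        if gamma not in kernels:
            kernels[gamma] = np.exp(-gamma * _D)
        K = kernels[gamma]
        scores = []
        for train_idx, test_idx in folds:
            if len(np.unique(y[train_idx])) < 2:
                scores.append(0.0)
                continue
            svc = SVC(C=C, kernel="precomputed", class_weight=class_weight)
            svc.fit(K[np.ix_(train_idx, train_idx)], y[train_idx])
            pred = svc.predict(K[np.ix_(test_idx, train_idx)])
            truth = y[test_idx]
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            scores.append(_f_score(tp, fp, fn))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:  # strict: ties keep earlier (smaller) point
            best_score = mean_score
            best = (C, gamma)
        if best_score == 1.0:
            # no later grid point can beat a perfect score, and ties always
            # keep the earlier (smaller) point, so stopping here is exact
            break
    assert best is not None
    return best


def _fit_node_model(
    node: str,
    vocab: feat.FeatureVocabulary,
    X: sp.spmatrix,
    y: np.ndarray,
    grid: Sequence[tuple[float, float]],
    inner_k: int,
    seed: int,
    class_weight: str | None,
    _D: np.ndarray | None = None,
) -> NodeModel:
    if _D is None:
        _D = _sqdist(X)
    C, gamma = tune_hyperparameters(
        X,
        y,
        grid=grid,
        inner_k=inner_k,
        seed=seed,
        class_weight=class_weight,
        _D=_D,
    )
    svc = SVC(C=C, kernel="precomputed", class_weight=class_weight)
    svc.fit(np.exp(-gamma * _D), y)
    dual = svc.dual_coef_
    if sp.issparse(dual):
        dual = dual.toarray()
    sv = sp.csr_matrix(X[svc.support_])
    support_indices = [
        sorted(sv.indices[sv.indptr[i] : sv.indptr[i + 1]].tolist())
        for i in range(sv.shape[0])
    ]
    return NodeModel(
        node=node,
        vocabulary=vocab,
        C=float(C),
        gamma=float(gamma),
        support_indices=support_indices,
        dual_coef=[float(a) for a in np.ravel(dual)],
        intercept=float(svc.intercept_[0]),
    )


# ----------------------------------------------------------------------
# the estimator


class ExposureTaxonomyClassifier(BaseEstimator, ClassifierMixin):
    """Multi-label classifier over the exposure taxonomy.

    Parameters
    ----------
    taxonomy : Taxonomy or None
        Label hierarchy; ``None`` uses the built-in 32-node taxonomy.
    families : sequence of str
        Feature families to use (default: all seven).
    min_df, max_df : selection thresholds, see
        :class:`~expotext.features.FeatureThresholds`.
    C_grid, gamma_grid : sequences of floats
        Hyperparameter search grid for the per-node inner CV.
    inner_k : int
        Inner cross-validation folds for tuning (default 5).
    class_weight : None or "balanced"
        Optional inverse-frequency class weighting (default: none).
    include_title : bool
        Prepend the title to the abstract before annotation.
    hierarchy_closure : bool
        If true, predicted label sets are closed upward post hoc
        (off by default: nodes are decided independently).
    verb_lexicon_path : str or None
        Optional TSV replacing the built-in verb-cluster lexicon.
    random_state : int
        Seed for every stochastic component (inner fold shuffling).

    Attributes
    ----------
    taxonomy_ : Taxonomy
    classes_ : ndarray of node slugs with trained classifiers
    node_models_ : dict node -> :class:`NodeModel`
    vocabularies_ : dict node -> :class:`FeatureVocabulary`
    skipped_nodes_ : list of nodes without both classes in training data
    manifest_ : dict of the training settings
    """

    def __init__(
        self,
        taxonomy: Taxonomy | None = None,
        families: Sequence[str] = feat.FAMILIES,
        min_df: int = 5,
        max_df: float = 0.30,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
        inner_k: int = 5,
        class_weight: str | None = None,
        include_title: bool = False,
        hierarchy_closure: bool = False,
        verb_lexicon_path: str | None = None,
        random_state: int = 0,
    ):
        self.taxonomy = taxonomy
        self.families = families
        self.min_df = min_df
        self.max_df = max_df
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_k = inner_k
        self.class_weight = class_weight
        self.include_title = include_title
        self.hierarchy_closure = hierarchy_closure
        self.verb_lexicon_path = verb_lexicon_path
        self.random_state = random_state

    # -- featurization --------------------------------------------------

    def _featurize(self, X: Sequence) -> list[frozenset[feat.FeatureKey]]:
        """Accept records, annotated documents, or precomputed feature sets."""
        lexicon = feat.load_verb_cluster_lexicon(self.verb_lexicon_path)
        annotator = TextAnnotator(include_title=self.include_title)
        out: list[frozenset[feat.FeatureKey]] = []
        for item in X:
            if isinstance(item, (frozenset, set)):
                out.append(frozenset(item))
            elif isinstance(item, AnnotatedDocument):
                out.append(
                    feat.extract_all(item, lexicon, families=self.families)
                )
            elif isinstance(item, DocumentRecord):
                out.append(
                    feat.extract_all(
                        annotator.annotate(item),
                        lexicon,
                        families=self.families,
                    )
                )
            else:
                raise TypeError(
                    "X items must be DocumentRecord, AnnotatedDocument or "
                    f"feature sets, got {type(item).__name__}"
                )
        return out

    def _thresholds(self) -> feat.FeatureThresholds:
        return feat.FeatureThresholds(min_df=self.min_df, max_df=self.max_df)

    def _restrict_families(
        self, featuresets: list[frozenset[feat.FeatureKey]]
    ) -> list[frozenset[feat.FeatureKey]]:
        fams = set(self.families)
        if fams == set(feat.FAMILIES):
            return featuresets
        return [
            frozenset(k for k in fs if k.family in fams) for fs in featuresets
        ]

    # -- fitting --------------------------------------------------------

    def fit(self, X: Sequence, y: Sequence[Iterable[str]]):
        """Train one binary node classifier per eligible taxonomy node.

        *X* is a sequence of documents (records, annotated documents or
        precomputed feature sets); *y* is the aligned sequence of gold
        label sets (node slugs or display names; empty = irrelevant).
        """
        if len(X) != len(y):
            raise ValueError(
                f"X and y have different lengths ({len(X)} vs {len(y)})"
            )
        if len(X) == 0:
            raise ValueError("cannot train on an empty corpus")
        self.taxonomy_ = self.taxonomy or default_taxonomy()
        featuresets = self._restrict_families(self._featurize(X))
        closures = [propagate_labels(self.taxonomy_, labels) for labels in y]

        thresholds = self._thresholds()
        # selection thresholds are global here, so the selected feature set
        # is shared; each node still records its own vocabulary object
        base_vocab = feat.build_vocabulary(featuresets, "_shared", thresholds)
        if len(base_vocab) == 0:
            raise ValueError(
                "feature selection removed every feature; relax min_df/max_df"
            )
        X_enc = feat.encode_matrix(featuresets, base_vocab)
        D = _sqdist(X_enc)

        grid = sorted(product(self.C_grid, self.gamma_grid))
        self.node_models_ = {}
        self.vocabularies_ = {}
        self.skipped_nodes_ = []
        for node in self.taxonomy_.node_names:
            y_node = np.array(
                [1 if node in closure else 0 for closure in closures]
            )
            if y_node.min() == y_node.max():
                self.skipped_nodes_.append(node)
                warnings.warn(
                    f"node {node!r} has a single training class; skipped",
                    stacklevel=2,
                )
                continue
            vocab = feat.FeatureVocabulary(
                node=node,
                features=base_vocab.features,
                document_frequency=base_vocab.document_frequency,
                thresholds=thresholds,
                n_docs=base_vocab.n_docs,
            )
            model = _fit_node_model(
                node,
                vocab,
                X_enc,
                y_node,
                grid=grid,
                inner_k=self.inner_k,
                seed=self.random_state,
                class_weight=self.class_weight,
                _D=D,
            )
            self.node_models_[node] = model
            self.vocabularies_[node] = vocab
        self.classes_ = np.array(list(self.node_models_), dtype=object)
        self.manifest_ = {
            "families": list(self.families),
            "min_df": self.min_df,
            "max_df": self.max_df,
            "C_grid": [float(c) for c in self.C_grid],
            "gamma_grid": [float(g) for g in self.gamma_grid],
            "inner_k": self.inner_k,
            "class_weight": self.class_weight,
            "include_title": self.include_title,
            "random_state": self.random_state,
            "n_documents": len(X),
            "n_nodes_trained": len(self.node_models_),
            "skipped_nodes": list(self.skipped_nodes_),
        }
        return self

    # -- prediction -----------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "node_models_"):
            raise RuntimeError("classifier is not fitted")

    def decision_function(self, X: Sequence) -> np.ndarray:
        """Per-node decision values, shape (n_docs, n_trained_nodes)."""
        self._check_fitted()
        featuresets = self._restrict_families(self._featurize(X))
        out = np.empty((len(featuresets), len(self.classes_)))
        # node vocabularies frequently share one feature list; cache encodings
        enc_cache: dict[int, sp.csr_matrix] = {}
        for j, node in enumerate(self.classes_):
            model = self.node_models_[node]
            key = id(model.vocabulary.features)
            if key not in enc_cache:
                enc_cache[key] = feat.encode_matrix(
                    featuresets, model.vocabulary
                )
            out[:, j] = model.decision_function(enc_cache[key])
        return out

    def predict(self, X: Sequence) -> np.ndarray:
        """Binary indicator matrix over ``classes_`` (decision > 0)."""
        scores = self.decision_function(X)
        indicator = (scores > 0.0).astype(int)
        if self.hierarchy_closure:
            col = {node: j for j, node in enumerate(self.classes_)}
            for i in range(indicator.shape[0]):
                active = [n for n in self.classes_ if indicator[i, col[n]]]
                for node in propagate_labels(self.taxonomy_, active):
                    if node in col:
                        indicator[i, col[node]] = 1
        return indicator

    def predict_labels(self, X: Sequence) -> list[set[str]]:
        indicator = self.predict(X)
        return [
            {
                node
                for j, node in enumerate(self.classes_)
                if indicator[i, j]
            }
            for i in range(indicator.shape[0])
        ]


# ----------------------------------------------------------------------
# functional wrappers


def _align_labels(
    records: Sequence[DocumentRecord | AnnotatedDocument],
    annotations: AnnotationSet,
) -> list[set[str]]:
    out = []
    for rec in records:
        pmid = rec.pmid if isinstance(rec, DocumentRecord) else rec.record.pmid
        if pmid not in annotations.labels:
            raise ValueError(f"no annotation for pmid {pmid}")
        out.append(set(annotations.labels[pmid]))
    return out


def assemble_training_set(
    corpus: Sequence,
    annotations: AnnotationSet,
    node: str,
    taxonomy: Taxonomy | None = None,
    thresholds: feat.FeatureThresholds | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Encoded vectors and binary labels for one node's classifier.

    A document is positive iff the upward closure of its annotation
    contains *node*; all other documents, including reviewed-irrelevant
    ones, are negatives.
    """
    taxonomy = taxonomy or default_taxonomy()
    node = taxonomy.resolve(node)
    est = ExposureTaxonomyClassifier(taxonomy=taxonomy)
    featuresets = est._featurize(corpus)
    vocab = feat.build_vocabulary(
        featuresets, node, thresholds or feat.FeatureThresholds()
    )
    X = feat.encode_matrix(featuresets, vocab)
    labels = _align_labels(corpus, annotations)
    y = np.array(
        [
            1 if node in propagate_labels(taxonomy, labs) else 0
            for labs in labels
        ]
    )
    return X, y


def train_ensemble(
    corpus: Sequence,
    annotations: AnnotationSet,
    taxonomy: Taxonomy | None = None,
    include_abstractless: bool = False,
    **params,
) -> ExposureTaxonomyClassifier:
    """Train the full node-classifier ensemble on an annotated corpus.

    Records without an abstract are excluded by default.  Keyword
    parameters are forwarded to :class:`ExposureTaxonomyClassifier`.
    """
    corpus = list(corpus)
    if not include_abstractless:
        corpus = [
            r
            for r in corpus
            if (
                r.has_abstract
                if isinstance(r, DocumentRecord)
                else r.record.has_abstract
            )
        ]
    if not corpus:
        raise ValueError("empty corpus")
    est = ExposureTaxonomyClassifier(taxonomy=taxonomy, **params)
    return est.fit(corpus, _align_labels(corpus, annotations))


def predict(
    ensemble: ExposureTaxonomyClassifier, docs: Sequence
) -> PredictionSet:
    """Apply every node classifier independently to *docs*."""
    pmids = [
        d.pmid if isinstance(d, DocumentRecord) else d.record.pmid
        for d in docs
    ]
    scores = ensemble.decision_function(docs)
    indicator = (scores > 0.0).astype(int)
    if ensemble.hierarchy_closure:
        col = {node: j for j, node in enumerate(ensemble.classes_)}
        for i in range(indicator.shape[0]):
            active = [n for n in ensemble.classes_ if indicator[i, col[n]]]
            for node in propagate_labels(ensemble.taxonomy_, active):
                if node in col:
                    indicator[i, col[node]] = 1
    labels = {}
    decisions = {}
    for i, pmid in enumerate(pmids):
        labels[pmid] = {
            node
            for j, node in enumerate(ensemble.classes_)
            if indicator[i, j]
        }
        decisions[pmid] = {
            node: float(scores[i, j])
            for j, node in enumerate(ensemble.classes_)
        }
    return PredictionSet(labels=labels, decisions=decisions)


def write_predictions(
    pred: PredictionSet, stream: IO[str], long_format: bool = False
) -> None:
    """TSV export: ``pmid<TAB>semicolon-joined nodes`` or long
    ``pmid<TAB>node<TAB>decision`` rows."""
    if long_format:
        for pmid in sorted(pred.decisions):
            for node, value in sorted(pred.decisions[pmid].items()):
                stream.write(f"{pmid}\t{node}\t{value!r}\n")
    else:
        for pmid in sorted(pred.labels):
            stream.write(f"{pmid}\t{';'.join(sorted(pred.labels[pmid]))}\n")


# ----------------------------------------------------------------------
# model bundle I/O (canonical, byte-deterministic)


def save_model_bundle(
    ensemble: ExposureTaxonomyClassifier, path: str | os.PathLike
) -> None:
    """Write manifest + per-node vocabulary and SVM parameters as JSON."""
    ensemble._check_fitted()
    path = os.fspath(path)
    nodes_dir = os.path.join(path, "nodes")
    os.makedirs(nodes_dir, exist_ok=True)
    manifest = dict(ensemble.manifest_)
    manifest["taxonomy"] = ensemble.taxonomy_.to_rows()
    manifest["nodes"] = sorted(ensemble.node_models_)
    with open(
        os.path.join(path, "manifest.json"), "w", encoding="utf-8"
    ) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for node, model in sorted(ensemble.node_models_.items()):
        payload = {
            "node": node,
            "C": model.C,
            "gamma": model.gamma,
            "intercept": model.intercept,
            "dual_coef": model.dual_coef,
            "support_indices": model.support_indices,
            "vocabulary": json.loads(model.vocabulary.to_json()),
        }
        with open(
            os.path.join(nodes_dir, f"{node}.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")


def load_model_bundle(path: str | os.PathLike) -> ExposureTaxonomyClassifier:
    """Reconstruct a fitted ensemble from :func:`save_model_bundle` output."""
    from .taxonomy import load_taxonomy

    path = os.fspath(path)
    with open(
        os.path.join(path, "manifest.json"), "r", encoding="utf-8"
    ) as fh:
        manifest = json.load(fh)
    taxonomy = load_taxonomy(manifest["taxonomy"])
    est = ExposureTaxonomyClassifier(
        taxonomy=taxonomy,
        families=tuple(manifest["families"]),
        min_df=manifest["min_df"],
        max_df=manifest["max_df"],
        C_grid=tuple(manifest["C_grid"]),
        gamma_grid=tuple(manifest["gamma_grid"]),
        inner_k=manifest["inner_k"],
        class_weight=manifest["class_weight"],
        include_title=manifest["include_title"],
        random_state=manifest["random_state"],
    )
    est.taxonomy_ = taxonomy
    est.node_models_ = {}
    est.vocabularies_ = {}
    bundled = set(manifest["nodes"])
    for node in [n for n in taxonomy.node_names if n in bundled]:
        with open(
            os.path.join(path, "nodes", f"{node}.json"), "r", encoding="utf-8"
        ) as fh:
            payload = json.load(fh)
        vocab = feat.FeatureVocabulary.from_json(
            json.dumps(payload["vocabulary"])
        )
        est.node_models_[node] = NodeModel(
            node=node,
            vocabulary=vocab,
            C=payload["C"],
            gamma=payload["gamma"],
            support_indices=[
                [int(i) for i in row] for row in payload["support_indices"]
            ],
            dual_coef=[float(a) for a in payload["dual_coef"]],
            intercept=payload["intercept"],
        )
        est.vocabularies_[node] = vocab
    est.skipped_nodes_ = list(manifest.get("skipped_nodes", []))
    est.classes_ = np.array(list(est.node_models_), dtype=object)
    est.manifest_ = {
        k: v for k, v in manifest.items() if k not in ("taxonomy", "nodes")
    }
    return est
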