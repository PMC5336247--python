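"""Evaluation machinery: confusion metrics, nested cross-validation,
leave-one-family-out feature ablation, inter-annotator agreement and
retrieval comparison.

The intrinsic evaluation is an outer k-fold cross-validation (default
k = 3) with per-node confusion counts pooled across folds; hyperparameter
tuning and feature selection run strictly inside each training split, so no
information leaks from the test fold.  Gold label sets are closed upward
through the taxonomy before comparison, mirroring how training labels are
propagated.

Reported measures per node: precision = tp/(tp+fp), recall = tp/(tp+fn),
accuracy = (tp+tn)/total and F-score = 2PR/(P+R).  A zero-denominator ratio
is reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .classify import ExposureTaxonomyClassifier, PredictionSet
from .corpus_io import AnnotationSet, DocumentRecord, split_folds
from .nlp import AnnotatedDocument, TextAnnotator
from .taxonomy import Taxonomy, default_taxonomy, propagate_labels

__all__ = [
    "ConfusionCounts",
    "NodeMetrics",
    "EvaluationReport",
    "AblationReport",
    "AgreementReport",
    "RetrievalComparison",
    "confusion",
    "metrics",
    "cross_validate",
    "ablate_feature_family",
    "ablation_report",
    "cohen_kappa",
    "compare_retrieval",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class NodeMetrics:
    """Fractions in [0, 1]; ``flags`` names any zero-denominator ratio."""

    precision: float
    recall: float
    accuracy: float
    f_score: float
    flags: tuple[str, ...] = ()

    def as_percent(self) -> dict[str, float]:
        return {
            "precision": 100.0 * self.precision,
            "recall": 100.0 * self.recall,
            "accuracy": 100.0 * self.accuracy,
            "f_score": 100.0 * self.f_score,
        }


def confusion(
    pred: PredictionSet | Mapping[str, set[str]],
    gold: AnnotationSet,
    node: str,
    taxonomy: Taxonomy | None = None,
) -> ConfusionCounts:
    """Per-document confusion counts for one node.

    Gold label sets are closed upward before comparison.  Predictions and
    gold must cover the identical PMID set.
    """
    taxonomy = taxonomy or default_taxonomy()
    node = taxonomy.resolve(node)
    pred_labels = pred.labels if isinstance(pred, PredictionSet) else pred
    missing = set(gold.labels) ^ set(pred_labels)
    if missing:
        raise ValueError(
            f"prediction/gold pmid mismatch: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    tp = fp = fn = tn = 0
    for pmid, labels in gold.labels.items():
        in_gold = node in propagate_labels(taxonomy, labels)
        in_pred = node in pred_labels[pmid]
        if in_gold and in_pred:
            tp += 1
        elif in_pred:
            fp += 1
        elif in_gold:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(counts: ConfusionCounts) -> NodeMetrics:
    """Standard measures from confusion counts (zero denominator -> 0)."""
    if counts.total == 0:
        raise ValueError("metrics of empty confusion counts are undefined")
    flags = []
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, flags = 0.0, flags + ["recall"]
    accuracy = (counts.tp + counts.tn) / counts.total
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score, flags = 0.0, flags + ["f_score"]
    return NodeMetrics(precision, recall, accuracy, f_score, tuple(flags))


# ----------------------------------------------------------------------
# cross-validation


@dataclass
class EvaluationReport:
    """Per-node metrics table with the manifest that reproduces it."""

    node_metrics: dict[str, NodeMetrics]
    node_counts: dict[str, ConfusionCounts]
    k: int
    inner_k: int
    seed: int
    manifest: dict = field(default_factory=dict)
    undefined_nodes: list[str] = field(default_factory=list)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        rows = {}
        for node, m in self.node_metrics.items():
            vals = m.as_percent() if percent else {
                "precision": m.precision,
                "recall": m.recall,
                "accuracy": m.accuracy,
                "f_score": m.f_score,
            }
            vals["flags"] = ";".join(m.flags)
            rows[node] = vals
        return pd.DataFrame.from_dict(rows, orient="index")

    def macro_f(self, nodes: Sequence[str] | None = None) -> float:
        nodes = list(nodes) if nodes is not None else list(self.node_metrics)
        return float(
            np.mean([self.node_metrics[n].f_score for n in nodes])
        )

    def results_json(self) -> str:
        """Canonical JSON of the per-node results only (no run manifest);
        two evaluations with identical outcomes serialize identically."""
        payload = {
            "k": self.k,
            "inner_k": self.inner_k,
            "seed": self.seed,
            "undefined_nodes": self.undefined_nodes,
            "nodes": {
                node: {
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "precision": self.node_metrics[node].precision,
                    "recall": self.node_metrics[node].recall,
                    "accuracy": self.node_metrics[node].accuracy,
                    "f_score": self.node_metrics[node].f_score,
                    "flags": list(self.node_metrics[node].flags),
                }
                for node, c in self.node_counts.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "inner_k": self.inner_k,
            "seed": self.seed,
            "manifest": self.manifest,
            "undefined_nodes": self.undefined_nodes,
            "nodes": {
                node: {
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "precision": self.node_metrics[node].precision,
                    "recall": self.node_metrics[node].recall,
                    "accuracy": self.node_metrics[node].accuracy,
                    "f_score": self.node_metrics[node].f_score,
                    "flags": list(self.node_metrics[node].flags),
                }
                for node, c in self.node_counts.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    def to_tsv(self) -> str:
        lines = ["node\tprecision\trecall\taccuracy\tf_score"]
        for node, m in self.node_metrics.items():
            p = m.as_percent()
            lines.append(
                f"{node}\t{p['precision']:.1f}\t{p['recall']:.1f}"
                f"\t{p['accuracy']:.1f}\t{p['f_score']:.1f}"
            )
        return "\n".join(lines) + "\n"


def _prepare_corpus(
    corpus: Sequence,
    include_title: bool,
) -> tuple[list[str], list[frozenset[feat.FeatureKey]]]:
    """PMIDs plus all-family feature sets, annotating records if needed."""
    annotator = TextAnnotator(include_title=include_title)
    lexicon = feat.load_verb_cluster_lexicon()
    pmids: list[str] = []
    featuresets: list[frozenset[feat.FeatureKey]] = []
    for item in corpus:
        if isinstance(item, DocumentRecord):
            pmids.append(item.pmid)
            featuresets.append(
                feat.extract_all(annotator.annotate(item), lexicon)
            )
        elif isinstance(item, AnnotatedDocument):
            pmids.append(item.record.pmid)
            featuresets.append(feat.extract_all(item, lexicon))
        else:
            raise TypeError(
                "corpus items must be DocumentRecord or AnnotatedDocument"
            )
    return pmids, featuresets


def cross_validate(
    corpus: Sequence,
    annotations: AnnotationSet,
    taxonomy: Taxonomy | None = None,
    k: int = 3,
    inner_k: int = 5,
    seed: int = 0,
    aggregate: str = "pool",
    include_abstractless: bool = False,
    _prepared: tuple[list[str], list[frozenset]] | None = None,
    **params,
) -> EvaluationReport:
    """Outer k-fold cross-validation of the full ensemble.

    Feature selection and hyperparameter tuning run inside each training
    split only.  Per-node confusion counts are pooled across folds before
    metrics are computed (``aggregate="mean"`` averages per-fold metrics
    instead).  Extra keyword parameters configure the underlying
    :class:`~expotext.classify.ExposureTaxonomyClassifier`.
    """
    if aggregate not in ("pool", "mean"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    taxonomy = taxonomy or default_taxonomy()
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
    if _prepared is not None:
        pmids, featuresets = _prepared
    else:
        pmids, featuresets = _prepare_corpus(
            corpus, params.get("include_title", False)
        )
    labels = []
    for pmid in pmids:
        if pmid not in annotations.labels:
            raise ValueError(f"no annotation for pmid {pmid}")
        labels.append(set(annotations.labels[pmid]))

    folds = split_folds(pmids, k=k, seed=seed)
    index_of = {pmid: i for i, pmid in enumerate(pmids)}
    pooled: dict[str, ConfusionCounts] = {}
    per_fold: dict[str, list[NodeMetrics]] = {}
    skipped: set[str] = set()
    for fold_idx in range(k):
        test_pmids = sorted(folds.fold(fold_idx))
        test_idx = [index_of[p] for p in test_pmids]
        train_idx = [
            i for i, p in enumerate(pmids) if folds.assignment[p] != fold_idx
        ]
        est = ExposureTaxonomyClassifier(
            taxonomy=taxonomy, inner_k=inner_k, random_state=seed, **params
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est.fit(
                [featuresets[i] for i in train_idx],
                [labels[i] for i in train_idx],
            )
        skipped.update(est.skipped_nodes_)
        pred_sets = est.predict_labels([featuresets[i] for i in test_idx])
        for node in est.classes_:
            tp = fp = fn = tn = 0
            for row, i in enumerate(test_idx):
                in_gold = node in propagate_labels(taxonomy, labels[i])
                in_pred = node in pred_sets[row]
                if in_gold and in_pred:
                    tp += 1
                elif in_pred:
                    fp += 1
                elif in_gold:
                    fn += 1
                else:
                    tn += 1
            fold_counts = ConfusionCounts(tp, fp, fn, tn)
            pooled[node] = pooled.get(node, ConfusionCounts()) + fold_counts
            per_fold.setdefault(node, []).append(metrics(fold_counts))

    node_order = [n for n in taxonomy.node_names if n in pooled]
    node_counts = {n: pooled[n] for n in node_order}
    if aggregate == "pool":
        node_metrics = {n: metrics(node_counts[n]) for n in node_order}
    else:
        node_metrics = {}
        for n in node_order:
            ms = per_fold[n]
            node_metrics[n] = NodeMetrics(
                precision=float(np.mean([m.precision for m in ms])),
                recall=float(np.mean([m.recall for m in ms])),
                accuracy=float(np.mean([m.accuracy for m in ms])),
                f_score=float(np.mean([m.f_score for m in ms])),
                flags=tuple(
                    sorted({flag for m in ms for flag in m.flags})
                ),
            )
    manifest = {
        "n_documents": len(pmids),
        "aggregate": aggregate,
        "families": list(params.get("families", feat.FAMILIES)),
        "min_df": params.get("min_df", 5),
        "max_df": params.get("max_df", 0.30),
        "C_grid": [float(c) for c in params.get("C_grid", (0.1, 1.0, 10.0, 100.0))],
        "gamma_grid": [
            float(g) for g in params.get("gamma_grid", (0.001, 0.01, 0.1, 1.0))
        ],
    }
    return EvaluationReport(
        node_metrics=node_metrics,
        node_counts=node_counts,
        k=k,
        inner_k=inner_k,
        seed=seed,
        manifest=manifest,
        undefined_nodes=sorted(skipped),
    )


# ----------------------------------------------------------------------
# feature ablation


@dataclass
class AblationReport:
    """Baseline F plus per-family F after removing that family."""

    baseline: EvaluationReport
    ablated: dict[str, EvaluationReport]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        nodes = list(self.baseline.node_metrics)
        data = {
            "all": [
                scale * self.baseline.node_metrics[n].f_score for n in nodes
            ]
        }
        for family, report in self.ablated.items():
            data[family] = [
                scale * report.node_metrics[n].f_score
                if n in report.node_metrics
                else np.nan
                for n in nodes
            ]
        return pd.DataFrame(data, index=nodes)

    def average_deltas(self) -> dict[str, float]:
        """Baseline mean F minus ablated mean F, per family (fractions)."""
        out = {}
        for family, report in self.ablated.items():
            common = [
                n
                for n in self.baseline.node_metrics
                if n in report.node_metrics
            ]
            base = np.mean(
                [self.baseline.node_metrics[n].f_score for n in common]
            )
            abl = np.mean([report.node_metrics[n].f_score for n in common])
            out[family] = float(base - abl)
        return out


def ablate_feature_family(
    corpus: Sequence,
    annotations: AnnotationSet,
    taxonomy: Taxonomy | None = None,
    family: str = "LBOW",
    **cv_params,
) -> EvaluationReport:
    """Cross-validate with one feature family removed everywhere."""
    if family not in feat.FAMILIES:
        raise ValueError(f"unknown feature family {family!r}")
    families = tuple(f for f in feat.FAMILIES if f != family)
    return cross_validate(
        corpus, annotations, taxonomy, families=families, **cv_params
    )


def ablation_report(
    corpus: Sequence,
    annotations: AnnotationSet,
    taxonomy: Taxonomy | None = None,
    families: Sequence[str] = feat.FAMILIES,
    **cv_params,
) -> AblationReport:
    """Leave-one-family-out analysis over all seven feature families."""
    corpus = list(corpus)
    if not cv_params.get("include_abstractless", False):
        corpus = [
            r
            for r in corpus
            if (
                r.has_abstract
                if isinstance(r, DocumentRecord)
                else r.record.has_abstract
            )
        ]
    pmids, featuresets = _prepare_corpus(
        corpus, cv_params.get("include_title", False)
    )
    prepared = (pmids, featuresets)
    baseline = cross_validate(
        corpus, annotations, taxonomy, _prepared=prepared, **cv_params
    )
    ablated = {}
    for family in families:
        kept = tuple(f for f in feat.FAMILIES if f != family)
        ablated[family] = cross_validate(
            corpus,
            annotations,
            taxonomy,
            families=kept,
            _prepared=prepared,
            **cv_params,
        )
    return AblationReport(baseline=baseline, ablated=ablated)


# ----------------------------------------------------------------------
# inter-annotator agreement


@dataclass
class AgreementReport:
    node_kappa: dict[str, float | None]
    average_kappa: float
    n_documents: int

    def defined(self) -> dict[str, float]:
        return {n: k for n, k in self.node_kappa.items() if k is not None}


def _kappa_2x2(n11: int, n10: int, n01: int, n00: int) -> float | None:
    """Cohen's kappa for a binary 2x2 agreement table.

    Perfect observed agreement gives 1.0 even when chance agreement is
    also perfect (both marginals degenerate); otherwise a degenerate
    expected agreement of 1 leaves kappa undefined (None).
    """
    n = n11 + n10 + n01 + n00
    if n == 0:
        return None
    po = (n11 + n00) / n
    if po == 1.0:
        return 1.0
    a1 = (n11 + n10) / n  # annotator A positive rate
    b1 = (n11 + n01) / n  # annotator B positive rate
    pe = a1 * b1 + (1 - a1) * (1 - b1)
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


def cohen_kappa(
    a: AnnotationSet,
    b: AnnotationSet,
    taxonomy: Taxonomy | None = None,
) -> AgreementReport:
    """Per-node chance-corrected agreement between two annotators.

    Both label sets are closed upward before comparison; the summary is
    the unweighted mean kappa over nodes where kappa is defined.
    """
    taxonomy = taxonomy or default_taxonomy()
    if set(a.labels) != set(b.labels):
        diff = sorted(set(a.labels) ^ set(b.labels))
        raise ValueError(f"annotator pmid coverage differs: {diff[:10]}")
    pmids = sorted(a.labels)
    closed_a = {p: propagate_labels(taxonomy, a.labels[p]) for p in pmids}
    closed_b = {p: propagate_labels(taxonomy, b.labels[p]) for p in pmids}
    node_kappa: dict[str, float | None] = {}
    for node in taxonomy.node_names:
        n11 = n10 = n01 = n00 = 0
        for p in pmids:
            in_a = node in closed_a[p]
            in_b = node in closed_b[p]
            if in_a and in_b:
                n11 += 1
            elif in_a:
                n10 += 1
            elif in_b:
                n01 += 1
            else:
                n00 += 1
        node_kappa[node] = _kappa_2x2(n11, n10, n01, n00)
    defined = [v for v in node_kappa.values() if v is not None]
    average = float(np.mean(defined)) if defined else float("nan")
    return AgreementReport(
        node_kappa=node_kappa,
        average_kappa=average,
        n_documents=len(pmids),
    )


# ----------------------------------------------------------------------
# retrieval comparison


@dataclass(frozen=True)
class RetrievalComparison:
    """Recall of a node classifier against a reference PMID list."""

    found: int
    total: int
    missing: tuple[str, ...]

    @property
    def ratio(self) -> str:
        return f"{self.found}/{self.total}"


def compare_retrieval(
    pred: PredictionSet | Mapping[str, set[str]],
    node: str,
    reference_pmids: Sequence[str],
    taxonomy: Taxonomy | None = None,
) -> RetrievalComparison:
    """How many reference documents the classifier labelled with *node*."""
    taxonomy = taxonomy or default_taxonomy()
    node = taxonomy.resolve(node)
    pred_labels = pred.labels if isinstance(pred, PredictionSet) else pred
    reference = list(dict.fromkeys(reference_pmids))
    positives = {p for p, labs in pred_labels.items() if node in labs}
    missing = tuple(p for p in reference if p not in positives)
    return RetrievalComparison(
        found=len(reference) - len(missing),
        total=len(reference),
        missing=missing,
    )
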