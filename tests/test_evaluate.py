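"""Metrics, cross-validation, ablation, kappa and retrieval comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

import expotext as et
from expotext.evaluate import (
    ConfusionCounts,
    _kappa_2x2,
    ablation_report,
    cohen_kappa,
    compare_retrieval,
    confusion,
    cross_validate,
    metrics,
)


# ----------------------------------------------------------------------
# metrics


def test_metrics_closed_form_example():
    m = metrics(ConfusionCounts(tp=1, fp=1, fn=0, tn=8))
    assert m.precision == 0.5
    assert m.recall == 1.0
    assert m.accuracy == 0.9
    assert m.f_score == pytest.approx(2 / 3)
    assert m.flags == ()


def test_metrics_zero_denominator_convention():
    m = metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
    assert m.precision == 0.0 and m.recall == 0.0 and m.f_score == 0.0
    assert "precision" in m.flags and "f_score" in m.flags
    with pytest.raises(ValueError):
        metrics(ConfusionCounts())


@given(
    st.tuples(
        st.integers(0, 500),
        st.integers(0, 500),
        st.integers(0, 500),
        st.integers(0, 500),
    )
)
def test_metrics_match_independent_formula_oracle(counts):
    tp, fp, fn, tn = counts
    if tp + fp + fn + tn == 0:
        return
    m = metrics(ConfusionCounts(tp, fp, fn, tn))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    assert abs(m.precision - precision) < 1e-12
    assert abs(m.recall - recall) < 1e-12
    assert abs(m.accuracy - (tp + tn) / (tp + fp + fn + tn)) < 1e-12
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    assert abs(m.f_score - f) < 1e-12


# ----------------------------------------------------------------------
# confusion


def test_confusion_identity_and_empty_predictions(taxonomy):
    gold = et.AnnotationSet(
        {str(i): ({"blood"} if i < 3 else set()) for i in range(10)}
    )
    same = {str(i): ({"blood"} if i < 3 else set()) for i in range(10)}
    c = confusion(same, gold, "blood", taxonomy)
    assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 7)
    empty = {str(i): set() for i in range(10)}
    c = confusion(empty, gold, "blood", taxonomy)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 3, 7)
    assert metrics(confusion(same, gold, "blood", taxonomy)).f_score == 1.0


def test_confusion_closes_gold_upward(taxonomy):
    gold = et.AnnotationSet({"1": {"blood"}})
    pred = {"1": {"biomonitoring"}}
    c = confusion(pred, gold, "biomonitoring", taxonomy)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 0)


def test_confusion_pmid_mismatch_lists_difference(taxonomy):
    gold = et.AnnotationSet({"1": set(), "2": set()})
    with pytest.raises(ValueError, match="3"):
        confusion({"1": set(), "3": set()}, gold, "blood", taxonomy)


def test_confusion_matches_brute_force_counter(taxonomy):
    rng = np.random.default_rng(7)
    nodes = list(taxonomy.node_names)
    gold_labels, pred_labels = {}, {}
    for i in range(400):
        pmid = str(i)
        gold_labels[pmid] = set(
            rng.choice(nodes, size=rng.integers(0, 3), replace=False)
        )
        pred_labels[pmid] = set(
            rng.choice(nodes, size=rng.integers(0, 3), replace=False)
        )
    gold = et.AnnotationSet(gold_labels)
    for node in rng.choice(nodes, size=6, replace=False):
        c = confusion(pred_labels, gold, node, taxonomy)
        tp = fp = fn = tn = 0
        for pmid in gold_labels:
            g = node in et.propagate_labels(taxonomy, gold_labels[pmid])
            p = node in pred_labels[pmid]
            tp += g and p
            fp += p and not g
            fn += g and not p
            tn += not g and not p
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 400


# ----------------------------------------------------------------------
# cross-validation and ablation (small fast corpus)


@pytest.fixture(scope="module")
def tiny_cv_corpus():
    spec = et.SyntheticCorpusSpec(
        leaves=("blood", "food"),
        docs_per_leaf=21,
        irrelevant_docs=21,
        mode="lbow_only",
        mesh_rate=0.0,
        chem_rate=0.0,
        multilabel_rate=0.0,
        seed=29,
    )
    return et.generate_corpus(spec)


CV_PARAMS = dict(
    k=3, inner_k=3, seed=1, min_df=3,
    C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1),
)


def test_cross_validation_is_deterministic_and_separable(tiny_cv_corpus):
    records, gold = tiny_cv_corpus
    r1 = cross_validate(records, gold, **CV_PARAMS)
    r2 = cross_validate(records, gold, **CV_PARAMS)
    assert r1.to_json() == r2.to_json()
    # strongly separable synthetic corpus: near-perfect leaf F-scores
    assert r1.macro_f(["blood", "food"]) >= 0.9
    # pooled counts cover the whole corpus for every node
    assert all(c.total == len(records) for c in r1.node_counts.values())


def test_per_fold_mean_aggregation_mode(tiny_cv_corpus):
    records, gold = tiny_cv_corpus
    r = cross_validate(records, gold, aggregate="mean", **CV_PARAMS)
    assert set(r.node_metrics) == set(r.node_counts)
    with pytest.raises(ValueError):
        cross_validate(records, gold, aggregate="median", **CV_PARAMS)


def test_report_exports(tiny_cv_corpus):
    records, gold = tiny_cv_corpus
    r = cross_validate(records, gold, **CV_PARAMS)
    frame = r.to_frame()
    assert {"precision", "recall", "accuracy", "f_score"} <= set(frame.columns)
    assert r.to_tsv().startswith("node\t")


def test_inert_family_ablation_reproduces_baseline_bitwise(tiny_cv_corpus):
    records, gold = tiny_cv_corpus
    # lbow_only template: bigram/relation/verb/entity families never fire
    report = ablation_report(
        records, gold, families=("NE", "VC", "GR", "NBIGRAM"), **CV_PARAMS
    )
    for family in ("NE", "VC", "GR", "NBIGRAM"):
        assert (
            report.ablated[family].results_json()
            == report.baseline.results_json()
        ), family
    deltas = report.average_deltas()
    assert all(abs(d) < 1e-12 for d in deltas.values())
    frame = report.to_frame()
    assert list(frame.columns) == ["all", "NE", "VC", "GR", "NBIGRAM"]


def test_unknown_family_rejected(tiny_cv_corpus):
    records, gold = tiny_cv_corpus
    with pytest.raises(ValueError):
        et.evaluate.ablate_feature_family(records, gold, family="TFIDF")


# ----------------------------------------------------------------------
# Cohen's kappa


def test_identical_annotators_have_kappa_one(taxonomy, small_corpus):
    _records, gold = small_corpus
    report = cohen_kappa(gold, gold, taxonomy)
    assert all(k == 1.0 for k in report.node_kappa.values())
    assert report.average_kappa == 1.0


def test_hand_2x2_table_gives_exact_kappa():
    # agreement table (45, 5 / 5, 45) over 100 documents: kappa = 0.8
    assert _kappa_2x2(45, 5, 5, 45) == pytest.approx(0.8, abs=1e-12)


def test_kappa_formula_cross_checked_against_sklearn():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        n11 = int(np.sum((a == 1) & (b == 1)))
        n10 = int(np.sum((a == 1) & (b == 0)))
        n01 = int(np.sum((a == 0) & (b == 1)))
        n00 = int(np.sum((a == 0) & (b == 0)))
        ours = _kappa_2x2(n11, n10, n01, n00)
        theirs = cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_kappa_is_symmetric_and_order_invariant(taxonomy):
    rng = np.random.default_rng(9)
    nodes = list(taxonomy.node_names)
    a_labels, b_labels = {}, {}
    for i in range(80):
        a_labels[str(i)] = set(
            rng.choice(nodes, size=rng.integers(0, 3), replace=False)
        )
        b_labels[str(i)] = set(
            rng.choice(nodes, size=rng.integers(0, 3), replace=False)
        )
    a = et.AnnotationSet(a_labels, "a")
    b = et.AnnotationSet(b_labels, "b")
    ab = cohen_kappa(a, b, taxonomy)
    ba = cohen_kappa(b, a, taxonomy)
    assert ab.node_kappa == ba.node_kappa
    shuffled = et.AnnotationSet(
        dict(sorted(b_labels.items(), reverse=True)), "b"
    )
    assert cohen_kappa(a, shuffled, taxonomy).node_kappa == ab.node_kappa


def test_kappa_coverage_mismatch_raises(taxonomy):
    a = et.AnnotationSet({"1": set()})
    b = et.AnnotationSet({"2": set()})
    with pytest.raises(ValueError):
        cohen_kappa(a, b, taxonomy)


# ----------------------------------------------------------------------
# retrieval comparison


def test_retrieval_comparison_found_over_total():
    pred = {f"p{i}": ({"blood"} if i < 27 else set()) for i in range(30)}
    reference = [f"p{i}" for i in range(28)]
    result = compare_retrieval(pred, "blood", reference)
    assert result.ratio == "27/28"
    assert result.missing == ("p27",)
    # reference fully covered
    assert compare_retrieval(pred, "blood", ["p0", "p1"]).ratio == "2/2"
    # disjoint sets: everything missing
    none = compare_retrieval(pred, "urine", reference)
    assert none.found == 0 and len(none.missing) == 28
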