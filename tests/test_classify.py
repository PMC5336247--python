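"""Node classifier ensemble: training sets, tuning, determinism, bundles."""

import hashlib
import os
import warnings

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.base import clone
from sklearn.svm import SVC

import expotext as et
from expotext.classify import (
    DegenerateTrainingError,
    assemble_training_set,
    load_model_bundle,
    save_model_bundle,
    tune_hyperparameters,
)
from conftest import FAST_PARAMS


def bundle_digest(path):
    h = hashlib.sha256()
    for root, _dirs, files in sorted(os.walk(path)):
        for name in sorted(files):
            h.update(name.encode())
            with open(os.path.join(root, name), "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()


# ----------------------------------------------------------------------
# training-set assembly


def test_subnode_annotation_is_positive_for_ancestors(taxonomy):
    records = [
        et.DocumentRecord(pmid="1", abstract="blood lead measured here."),
        et.DocumentRecord(pmid="2", abstract="nothing relevant at all."),
    ]
    gold = et.AnnotationSet({"1": {"blood"}, "2": set()})
    for node, expected in [
        ("blood", [1, 0]),
        ("exposure_biomarker", [1, 0]),
        ("biomonitoring", [1, 0]),
        ("urine", [0, 0]),
    ]:
        _X, y = assemble_training_set(
            records, gold, node, taxonomy,
            thresholds=et.FeatureThresholds(min_df=1, max_df=2),
        )
        assert y.tolist() == expected, node


def test_irrelevant_documents_are_negative_everywhere(taxonomy):
    records = [et.DocumentRecord(pmid="1", abstract="background words only.")]
    gold = et.AnnotationSet({"1": set()})
    for node in taxonomy.node_names:
        _X, y = assemble_training_set(
            records, gold, node, taxonomy,
            thresholds=et.FeatureThresholds(min_df=1, max_df=1),
        )
        assert y.tolist() == [0]


def test_positive_counts_match_closure_counting_oracle(taxonomy):
    rng = np.random.default_rng(42)
    nodes = list(taxonomy.node_names)
    records, labels = [], {}
    for i in range(60):
        pmid = str(i)
        records.append(
            et.DocumentRecord(pmid=pmid, abstract=f"doc number {i} text.")
        )
        labels[pmid] = set(
            rng.choice(nodes, size=rng.integers(0, 4), replace=False)
        )
    gold = et.AnnotationSet(labels)
    positives = {}
    for node in nodes:
        _X, y = assemble_training_set(
            records, gold, node, taxonomy,
            thresholds=et.FeatureThresholds(min_df=1, max_df=60),
        )
        positives[node] = int(y.sum())
        # brute-force closure counting oracle
        oracle = sum(
            1
            for pmid in labels
            if node in et.propagate_labels(taxonomy, labels[pmid])
        )
        assert positives[node] == oracle
    # parent positives are a superset of each child's positives
    for node in nodes:
        for child in taxonomy.node(node).children:
            assert positives[node] >= positives[child]


# ----------------------------------------------------------------------
# hyperparameter tuning


def _blobs(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 4))
    y = np.array([i % 2 for i in range(n)])
    X[y == 1, :2] = 1.0
    X[y == 0, 2:] = 1.0
    X += rng.normal(0, 0.01, X.shape)
    return sp.csr_matrix(X), y


def test_single_grid_point_is_returned_unchanged():
    X, y = _blobs()
    assert tune_hyperparameters(X, y, grid=[(7.0, 0.5)]) == (7.0, 0.5)


def test_separable_blobs_reach_perfect_inner_f():
    X, y = _blobs()
    C, gamma = tune_hyperparameters(
        X, y, grid=[(0.01, 0.001), (1.0, 0.1), (10.0, 0.1)], inner_k=3
    )
    svc = SVC(C=C, gamma=gamma).fit(X, y)
    assert (svc.predict(X) == y).all()


def test_ties_break_toward_smaller_c_then_gamma():
    X, y = _blobs()
    # all these points separate the blobs perfectly -> tie at F = 1
    grid = [(10.0, 0.1), (1.0, 0.1), (1.0, 0.01), (10.0, 0.01)]
    assert tune_hyperparameters(X, y, grid=grid, inner_k=3) == (1.0, 0.01)


def test_single_class_labels_raise_degenerate_error():
    X, _ = _blobs()
    with pytest.raises(DegenerateTrainingError):
        tune_hyperparameters(X, np.zeros(X.shape[0]))


# ----------------------------------------------------------------------
# ensemble training and prediction


def test_ensemble_trains_annotated_nodes_and_skips_the_rest(small_ensemble):
    trained = set(small_ensemble.classes_)
    assert trained == {
        "biomonitoring", "exposure_biomarker", "blood", "urine",
        "exposure_routes", "oral_intake", "food",
    }
    assert "soil" in small_ensemble.skipped_nodes_
    assert len(small_ensemble.skipped_nodes_) == 32 - len(trained)


def test_ensemble_recovers_planted_labels_on_training_data(
    small_corpus, small_ensemble
):
    records, gold = small_corpus
    pred = et.predict(small_ensemble, records)
    hits = sum(
        1
        for rec in records
        if et.propagate_labels(small_ensemble.taxonomy_, gold.labels[rec.pmid])
        & set(small_ensemble.classes_)
        <= pred.labels[rec.pmid]
    )
    assert hits >= 0.95 * len(records)


def test_empty_abstract_document_predicts_from_metadata(small_ensemble):
    rec = et.DocumentRecord(pmid="x", abstract="", mesh_terms=["mesh-blood"])
    pred = et.predict(small_ensemble, [rec])
    assert isinstance(pred.labels["x"], set)  # may be empty; must not crash


def test_node_decisions_are_independent(small_corpus, small_ensemble):
    records, _ = small_corpus
    docs = records[:15]
    before = et.predict(small_ensemble, docs)
    # removing one node's classifier must not change any other node
    import copy

    pruned = copy.copy(small_ensemble)
    pruned.node_models_ = dict(small_ensemble.node_models_)
    del pruned.node_models_["food"]
    pruned.classes_ = np.array(
        [n for n in small_ensemble.classes_ if n != "food"], dtype=object
    )
    after = et.predict(pruned, docs)
    for pmid in before.labels:
        assert before.labels[pmid] - {"food"} == after.labels[pmid]


def test_child_may_be_predicted_without_parent(small_ensemble):
    # no hierarchy consistency is forced at prediction time: the decision
    # columns are computed independently, so nothing couples child to parent
    assert small_ensemble.hierarchy_closure is False


def test_hierarchy_closure_flag_adds_ancestors(small_corpus, small_ensemble):
    records, _ = small_corpus
    import copy

    closed = copy.copy(small_ensemble)
    closed.hierarchy_closure = True
    pred = et.predict(closed, records[:10])
    for labels in pred.labels.values():
        assert (
            et.propagate_labels(closed.taxonomy_, labels)
            & set(closed.classes_)
            == labels
        )


def test_stored_decision_function_matches_sklearn_svc(small_corpus):
    """Dual route: NodeModel's kernel expansion equals SVC.decision_function."""
    records, gold = small_corpus
    node = "blood"
    X, y = assemble_training_set(
        records, gold, node,
        thresholds=et.FeatureThresholds(min_df=3, max_df=0.5),
    )
    svc = SVC(C=10.0, gamma=0.1, kernel="rbf").fit(X, y)
    model = et.NodeModel(
        node=node,
        vocabulary=et.build_vocabulary(
            [frozenset()], node, et.FeatureThresholds(1, 1)
        ),
        C=10.0,
        gamma=0.1,
        support_indices=[
            sorted(
                sp.csr_matrix(svc.support_vectors_)[i].indices.tolist()
            )
            for i in range(svc.support_vectors_.shape[0])
        ],
        dual_coef=np.ravel(
            svc.dual_coef_.toarray()
            if sp.issparse(svc.dual_coef_)
            else svc.dual_coef_
        ).tolist(),
        intercept=float(svc.intercept_[0]),
    )
    model.vocabulary.features = list(range(X.shape[1]))  # width only
    np.testing.assert_allclose(
        model.decision_function(X), svc.decision_function(X), atol=1e-9
    )


def test_sklearn_estimator_api_round_trips_params():
    est = et.ExposureTaxonomyClassifier(min_df=7, random_state=3)
    params = est.get_params()
    assert params["min_df"] == 7
    cloned = clone(est)
    assert cloned.get_params()["random_state"] == 3
    est.set_params(min_df=2)
    assert est.get_params()["min_df"] == 2


def test_fit_input_validation():
    est = et.ExposureTaxonomyClassifier()
    with pytest.raises(ValueError):
        est.fit([], [])
    with pytest.raises(ValueError):
        est.fit([et.DocumentRecord(pmid="1")], [])
    with pytest.raises(TypeError):
        est.fit([42], [set()])


def test_retraining_with_same_seed_is_byte_identical(
    small_corpus, tmp_path
):
    records, gold = small_corpus
    digests = []
    for run in ("a", "b"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = et.train_ensemble(records, gold, **FAST_PARAMS)
        save_model_bundle(ens, tmp_path / run)
        digests.append(bundle_digest(tmp_path / run))
    assert digests[0] == digests[1]


def test_model_bundle_round_trip(small_corpus, small_ensemble, tmp_path):
    records, _ = small_corpus
    d1, d2 = tmp_path / "m1", tmp_path / "m2"
    save_model_bundle(small_ensemble, d1)
    loaded = load_model_bundle(d1)
    save_model_bundle(loaded, d2)
    assert bundle_digest(d1) == bundle_digest(d2)
    assert list(loaded.classes_) == list(small_ensemble.classes_)
    docs = records[:20]
    assert np.array_equal(
        loaded.predict(docs), small_ensemble.predict(docs)
    )


def test_prediction_tsv_export(small_ensemble, small_corpus):
    import io

    records, _ = small_corpus
    pred = et.predict(small_ensemble, records[:5])
    buf = io.StringIO()
    et.classify.write_predictions(pred, buf)
    lines = buf.getvalue().splitlines()
    assert len(lines) == 5
    assert all("\t" in line for line in lines)
    long_buf = io.StringIO()
    et.classify.write_predictions(pred, long_buf, long_format=True)
    assert len(long_buf.getvalue().splitlines()) == 5 * len(
        small_ensemble.classes_
    )
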