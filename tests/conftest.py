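import warnings

import pytest
from hypothesis import HealthCheck, settings

import expotext as et

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# reduced training settings for fast unit-level ensemble tests
FAST_PARAMS = dict(
    min_df=3, C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), inner_k=3
)


@pytest.fixture(scope="session")
def taxonomy():
    return et.default_taxonomy()


@pytest.fixture(scope="session")
def small_corpus():
    """Separable 3-leaf corpus: 24 positives per leaf + 30 irrelevant."""
    spec = et.SyntheticCorpusSpec(
        leaves=("blood", "urine", "food"),
        docs_per_leaf=24,
        irrelevant_docs=30,
        seed=11,
    )
    return et.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_ensemble(small_corpus):
    records, gold = small_corpus
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return et.train_ensemble(records, gold, **FAST_PARAMS)


@pytest.fixture(scope="session")
def annotator():
    return et.TextAnnotator()
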