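import numpy as np
import pytest

from msm.features import build_matrix
from msm.lexicons import score_document
from msm.metaphor_id import MetaphorAnnotator
from msm.synthetic import (
    CohortSpec,
    PlantedEmbeddingSpec,
    make_cohort,
    make_embeddings,
    make_lexicons,
    make_planted_corpus,
)


@pytest.fixture(scope="session")
def world():
    return make_embeddings(PlantedEmbeddingSpec(seed=1))


@pytest.fixture(scope="session")
def lexicons(world):
    return make_lexicons(world)


@pytest.fixture(scope="session")
def planted_corpus(world):
    return make_planted_corpus(world, seed=1)


@pytest.fixture(scope="session")
def annotated_cohort(world, lexicons):
    """A study-scale cohort, annotated and scored, with its feature matrix."""
    cohort = make_cohort(CohortSpec(seed=2), world, lexicons)
    MetaphorAnnotator(world.store, world.ontology).transform(cohort.documents)
    for doc in cohort.documents:
        score_document(doc, lexicons.strength)
    X, y = build_matrix(
        cohort.documents, cohort.labels, "depression", lexicons.sentic
    )
    return cohort, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
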