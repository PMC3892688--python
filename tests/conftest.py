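import numpy as np
import pytest

from flystage import gabor, synthetic
from flystage.ensemble import ModelPool, PoolMember, PoolSpec
from flystage.learners import LinearModel, OneVsRestModel

STAGE_CLASSES = np.arange(3, 18)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def standard_bank():
    return gabor.build_filter_bank()


@pytest.fixture(scope="session")
def tiny_corpus():
    """60-image synthetic corpus (4 per stage), moderate noise."""
    return synthetic.generate(synthetic.SyntheticSpec(n_per_stage=4, seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus, standard_bank):
    X, groups = gabor.extract_feature_matrix(tiny_corpus.images, standard_bank)
    return X, groups


@pytest.fixture(scope="session")
def blob_data():
    """Cheap well-separated 15-class data for exercising pool machinery."""
    gen = np.random.default_rng(5)
    stages = np.repeat(STAGE_CLASSES, 12)
    means = gen.normal(scale=4.0, size=(15, 20))
    X = means[stages - 3] + gen.normal(scale=0.5, size=(len(stages), 20))
    return X, stages


def constant_stage_member(
    stage: int,
    confidence: float,
    d: int = 4,
    algorithm: str = "lasso_ls",
    training_ratio: float = 0.5,
    partition_index: int = 0,
) -> PoolMember:
    """A member that always votes for one fixed stage (intercept one-hot)."""
    models = tuple(
        LinearModel(
            weights=np.zeros(d),
            intercept=1.0 if c == stage else 0.0,
            loss_name="least_square",
            regularizer_name="l1",
        )
        for c in STAGE_CLASSES
    )
    ovr = OneVsRestModel(classes=STAGE_CLASSES.copy(), models=models)
    return PoolMember(
        ovr=ovr,
        confidence=confidence,
        algorithm=algorithm,
        training_ratio=training_ratio,
        partition_index=partition_index,
        seed=0,
        feature_mean=np.zeros(d),
        feature_scale=np.ones(d),
        train_indices=np.arange(0),
        val_indices=np.arange(0),
    )


def make_pool(members, d: int = 4) -> ModelPool:
    spec = PoolSpec(
        algorithms=("lasso_ls",), training_ratios=(0.5,), n_partitions=1
    )
    return ModelPool(
        members=tuple(members), classes=STAGE_CLASSES.copy(), spec=spec, feature_dim=d
    )
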