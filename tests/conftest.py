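import pytest

from coformer_scout import (
    BPClassifier,
    CoformerFeaturizer,
    GeneratorConfig,
    generate_library,
    split_library,
)


@pytest.fixture(scope="session")
def default_library():
    """Default synthetic screening library: 159 records, 10% label noise."""
    return generate_library(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def trained_screen(default_library):
    """A trained suitability classifier + featurizer on the 120/39 split.

    Session-scoped: training is the expensive step shared by the GA and
    evaluation tests.
    """
    lib = default_library
    sp = split_library(lib, 120, seed=2)
    train = lib.subset(sp.train_ids)
    test = lib.subset(sp.test_ids)
    featurizer = CoformerFeaturizer()
    fm = featurizer.fit_transform(train)
    model = BPClassifier(random_state=3).fit(fm, train.labels)
    return model, featurizer, train, test
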