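import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template20():
    """Mean-of-20 synthetic brain template used as registration target."""
    from petbrainx import phantom

    return phantom.make_template(20, seed=5)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A model overfit on a 12-phantom cohort; good enough for pipeline tests."""
    from petbrainx import model, phantom

    cohort = phantom.generate_cohort(
        12, phantom.CohortSpec(truncated_fraction=0.25), seed=7
    )
    ds = model.make_dataset(cohort)
    m, hist = model.train(
        ds, model.ModelConfig.small(),
        model.TrainConfig.overfit(seed=0, epochs=80),
    )
    return m, ds, hist


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
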