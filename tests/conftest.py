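import numpy as np
import pytest

from olfthresh import ObserverSpec, WeibullParams, make_responder


@pytest.fixture
def default_shape():
    """The study's assumed psychometric shape, threshold at pen 8."""
    return WeibullParams(threshold=8.0, beta=3.5, guess=1 / 3, lapse=0.01)


@pytest.fixture
def anchored_shape():
    """Same shape with the threshold anchored at the 80%-correct level."""
    return WeibullParams(threshold=8.0, beta=3.5, guess=1 / 3, lapse=0.01,
                         anchor_p=0.80)


def scripted_responder(responses):
    """Replay a fixed sequence of correct/incorrect flags."""
    it = iter(responses)

    def respond(pen):
        return bool(next(it))

    return respond


@pytest.fixture
def weibull_responder():
    def factory(threshold, beta=3.5, lapse=0.01, seed=0, anchor_p=None):
        pf = WeibullParams(threshold=threshold, beta=beta, lapse=lapse,
                           anchor_p=anchor_p)
        rng = np.random.default_rng(seed)
        return make_responder(ObserverSpec(pf=pf), rng)

    return factory
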