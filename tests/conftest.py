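import numpy as np
import pytest

import sh2pep as s
from sh2pep.svm import SVMConfig


@pytest.fixture(scope="session")
def xor_problem():
    """Balanced XOR domain: linear models blind, quadratic models perfect."""
    rule, background = s.make_xor_rule(1)
    train = s.sample_problem(rule, 500, 500, 0, seed=2, background=background)
    test = s.sample_problem(rule, 300, 300, 0, seed=99, background=background)
    return rule, background, train, test


@pytest.fixture(scope="session")
def xor_split(xor_problem):
    """Encoded train/test arrays for the XOR domain."""
    _, _, train, test = xor_problem
    Xp = s.encode_many(train.positives)
    Xn = s.encode_many(train.negatives)
    Xt = s.encode_many(test.positives + test.negatives)
    yt = np.concatenate([np.ones(len(test.positives)), -np.ones(len(test.negatives))])
    return Xp, Xn, Xt, yt


@pytest.fixture(scope="session")
def xor_models(xor_split):
    """Degree-1 and degree-2 SVMs trained on the XOR domain."""
    Xp, Xn, _, _ = xor_split
    return {
        d: s.train(Xp, Xn, SVMConfig(degree=d, C=1.0), seed=0) for d in (1, 2)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
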