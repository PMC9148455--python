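import numpy as np
import pytest

from longde.design import StudyDesign


@pytest.fixture
def design10():
    return StudyDesign.balanced(10)


@pytest.fixture
def design5():
    return StudyDesign.balanced(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def paired_design():
    """2 timepoints per subject, no group split: X = [1, time2]."""

    def make(n_subjects):
        X = np.zeros((2 * n_subjects, 2))
        X[:, 0] = 1.0
        X[1::2, 1] = 1.0
        subj = np.repeat(np.arange(n_subjects), 2)
        return X, subj

    return make
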