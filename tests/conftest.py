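import numpy as np
import pytest

from corneatrace import CorneaModel, best_focus_all, build_fan, trace_eye

#: marginal means of the study cohort, used as the canonical test eye
MEAN_EYE = dict(R_f=7.733, Q_f=-0.3141, R_b=6.534, Q_b=-0.007, CCT=0.547, PUP=4.408)


@pytest.fixture(scope="session")
def mean_cornea():
    return CorneaModel.from_biometry(
        MEAN_EYE["R_f"], MEAN_EYE["Q_f"], MEAN_EYE["R_b"], MEAN_EYE["Q_b"], MEAN_EYE["CCT"]
    )


@pytest.fixture(scope="session")
def mean_traced(mean_cornea):
    """Mean cornea traced with the standard 1001-ray pupil fan."""
    return trace_eye(mean_cornea, build_fan(MEAN_EYE["PUP"], n_rays=1001))


@pytest.fixture(scope="session")
def mean_focus(mean_traced):
    """All four best-focus planes of the mean cornea (shared, expensive)."""
    return best_focus_all(mean_traced)


def paraxial_focus(R_f, R_b, CCT, n_c=1.376, n_aq=1.336):
    """Matrix-optics (vergence) focus of the thick two-surface cornea.

    Returns the paraxial focal distance from the front apex in mm:
    refract at the front surface, transfer the vergence through the stroma,
    refract at the back surface, then image in the aqueous.
    """
    p1 = 1000.0 * (n_c - 1.0) / R_f
    p2 = 1000.0 * (n_aq - n_c) / R_b
    tau = CCT / 1000.0 / n_c  # reduced thickness in m
    v = p1 / (1.0 - tau * p1) + p2
    return 1000.0 * n_aq / v + CCT


@pytest.fixture(scope="session")
def paraxial_oracle():
    return paraxial_focus


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
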