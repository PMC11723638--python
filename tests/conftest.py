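import numpy as np
import pytest

from swingfree.core_dynamics import ImpedanceParams, SystemParams
from swingfree.internal_models import InternalModelKind
from swingfree.metrics import trim_trial
from swingfree.trial_pipeline import simulate_trial


@pytest.fixture(scope="session")
def params() -> SystemParams:
    return SystemParams()


@pytest.fixture(scope="session")
def imp() -> ImpedanceParams:
    return ImpedanceParams(K=100.0, B=10.0)


@pytest.fixture(scope="session")
def rb_trial(params):
    """One noiseless rigid-body trial (K=150, B=5), untrimmed."""
    return simulate_trial(InternalModelKind.RIGID_BODY, params,
                          ImpedanceParams(K=150.0, B=5.0),
                          D=1.0, L=0.25, extra_T=0.2)


@pytest.fixture(scope="session")
def rb_trimmed(rb_trial):
    return trim_trial(rb_trial)


def make_record(t, xd, x=None, **cols):
    """Hand-built TrialRecord for metric tests."""
    from swingfree.trial_pipeline import TrialRecord
    t = np.asarray(t, dtype=float)
    xd = np.asarray(xd, dtype=float)
    if x is None:
        x = np.concatenate([[0.0], np.cumsum(0.5 * (xd[1:] + xd[:-1])
                                             * np.diff(t))])
    zeros = np.zeros_like(t)
    defaults = dict(F=zeros, xdd=zeros, phi=zeros, phid=zeros, phidd=zeros)
    defaults.update(cols)
    rate = 1.0 / (t[1] - t[0])
    return TrialRecord(subject="T", block="0", trial_index=0, rate=rate,
                       t=t, x=np.asarray(x, dtype=float), xd=xd,
                       metadata={"displacement": 0.25}, **defaults)
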