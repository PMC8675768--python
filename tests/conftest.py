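import numpy as np
import pytest

from hlm.contacts import CrosslinkModel
from hlm.polymer import build_kirchhoff, pinned_covariance, sample_ensemble
from hlm.synthetic import make_chain, make_loops

# (n_bins, n_loops, seed) of the shared loop-decorated sweep models
SWEEP_MODELS = [(10, 3, 11), (12, 3, 12), (15, 4, 13), (20, 5, 14), (25, 5, 15)]


@pytest.fixture(scope="session")
def xl():
    return CrosslinkModel(form="gaussian", capture_radius=1.0)


@pytest.fixture(scope="session")
def xl_step():
    return CrosslinkModel(form="step", capture_radius=1.0)


@pytest.fixture(scope="session")
def chain20_cov():
    return pinned_covariance(build_kirchhoff(make_chain(20, 1.0)))


@pytest.fixture(scope="session")
def loop_model():
    """One loop-decorated network (N = 12) with its pinned covariance."""
    sm, spec = make_loops(12, n_loops=4, seed=3)
    return sm, pinned_covariance(build_kirchhoff(sm)), spec


@pytest.fixture(scope="session")
def sweep_models():
    """Five seeded loop-decorated models for property sweeps."""
    out = []
    for n, n_loops, seed in SWEEP_MODELS:
        sm, spec = make_loops(n, n_loops=n_loops, seed=seed)
        out.append((sm, pinned_covariance(build_kirchhoff(sm))))
    return out


@pytest.fixture(scope="session")
def loop_ensemble(loop_model):
    _, cov, _ = loop_model
    return sample_ensemble(cov, 100_000, seed=5)


def assert_close(a, b, rtol=1e-10, msg=""):
    assert abs(a - b) <= rtol * max(abs(a), abs(b), 1e-300), (
        msg or f"{a} != {b} (rtol {rtol})"
    )
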