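import numpy as np
import pytest

from walkhmm import AngleDist, HMMParams, StepDist, Track


@pytest.fixture
def rng():
    return np.random.default_rng(20240806)


@pytest.fixture
def make_track():
    """Factory for random-walk test tracks with strictly positive steps."""

    def _make(rng, n_positions=20, ndim=2, track_id="t", scale=1.0):
        while True:
            increments = rng.normal(scale=scale, size=(n_positions - 1, ndim))
            if np.all(np.linalg.norm(increments, axis=1) > 1e-9):
                break
        positions = np.vstack([np.zeros(ndim), np.cumsum(increments, axis=0)])
        return Track(id=track_id, positions=positions)

    return _make


@pytest.fixture
def random_params():
    """Factory for random valid HMM parameter sets."""

    def _make(rng, n_states, family="vonmises"):
        if family == "vonmises":
            conc = rng.uniform(0.2, 4.0, size=n_states)
        else:
            conc = rng.uniform(0.05, 0.9, size=n_states)
        angle_dists = tuple(
            AngleDist(mu=float(rng.uniform(-np.pi, np.pi)), kappa=float(c),
                      family=family)
            for c in conc
        )
        step_dists = tuple(
            StepDist(mu_gamma=float(rng.uniform(0.2, 2.0)),
                     sigma_gamma=float(rng.uniform(0.1, 1.0)))
            for _ in range(n_states)
        )
        raw = rng.uniform(0.2, 1.0, size=(n_states, n_states)) + 2.0 * np.eye(n_states)
        tpm = raw / raw.sum(axis=1, keepdims=True)
        return HMMParams(angle_dists=angle_dists, step_dists=step_dists, tpm=tpm)

    return _make
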