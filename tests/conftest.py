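"""Shared fixtures: small randomized models and stimulus-response pairs."""

import numpy as np
import pytest

from mphmm import (
    StimulusEmbeddingSpec,
    StimulusResponsePair,
    build_mn_template,
    build_mxr_template,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_mxr(rng, d=2, W=4, r_spike=0.3, m_spike=0.3):
    """MXR model with random transitions and spike mean; R-state may spike."""
    emb = StimulusEmbeddingSpec(window_length=d, channels=1)
    m = build_mxr_template(emb, spike_rate=m_spike, band_width=W)
    n = m.n_states
    T = rng.dirichlet(np.ones(n + 1), size=n)
    m.transitions, m.final = T[:, :n], T[:, n]
    m.initial = rng.dirichlet(np.ones(n))
    m.states[0].emission.conditional_stimulus[1].means = rng.normal(size=(1, d))
    m.states[2].emission.probs = np.array([1.0 - r_spike, r_spike])
    return m


def make_random_mn(rng, n=2, d=2, spike_rate=0.3):
    """n-M-state model with random transitions and distinct spike means."""
    emb = StimulusEmbeddingSpec(window_length=d, channels=1)
    m = build_mn_template(n, emb, spike_rate=spike_rate)
    T = rng.dirichlet(np.ones(n + 1), size=n)
    m.transitions, m.final = T[:, :n], T[:, n]
    m.initial = rng.dirichlet(np.ones(n))
    for st in m.states:
        st.emission.conditional_stimulus[1].means = rng.normal(size=(1, d))
    return m


def make_pair(rng, Tx, Tr=None, d=2, p_spike=0.4):
    if Tr is None:
        Tr = Tx
    return StimulusResponsePair(
        stimulus=rng.normal(size=(Tx, d)),
        response=(rng.random(Tr) < p_spike).astype(int),
    )


@pytest.fixture
def random_mxr(rng):
    return make_random_mxr(rng)


@pytest.fixture
def small_pair(rng):
    return make_pair(rng, 3)
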