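"""Shared fixtures: small synthetic corpora generated at session scope."""

import numpy as np
import pytest

import charmark as cm


@pytest.fixture(scope="session")
def base_chain():
    return cm.base_chain_from_text()


@pytest.fixture(scope="session")
def space_effect_corpus():
    """Two groups whose only difference is an elevated space transition rate
    in the case group; full emulated corpus composition."""
    spec = cm.GeneratorSpec(space_shift=0.03, seed=11)
    corpus, manifest = cm.generate_corpus(spec)
    return corpus, manifest, spec


@pytest.fixture(scope="session")
def null_corpus():
    """Exchangeable null: both groups share one generator."""
    spec = cm.GeneratorSpec(
        seed=12,
        n_participants={"case": 40, "control": 40},
        n_transcripts={"case": 60, "control": 60},
        transcript_length=(300, 900),
    )
    corpus, manifest = cm.generate_corpus(spec)
    return corpus, manifest, spec


@pytest.fixture(scope="session")
def letter_effect_corpus():
    """Transition-level group effect with matched space usage."""
    spec = cm.GeneratorSpec(
        letter_shift=0.3,
        seed=13,
        n_participants={"case": 60, "control": 60},
        n_transcripts={"case": 120, "control": 120},
        transcript_length=(300, 1200),
    )
    corpus, manifest = cm.generate_corpus(spec)
    return corpus, manifest, spec


@pytest.fixture(scope="session")
def space_features(space_effect_corpus):
    corpus, _, _ = space_effect_corpus
    return cm.build_feature_matrix(corpus, alpha=0.01, order=1)


def random_stochastic(rng, k):
    """Random strictly positive row-stochastic matrix."""
    M = rng.gamma(1.0, size=(k, k)) + 1e-3
    return M / M.sum(axis=1, keepdims=True)


def stationary_by_powers(P, n_squarings=60):
    """Brute-force stationary vector: rows of P^(2^m) converge to pi."""
    Q = np.asarray(P, dtype=float)
    for _ in range(n_squarings):
        Q = Q @ Q
        Q /= Q.sum(axis=1, keepdims=True)  # fight round-off drift
    return Q.mean(axis=0) / Q.mean(axis=0).sum()
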