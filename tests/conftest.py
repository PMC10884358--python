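"""Shared fixtures: montages, prototype maps, and a small synthetic atlas."""

import numpy as np
import pytest

import msx


@pytest.fixture(scope="session")
def m19():
    return msx.standard_1020_montage()


@pytest.fixture(scope="session")
def m32():
    return msx.make_montage(32, seed=5)


@pytest.fixture(scope="session")
def m64():
    return msx.make_montage(64, seed=3)


@pytest.fixture(scope="session")
def prototypes19(m19):
    """Five decorrelated smooth prototype maps on the 10-20 montage."""
    return msx.make_prototypes(5, m19, smoothness=3, seed=0)


@pytest.fixture(scope="session")
def small_atlas():
    """Six-study atlas over mixed montages, 5 prototypes, default noise."""
    return msx.make_atlas(msx.FixtureSpec(seed=1, n_studies=6))


def orthonormal_canonical_set(n_channels: int, k: int, seed: int = 0) -> np.ndarray:
    """k mutually orthogonal canonical maps (zero-mean, unit-norm rows)."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, n_channels))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    # columns of q span the zero-mean subspace (n-1 dims) plus a residual;
    # keep only columns that are zero-mean after the QR
    cols = [q[:, i] for i in range(q.shape[1]) if abs(q[:, i].mean()) < 1e-10]
    assert len(cols) >= k
    out = np.stack(cols[:k])
    return out / np.linalg.norm(out, axis=1, keepdims=True)
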