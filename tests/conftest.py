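import numpy as np
import pytest

import growthseam as gs


@pytest.fixture
def pouch_logistic() -> gs.LogisticParams:
    """Published pouch-phase logistic pes-growth coefficients."""
    return gs.LogisticParams(A=16.06, K=93.92, L0=1.11, r=0.96)


@pytest.fixture
def male_pp_brody() -> gs.BrodyParams:
    """Published post-pouch male Brody pes-growth coefficients."""
    return gs.BrodyParams(B=154.91, C=0.567, k=0.077)


@pytest.fixture
def male_sj2p_free() -> gs.SJ2PFreeParams:
    """Published male SJ2P free-parameter row (pes length)."""
    return gs.SJ2PFreeParams(C=0.57, K=95.21, L0=1.22, k=0.078, j=7.85, r=0.78)


@pytest.fixture
def male_sj2p(male_sj2p_free) -> gs.SJ2PModel:
    return gs.derive_joined(male_sj2p_free)


@pytest.fixture
def study_ages() -> np.ndarray:
    """Two-cohort age design: pouch ages plus post-weaning cull ages (months)."""
    return np.concatenate([np.linspace(0.7, 7.4, 68), np.linspace(17.0, 80.0, 97)])


def random_valid_free(rng: np.random.Generator) -> gs.SJ2PFreeParams:
    """A random SJ2P free-parameter draw within its domain invariants."""
    K = rng.uniform(20.0, 200.0)
    return gs.SJ2PFreeParams(
        C=rng.uniform(0.05, 0.95),
        K=K,
        L0=rng.uniform(0.01, 0.5) * K,
        k=rng.uniform(0.01, 0.5),
        j=rng.uniform(1.0, 20.0),
        r=rng.uniform(0.1, 2.0),
    )
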