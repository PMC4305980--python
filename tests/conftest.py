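import numpy as np
import pytest

from ringosc.model import OscillatorParams


@pytest.fixture
def ring3():
    """The reference 3-loop: alpha = beta = 1, K = 0.5 (rho = 0.5)."""
    return OscillatorParams(alpha=[1, 1, 1], beta=[1, 1, 1], K=[0.5, 0.5, 0.5])


@pytest.fixture
def uniform_ring():
    """Factory for uniform symmetric loops with unit ceiling and given rho."""

    def make(n: int, rho: float = 0.5, alpha: float = 1.0) -> OscillatorParams:
        return OscillatorParams(
            alpha=np.full(n, alpha),
            beta=np.full(n, alpha),
            K=np.full(n, rho),
        )

    return make


def params_with_rho(alpha, rho, beta=None):
    """Params with prescribed decay rates and threshold ratios."""
    alpha = np.asarray(alpha, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), alpha.shape)
    beta = np.ones_like(alpha) if beta is None else np.asarray(beta, dtype=float)
    return OscillatorParams(alpha=alpha, beta=beta, K=rho * beta / alpha)
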