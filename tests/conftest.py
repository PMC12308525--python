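import numpy as np
import pytest

from guilt_egt import GameParams, closed_form_payoffs, cooperation_matrix


@pytest.fixture(scope="session")
def canonical_params() -> GameParams:
    """The payoff set used throughout the analytics: T=2, R=1, P=0, S=-1."""
    return GameParams(T=2.0, R=1.0, P=0.0, S=-1.0, omega=10, gamma=1.0, gamma_s=0.1)


@pytest.fixture(scope="session")
def canonical_matrix(canonical_params):
    return closed_form_payoffs(canonical_params)


@pytest.fixture(scope="session")
def canonical_coop(canonical_params):
    return cooperation_matrix(canonical_params)


def random_valid_params(rng: np.random.Generator) -> GameParams:
    """Draw parameters satisfying T > R > P > S and 2R > T + S."""
    while True:
        vals = np.sort(rng.uniform(-5, 5, size=4))[::-1]
        T, R, P, S = vals
        if T > R > P > S and 2 * R > T + S:
            break
    return GameParams(
        T=float(T),
        R=float(R),
        P=float(P),
        S=float(S),
        omega=int(rng.integers(1, 16)),
        gamma=float(rng.uniform(0, 3)),
        gamma_s=float(rng.uniform(0, 3)),
    )
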