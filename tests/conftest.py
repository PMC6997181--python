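import numpy as np
import pytest

import mirloop as ml


@pytest.fixture(scope="session")
def default_network():
    return ml.build_default_network()


@pytest.fixture(scope="session")
def default_responses(default_network):
    """Normalized responses of every builtin genotype under shipped defaults
    (50-lifetime horizon, unit step stimulus)."""
    return ml.simulate_genotypes(default_network, ml.builtin_genotypes(),
                                 horizon=50.0)


@pytest.fixture(scope="session")
def default_metrics(default_responses):
    return ml.response_metrics_table(default_responses).set_index("genotype")


def hand_rhs(p, y, u, extra=0.0):
    """Literal, term-by-term assembly of the eight governing equations,
    independent of the reaction-network machinery."""
    R, P, V, A, St, Sp, K, M = y
    return np.array([
        p.k_R + p.a_R * V - p.d_R * R - p.k_rep * M * R,
        p.k_P * R - p.d_P * P,
        p.k_V * u * P - p.k_leak * V - p.g_K * K * (1 + p.alpha * Sp) * V + extra,
        p.k_Aon * V * (1 - A) - p.k_Aoff * A,
        p.a_S * A - p.d_St * St,
        p.k_Sp * St - p.d_Sp * Sp,
        p.a_K * A - p.d_K * K,
        p.eta * p.a_S * A - p.d_M * M,
    ])
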