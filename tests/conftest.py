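"""Shared fixtures.

The expensive benchmark fit is session-scoped: one MCMC run on the scaled
metabolic stand-in feeds every validation-level test.
"""

import warnings

import numpy as np
import pytest

import tdbscore as t
from tdbscore.synthetic import metabolic_benchmark


@pytest.fixture
def toy_net():
    """3 metabolites, 2 reactions, 4 edges: the smallest worked example."""
    return t.BipartiteNetwork.from_edges(
        [("m1", "r1"), ("m2", "r1"), ("m2", "r2"), ("m3", "r2")]
    )


@pytest.fixture
def path_net_2x2():
    """Path m1-r1-m2-r2: 4 leaves, 15 dendrograms, fully enumerable."""
    return t.BipartiteNetwork.from_edges(
        [("m1", "r1"), ("m2", "r1"), ("m2", "r2")]
    )


@pytest.fixture
def path_net_3x2():
    """Path m0-r0-m1-r1-m2: 5 leaves, 105 dendrograms."""
    return t.BipartiteNetwork.from_edges(
        [("m0", "r0"), ("m1", "r0"), ("m1", "r1"), ("m2", "r1")]
    )


@pytest.fixture
def complete_net():
    return t.BipartiteNetwork.from_edges(
        [(m, r) for m in ("a", "b", "c") for r in ("x", "y")]
    )


@pytest.fixture(scope="session")
def benchmark():
    """Scaled metabolic benchmark network with its planted big reaction."""
    net, P, big_id = metabolic_benchmark(seed=1)
    return net, P, big_id


@pytest.fixture(scope="session")
def benchmark_fit(benchmark):
    """One equilibrated MCMC fit of the benchmark, shared across tests."""
    net, _, _ = benchmark
    cfg = t.McmcConfig(
        burn_in=2_000_000,
        num_samples=500,
        sample_interval=net.M + net.R,
        seed=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", t.NonEquilibratedWarning)
        pairs, trace = t.fit(net, cfg)
    return pairs, trace
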