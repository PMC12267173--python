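"""Shared fixtures.

The full-scale (100-neuron, 300 ms) reference runs are expensive, so they
are session-scoped and computed lazily: only tests that request them pay
for them, and every test sees the identical deterministic result.
"""

from __future__ import annotations

import pytest

import hhnet as H


def _full_scale(kind: str, topology: str, seed: int | None = None):
    directed = kind != "ES"
    if topology == "ring":
        graph = H.build_ring(100, directed=directed)
    else:
        graph = H.build_nw_hub(100, directed=directed)
    waveform = "sine" if seed is None else "sine_plus_noise"
    stimulus = H.StimulusSpec(waveform=waveform, seed=seed)
    return H.simulate(graph, H.SynapseSpec(kind=kind, g=0.1), stimulus)


@pytest.fixture(scope="session")
def es_ring_result():
    return _full_scale("ES", "ring")


@pytest.fixture(scope="session")
def hs_ring_result():
    return _full_scale("HS", "ring")


@pytest.fixture(scope="session")
def rs_ring_result():
    return _full_scale("RS", "ring")


@pytest.fixture(scope="session")
def es_nw_result():
    return _full_scale("ES", "nw")


@pytest.fixture(scope="session")
def hs_nw_result():
    return _full_scale("HS", "nw")


@pytest.fixture(scope="session")
def rs_nw_result():
    return _full_scale("RS", "nw")


@pytest.fixture(scope="session")
def rs_ring_noise_results():
    """RS ring with sine + Gaussian interference, ten replicate noise seeds."""
    return [_full_scale("RS", "ring", seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def small_rs_ring_result():
    """10-neuron RS ring, 150 ms: fast run used by propagation/metrics tests."""
    graph = H.build_ring(10, directed=True)
    return H.simulate(
        graph, H.SynapseSpec(kind="RS", g=0.1), H.StimulusSpec(),
        sim=H.SimConfig(t_total=150.0),
    )
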