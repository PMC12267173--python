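"""Fixed-step integration of the coupled (delay-)differential network.

Every neuron follows the Hodgkin-Huxley equations; neuron ``stimulated_node``
additionally receives the external stimulus, and every neuron receives the
sum of its afferent synaptic currents.  Chemical synapses read the
presynaptic potential ``tau`` ms in the past, which makes the system a delay
differential equation: it is integrated by the method of steps on a fixed
grid, with the delayed Heaviside gates (and the noise sample) frozen over
each step while the smooth terms are advanced with classical RK4 (or
forward Euler).  Gap-junction currents couple the live stage voltages, so
the electrically coupled system is integrated as one smooth ODE.

Initial conditions are the common resting state (V = -65 mV, gating at the
standard resting triple) for every neuron, and delay buffers are pre-filled
with the resting potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .neuron import HHParams, NeuronState
from .stimulus import StimulusSpec, Waveform, render_noise
from .synapses import ConfigurationError, SynapseKind, SynapseSpec
from .topology import NetworkGraph

__all__ = [
    "SimConfig",
    "SimulationResult",
    "DivergenceError",
    "simulate",
    "step_network",
    "network_derivatives",
]

#: Hard |V| bound (mV); beyond this the run is aborted as divergent.
DIVERGENCE_LIMIT = 150.0


class DivergenceError(RuntimeError):
    def __init__(self, neuron: int, time: float, value: float):
        self.neuron, self.time, self.value = neuron, time, value
        super().__init__(
            f"integration diverged: neuron {neuron} reached V={value:.1f} mV at t={time:.3f} ms"
        )


@dataclass(frozen=True)
class SimConfig:
    """Integration settings: step (ms), duration (ms), scheme, recording stride."""

    dt: float = 0.01
    t_total: float = 300.0
    integrator: str = "rk4"
    record_stride: int = 1
    record_gating: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.t_total < self.dt:
            raise ConfigurationError("t_total must be at least one step")
        if self.integrator not in ("rk4", "euler"):
            raise ConfigurationError(f"unknown integrator {self.integrator!r}")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


@dataclass
class SimulationResult:
    """Recorded traces and bookkeeping for one network run.

    ``v`` has shape (N, samples) with rows ordered by neuron number 1..N;
    ``spike_times[i]`` are the threshold-crossing times of neuron i+1.
    ``gating_min``/``gating_max`` hold per-neuron extrema of (m, h, n) over
    the *entire* integration (not just recorded samples).
    """

    t: np.ndarray
    v: np.ndarray
    spike_times: list[np.ndarray]
    gating_min: np.ndarray
    gating_max: np.ndarray
    metadata: dict = field(default_factory=dict)
    m: np.ndarray | None = None
    h: np.ndarray | None = None
    n_gate: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]

    def trace(self, neuron: int) -> np.ndarray:
        """Voltage trace of 1-based ``neuron``."""
        return self.v[neuron - 1]

    def first_spike(self, neuron: int) -> float:
        """First spike time (ms) of 1-based ``neuron``; NaN if silent."""
        st = self.spike_times[neuron - 1]
        return float(st[0]) if st.size else float("nan")


# ---------------------------------------------------------------------------
# derivative field


def _gating_rates(v: np.ndarray):
    """Vectorised alpha/beta for m, h, n (duplicated from neuron.rate_constants
    for the hot loop; the unit tests pin the two code paths together)."""
    x_m = v + 40.0
    x_n = v + 55.0
    safe_m = np.where(np.abs(x_m) < 1e-7, 1.0, x_m)
    safe_n = np.where(np.abs(x_n) < 1e-7, 1.0, x_n)
    a_m = 0.1 * np.where(np.abs(x_m) < 1e-7, 10.0, safe_m / (-np.expm1(-safe_m / 10.0)))
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)
    a_n = 0.01 * np.where(np.abs(x_n) < 1e-7, 10.0, safe_n / (-np.expm1(-safe_n / 10.0)))
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


class _Coupling:
    """Precompiled coupling terms for one (graph, synapse) pair."""

    def __init__(self, graph: NetworkGraph, synapse: SynapseSpec):
        self.synapse = synapse
        self.n = graph.n
        src, tgt = graph.edge_arrays()
        self.src, self.tgt = src, tgt
        if synapse.kind is SynapseKind.ES:
            if any(e.directed for e in graph.edges):
                raise ConfigurationError(
                    "electrical synapses are bidirectional: use an undirected graph"
                )
            self.degree = np.bincount(tgt, minlength=self.n).astype(float)
        else:
            if any(not e.directed for e in graph.edges):
                raise ConfigurationError(
                    "chemical synapses are unidirectional: use a directed graph"
                )

    def gate_counts(self, v_delayed: np.ndarray) -> np.ndarray:
        """Number of afferent synapses per neuron whose delayed presynaptic
        potential strictly exceeds threshold (frozen once per step)."""
        gate = (v_delayed[self.src] > self.synapse.v_thresh).astype(float)
        return np.bincount(self.tgt, weights=gate, minlength=self.n)

    def electrical(self, v: np.ndarray) -> np.ndarray:
        """Gap-junction current at live voltages: g * sum_j (V_j - V_i)."""
        return self.synapse.g * (
            np.bincount(self.tgt, weights=v[self.src], minlength=self.n)
            - self.degree * v
        )


def network_derivatives(
    v: np.ndarray,
    m: np.ndarray,
    h: np.ndarray,
    n: np.ndarray,
    i_inject: np.ndarray,
    params: HHParams,
    coupling: _Coupling | None = None,
    gate_counts: np.ndarray | None = None,
):
    """RHS for all neurons at once.

    ``i_inject`` collects the per-neuron currents that are frozen over the
    step (external stimulus + noise on the stimulated node, Hansel synaptic
    current); voltage-dependent coupling (gap junctions, the Rabinovich
    driving force) is evaluated at the live stage voltages.
    """
    i_total = i_inject
    if coupling is not None:
        syn = coupling.synapse
        if syn.kind is SynapseKind.ES:
            i_total = i_total + coupling.electrical(v)
        elif syn.kind is SynapseKind.RS:
            drive = (v - syn.v_rev) if syn.rs_sign_literal else (syn.v_rev - v)
            i_total = i_total + syn.g * gate_counts * drive
    a_m, b_m, a_h, b_h, a_n, b_n = _gating_rates(v)
    i_ion = (
        params.g_na * m**3 * h * (params.e_na - v)
        + params.g_k * n**4 * (params.e_k - v)
        + params.g_l * (params.e_l - v)
    )
    dv = (i_ion + i_total) / params.c
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dn = a_n * (1.0 - n) - b_n * n
    return dv, dm, dh, dn


DerivFn = Callable[[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray], tuple]


def step_network(
    v: np.ndarray,
    m: np.ndarray,
    h: np.ndarray,
    n: np.ndarray,
    t: float,
    dt: float,
    deriv: DerivFn,
    method: str = "rk4",
):
    """Advance all neurons by one step of RK4 or forward Euler.

    ``deriv(t, v, m, h, n)`` returns the four derivative arrays; any delayed
    or sampled quantity must already be frozen inside it (method of steps).
    """
    if method == "euler":
        dv, dm, dh, dn = deriv(t, v, m, h, n)
        return v + dt * dv, m + dt * dm, h + dt * dh, n + dt * dn
    if method != "rk4":
        raise ConfigurationError(f"unknown integrator {method!r}")
    k1 = deriv(t, v, m, h, n)
    half = 0.5 * dt
    k2 = deriv(t + half, v + half * k1[0], m + half * k1[1], h + half * k1[2], n + half * k1[3])
    k3 = deriv(t + half, v + half * k2[0], m + half * k2[1], h + half * k2[2], n + half * k2[3])
    k4 = deriv(t + dt, v + dt * k3[0], m + dt * k3[1], h + dt * k3[2], n + dt * k3[3])
    sixth = dt / 6.0
    return (
        v + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        m + sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        h + sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        n + sixth * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
    )


# ---------------------------------------------------------------------------
# full simulation


def simulate(
    graph: NetworkGraph,
    synapse: SynapseSpec | None,
    stimulus: StimulusSpec,
    hh: HHParams | None = None,
    sim: SimConfig | None = None,
    initial_state: NeuronState | None = None,
    spike_threshold: float = 0.0,
    spike_refractory: float = 2.0,
) -> SimulationResult:
    """Integrate the network and return recorded traces plus spike times.

    ``synapse=None`` (or g=0) runs uncoupled neurons.  The stimulus is
    injected only into ``graph.stimulated_node``; its smooth part is
    evaluated at the RK4 stage times while noise and delayed chemical gates
    are held constant within each step.  Deterministic for a fixed
    ``stimulus.seed``.
    """
    from .metrics import detect_spikes  # deferred: metrics imports nothing from here

    hh = hh or HHParams()
    sim = sim or SimConfig()
    init = initial_state or NeuronState()
    init.validate()

    n_net = graph.n
    steps = sim.n_steps
    dt = sim.dt
    t_grid = np.arange(steps + 1) * dt

    coupling = _Coupling(graph, synapse) if (synapse is not None and synapse.g > 0) else None
    chemical = coupling is not None and coupling.synapse.is_chemical
    if chemical:
        lag_float = coupling.synapse.tau / dt
        lag_int = int(np.floor(lag_float + 1e-9))
        lag_frac = lag_float - lag_int
        if lag_frac < 1e-9:
            lag_frac = 0.0

    stim_idx = graph.stimulated_node - 1
    det_t = stimulus.deterministic_part(t_grid)  # stage values at grid points
    det_mid = stimulus.deterministic_part(t_grid[:-1] + 0.5 * dt)
    if stimulus.waveform is Waveform.SINE_PLUS_NOISE:
        noise = render_noise(stimulus, t_grid[:-1])
    else:
        noise = np.zeros(steps)

    v = np.full(n_net, init.v)
    m = np.full(n_net, init.m)
    h = np.full(n_net, init.h)
    n = np.full(n_net, init.n)

    hist = np.empty((steps + 1, n_net))
    hist[0] = v
    v_init_vec = np.full(n_net, init.v)
    record_gating = sim.record_gating
    if record_gating:
        m_rec = np.empty((steps + 1, n_net))
        h_rec = np.empty((steps + 1, n_net))
        n_rec = np.empty((steps + 1, n_net))
        m_rec[0], h_rec[0], n_rec[0] = m, h, n
    g_min = np.stack([m, h, n], axis=1).copy()
    g_max = g_min.copy()

    method = sim.integrator
    euler = method == "euler"
    half = 0.5 * dt
    sixth = dt / 6.0
    for s in range(steps):
        t = t_grid[s]
        # frozen-per-step quantities (method of steps)
        if chemical:
            back = s - lag_int
            v_del = hist[back] if back >= 0 else v_init_vec
            if lag_frac > 0.0:
                older = hist[back - 1] if back - 1 >= 0 else v_init_vec
                v_del = (1.0 - lag_frac) * v_del + lag_frac * older
            gates = coupling.gate_counts(v_del)
            i_chem = coupling.synapse.g * gates if coupling.synapse.kind is SynapseKind.HS else None
        else:
            gates = None
            i_chem = None

        # per-stage injected currents: smooth stimulus at the stage times,
        # noise and chemical gates frozen over the step
        i_start = np.zeros(n_net)
        i_start[stim_idx] = det_t[s] + noise[s]
        if i_chem is not None:
            i_start += i_chem
        if euler:
            dv, dm, dh, dn = network_derivatives(v, m, h, n, i_start, hh, coupling, gates)
            v = v + dt * dv
            m = m + dt * dm
            h = h + dt * dh
            n = n + dt * dn
        else:
            i_mid = i_start.copy()
            i_mid[stim_idx] += det_mid[s] - det_t[s]
            i_end = i_start.copy()
            i_end[stim_idx] += det_t[s + 1] - det_t[s]
            k1 = network_derivatives(v, m, h, n, i_start, hh, coupling, gates)
            k2 = network_derivatives(
                v + half * k1[0], m + half * k1[1], h + half * k1[2], n + half * k1[3],
                i_mid, hh, coupling, gates,
            )
            k3 = network_derivatives(
                v + half * k2[0], m + half * k2[1], h + half * k2[2], n + half * k2[3],
                i_mid, hh, coupling, gates,
            )
            k4 = network_derivatives(
                v + dt * k3[0], m + dt * k3[1], h + dt * k3[2], n + dt * k3[3],
                i_end, hh, coupling, gates,
            )
            v = v + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            m = m + sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            h = h + sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            n = n + sixth * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])

        vmax = np.max(np.abs(v))
        if not np.isfinite(vmax) or vmax > DIVERGENCE_LIMIT:
            bad = int(np.argmax(np.where(np.isfinite(v), np.abs(v), np.inf)))
            raise DivergenceError(bad + 1, float(t_grid[s + 1]), float(v[bad]))

        hist[s + 1] = v
        if record_gating:
            m_rec[s + 1], h_rec[s + 1], n_rec[s + 1] = m, h, n
        np.minimum(g_min[:, 0], m, out=g_min[:, 0])
        np.minimum(g_min[:, 1], h, out=g_min[:, 1])
        np.minimum(g_min[:, 2], n, out=g_min[:, 2])
        np.maximum(g_max[:, 0], m, out=g_max[:, 0])
        np.maximum(g_max[:, 1], h, out=g_max[:, 1])
        np.maximum(g_max[:, 2], n, out=g_max[:, 2])

    stride = sim.record_stride
    v_out = hist[::stride].T.copy()
    t_out = t_grid[::stride]
    spikes = [
        detect_spikes(v_out[i], t_out[1] - t_out[0] if len(t_out) > 1 else dt,
                      threshold=spike_threshold, refractory=spike_refractory)
        for i in range(n_net)
    ]
    meta = {
        "n_neurons": n_net,
        "dt": dt,
        "t_total": sim.t_total,
        "integrator": method,
        "stimulated_node": graph.stimulated_node,
        "topology_hash": graph.topology_hash(),
        "synapse": None if synapse is None else {
            "kind": synapse.kind.value, "g": synapse.g, "v_thresh": synapse.v_thresh,
            "tau": synapse.tau, "v_rev": synapse.v_rev,
        },
        "stimulus": {
            "waveform": stimulus.waveform.value,
            "seed": stimulus.seed,
            "noise_std": stimulus.noise_std,
        },
        "spike_threshold": spike_threshold,
        "spike_refractory": spike_refractory,
    }
    result = SimulationResult(
        t=t_out, v=v_out, spike_times=spikes,
        gating_min=g_min, gating_max=g_max, metadata=meta,
    )
    if record_gating:
        result.m = m_rec[::stride].T.copy()
        result.h = h_rec[::stride].T.copy()
        result.n_gate = n_rec[::stride].T.copy()
    return result
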