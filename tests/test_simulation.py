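"""Network integration: correctness, invariants, and the stepping oracle checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import hhnet as H
from hhnet.neuron import HHParams, rate_constants
from hhnet.simulation import DivergenceError, _Coupling, network_derivatives, step_network
from hhnet.synapses import ConfigurationError, SynapseKind


def small_sim(t_total=50.0, **kw):
    return H.SimConfig(t_total=t_total, **kw)


class TestSingleNeuron:
    def test_matches_reference_ode_solver(self):
        """Uncoupled stimulated neuron vs scipy solve_ivp at tight tolerance."""
        p = HHParams()

        def rhs(t, y):
            v, m, h, n = y
            r = rate_constants(v)
            i_ext = 60.0 * np.sin(0.1 * np.pi * t) + 30.0
            dv = (
                p.g_na * m**3 * h * (p.e_na - v)
                + p.g_k * n**4 * (p.e_k - v)
                + p.g_l * (p.e_l - v)
                + i_ext
            ) / p.c
            return [
                dv,
                r.alpha_m * (1 - m) - r.beta_m * m,
                r.alpha_h * (1 - h) - r.beta_h * h,
                r.alpha_n * (1 - n) - r.beta_n * n,
            ]

        res = H.simulate(
            H.build_ring(2, directed=True),
            H.SynapseSpec(kind="HS", g=0.0),
            H.StimulusSpec(),
            sim=small_sim(50.0),
        )
        sol = solve_ivp(
            rhs, (0, 50.0), [-65.0, 0.05293, 0.5961, 0.3177],
            rtol=1e-10, atol=1e-12, dense_output=True, max_step=0.5,
        )
        assert np.abs(sol.sol(res.t)[0] - res.trace(1)).max() < 5e-3

    def test_square_wave_fires_every_on_phase(self):
        """At least one suprathreshold action potential per 20 ms stimulus period."""
        res = H.simulate(
            H.build_ring(2, directed=True),
            H.SynapseSpec(kind="HS", g=0.0),
            H.StimulusSpec(waveform="square"),
            sim=small_sim(100.0),
        )
        spikes = res.spike_times[0]
        assert res.trace(1).max() > 0.0
        for k in range(5):
            assert np.any((spikes >= 20 * k) & (spikes < 20 * (k + 1)))


class TestStepNetwork:
    p = HHParams()

    def deriv_uncoupled(self, t, v, m, h, n):
        return network_derivatives(v, m, h, n, np.zeros_like(v), self.p)

    def test_near_fixed_point_barely_moves(self):
        st = H.resting_state(-65.0)
        v = np.full(3, st.v); m = np.full(3, st.m); h = np.full(3, st.h); n = np.full(3, st.n)
        v2, m2, h2, n2 = step_network(v, m, h, n, 0.0, 0.01, self.deriv_uncoupled)
        for a, b in [(v, v2), (m, m2), (h, h2), (n, n2)]:
            assert np.abs(b - a).max() < 1e-3

    def test_rk4_vs_four_euler_substeps_second_order(self):
        """The Euler-substep composite approaches the RK4 step at O(dt^2)."""

        def gap(dt):
            v = np.array([-55.0]); m = np.array([0.2]); h = np.array([0.5]); n = np.array([0.35])
            rk = step_network(v, m, h, n, 0.0, dt, self.deriv_uncoupled, "rk4")
            eu = (v, m, h, n)
            for i in range(4):
                eu = step_network(*eu, i * dt / 4, dt / 4, self.deriv_uncoupled, "euler")
            return max(np.abs(a - b).max() for a, b in zip(rk, eu))

        d1, d2 = gap(0.01), gap(0.005)
        assert d1 < 100 * 0.01**2
        assert d1 / d2 == pytest.approx(4.0, rel=0.3)  # halving dt quarters the gap

    def test_unknown_method_rejected(self):
        v = np.zeros(1)
        with pytest.raises(ConfigurationError):
            step_network(v, v, v, v, 0.0, 0.01, self.deriv_uncoupled, "leapfrog")


class TestConvergence:
    def test_step_halving_single_neuron(self):
        """RK4 at dt=0.01 vs dt=0.005: recorded voltages agree within 0.5 mV."""
        graph = H.build_ring(2, directed=True)
        syn = H.SynapseSpec(kind="HS", g=0.0)
        stim = H.StimulusSpec()
        a = H.simulate(graph, syn, stim, sim=small_sim(100.0, dt=0.01))
        b = H.simulate(graph, syn, stim, sim=small_sim(100.0, dt=0.005, record_stride=2))
        assert a.t.shape == b.t.shape
        assert np.abs(a.trace(1) - b.trace(1)).max() < 0.5

    def test_step_halving_electrically_coupled_network(self):
        """The smooth gap-junction ODE keeps 4th-order convergence network-wide."""
        graph = H.build_ring(10, directed=False)
        syn = H.SynapseSpec(kind="ES", g=0.1)
        stim = H.StimulusSpec()
        a = H.simulate(graph, syn, stim, sim=small_sim(100.0, dt=0.01))
        b = H.simulate(graph, syn, stim, sim=small_sim(100.0, dt=0.005, record_stride=2))
        assert np.abs(a.v - b.v).max() < 0.5


class TestCouplingSemantics:
    def test_zero_coupling_quiescence(self):
        """With g=0 only the stimulated neuron leaves rest."""
        res = H.simulate(
            H.build_ring(6, directed=True),
            H.SynapseSpec(kind="RS", g=0.0),
            H.StimulusSpec(),
            sim=small_sim(100.0),
        )
        assert res.spike_times[0].size > 0
        for i in range(2, 7):
            assert np.abs(res.trace(i) + 65.0).max() < 1.0

    def test_incompatible_graph_and_synapse_rejected(self):
        with pytest.raises(ConfigurationError):
            H.simulate(
                H.build_ring(4, directed=True),
                H.SynapseSpec(kind="ES", g=0.1),
                H.StimulusSpec(),
                sim=small_sim(1.0),
            )
        with pytest.raises(ConfigurationError):
            H.simulate(
                H.build_ring(4, directed=False),
                H.SynapseSpec(kind="HS", g=0.1),
                H.StimulusSpec(),
                sim=small_sim(1.0),
            )

    @pytest.mark.parametrize("kind, g", [("HS", 10.0), ("RS", 0.1)])
    def test_tau_zero_matches_instantaneous_coupling_oracle(self, kind, g):
        """simulate() with tau=0 must equal an in-test integrator that reads
        the live presynaptic voltage for the Heaviside gate."""
        n_net = 4
        graph = H.build_ring(n_net, directed=True)
        syn = H.SynapseSpec(kind=kind, g=g, tau=0.0)
        stim = H.StimulusSpec()
        sim = small_sim(40.0)
        res = H.simulate(graph, syn, stim, sim=sim)

        coupling = _Coupling(graph, syn)
        p = HHParams()
        v = np.full(n_net, -65.0)
        m = np.full(n_net, 0.05293); h = np.full(n_net, 0.5961); n = np.full(n_net, 0.3177)
        dt = sim.dt
        trace = [v.copy()]
        for s in range(sim.n_steps):
            t = s * dt
            gates = coupling.gate_counts(v)  # live voltage, no delay

            def deriv(tt, vv, mm, hh, nn):
                i = np.zeros(n_net)
                i[0] = 60.0 * np.sin(0.1 * np.pi * tt) + 30.0
                if kind == "HS":
                    i = i + g * gates
                return network_derivatives(vv, mm, hh, nn, i, p, coupling, gates)

            v, m, h, n = step_network(v, m, h, n, t, dt, deriv)
            trace.append(v.copy())
        oracle = np.asarray(trace).T
        np.testing.assert_allclose(res.v, oracle, atol=1e-9)

    def test_symmetric_electrical_pair_stays_synchronous(self):
        """Two identically stimulated gap-junction-coupled neurons never diverge."""
        p = HHParams()
        g = 0.1
        v = np.full(2, -65.0)
        m = np.full(2, 0.05293); h = np.full(2, 0.5961); n = np.full(2, 0.3177)
        dt = 0.01
        worst = 0.0
        for s in range(5000):  # 50 ms
            t = s * dt

            def deriv(tt, vv, mm, hh, nn):
                i = np.full(2, 60.0 * np.sin(0.1 * np.pi * tt) + 30.0)
                i[0] += H.electrical_current(vv[1], vv[0], g)
                i[1] += H.electrical_current(vv[0], vv[1], g)
                return network_derivatives(vv, mm, hh, nn, i, p)

            v, m, h, n = step_network(v, m, h, n, t, dt, deriv)
            worst = max(worst, abs(v[0] - v[1]))
        assert worst < 1e-6

    def test_electrical_current_conservation_on_recorded_run(self, es_ring_result):
        """Summed gap-junction current over the whole network is zero at every sample."""
        graph = H.build_ring(100, directed=False)
        coupling = _Coupling(graph, H.SynapseSpec(kind="ES", g=0.1))
        v = es_ring_result.v
        worst = max(abs(coupling.electrical(v[:, k]).sum()) for k in range(0, v.shape[1], 371))
        assert worst < 1e-9


class TestResultContract:
    def test_gating_stays_in_unit_interval(self, small_rs_ring_result):
        res = small_rs_ring_result
        assert res.gating_min.min() >= 0.0
        assert res.gating_max.max() <= 1.0

    def test_propagation_monotone_on_directed_ring(self, small_rs_ring_result):
        lat = H.first_spike_latency(small_rs_ring_result)
        fired = lat.latency[~np.isnan(lat.latency)]
        assert fired.size >= 5  # the wave reaches at least half the small ring
        assert np.all(np.diff(fired) >= 0)

    def test_deterministic_rerun_bit_identical(self):
        graph = H.build_ring(5, directed=True)
        syn = H.SynapseSpec(kind="RS", g=0.1)
        a = H.simulate(graph, syn, H.StimulusSpec(), sim=small_sim(30.0))
        b = H.simulate(graph, syn, H.StimulusSpec(), sim=small_sim(30.0))
        np.testing.assert_array_equal(a.v, b.v)

    def test_noise_seeds_distinguish_replicates(self):
        graph = H.build_ring(3, directed=True)
        syn = H.SynapseSpec(kind="RS", g=0.1)
        a = H.simulate(graph, syn, H.StimulusSpec(waveform="sine_plus_noise", seed=0), sim=small_sim(30.0))
        b = H.simulate(graph, syn, H.StimulusSpec(waveform="sine_plus_noise", seed=1), sim=small_sim(30.0))
        assert not np.array_equal(a.v, b.v)

    def test_record_stride_downsamples(self):
        res = H.simulate(
            H.build_ring(3, directed=True),
            H.SynapseSpec(kind="RS", g=0.1),
            H.StimulusSpec(),
            sim=small_sim(30.0, record_stride=10),
        )
        assert res.t[1] - res.t[0] == pytest.approx(0.1)
        assert res.v.shape == (3, 301)

    def test_gating_traces_recorded_on_request(self):
        res = H.simulate(
            H.build_ring(3, directed=True),
            H.SynapseSpec(kind="RS", g=0.1),
            H.StimulusSpec(),
            sim=small_sim(20.0, record_gating=True),
        )
        assert res.m.shape == res.v.shape
        assert res.m.min() >= 0.0 and res.m.max() <= 1.0

    def test_divergence_raises_named_error(self):
        with pytest.raises(DivergenceError) as err:
            H.simulate(
                H.build_ring(3, directed=True),
                H.SynapseSpec(kind="RS", g=0.1),
                H.StimulusSpec(amplitude=1e7),
                sim=small_sim(5.0),
            )
        assert err.value.neuron == 1
        assert err.value.time > 0.0

    def test_metadata_identifies_run(self, small_rs_ring_result):
        meta = small_rs_ring_result.metadata
        assert meta["synapse"]["kind"] == "RS"
        assert meta["stimulated_node"] == 1
        assert len(meta["topology_hash"]) == 12
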