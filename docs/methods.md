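# Methods

## Model

Every neuron is a single-compartment Hodgkin–Huxley membrane: potential `V`
(mV) plus gating variables `m, h, n` in [0, 1] with voltage-dependent rates
α, β (1/ms). The rate set is the canonical squid-axon parameterisation;
the removable 0/0 singularities of α_m (V = −40 mV) and α_n (V = −55 mV)
are evaluated by their analytic limits whenever |V − V_sing| < 10⁻⁷ mV, and
β_h is the sigmoid `1/(exp(−(V+35)/10) + 1)`. With these rates the
voltage-clamp steady state at −65 mV is (m, h, n) =
(0.05293, 0.5961, 0.3177), which is also the initial state of every neuron.

Parameter defaults (all overridable through `ExperimentConfig` / YAML):

| parameter | symbol | default | unit | note |
|---|---|---|---|---|
| membrane capacitance | C | 1 | µF/cm² | |
| Na / K / leak conductance | G_Na, G_K, G_L | 120, 36, 0.3 | mS/cm² | G_K = 36 is the value consistent with the resting triple above; a tenfold larger G_K makes the membrane inexcitable, so configs requesting ≥ 360 load with a warning |
| reversal potentials | E_Na, E_K, E_L | 50, −77, −54.5 | mV | |
| coupling strength | g / G_syn | 0.1 | mS/cm² (ES, RS); µA/cm² (HS) | the network-study value |
| synaptic threshold | V_thresh | −52 | mV | chemical models |
| transmission delay | τ | 1.0 | ms | chemical models; no biologically fixed value exists for this abstraction, so a round 1 ms was chosen and exposed — see *Limitations* for how results depend on it |
| synaptic reversal | V_rev | 0 | mV | RS only |
| integration step / duration | dt, T | 0.01, 300 | ms | two-neuron validation uses T = 100 ms |

### Coupling models

* **Electrical synapse (gap junction)**: `I = g (V_pre − V_post)` on
  undirected edges; the two endpoint currents cancel exactly, so total
  gap-junction current over the network is zero at machine precision.
* **Hansel synapse**: `I = G · H(V_pre(t−τ) − V_thresh)` on directed edges —
  a two-valued current, 0 or G.
* **Rabinovich synapse**: `I = G (V_rev − V_post) · H(V_pre(t−τ) − V_thresh)`.
  The Heaviside gate scales a driving force toward V_rev = 0 mV, i.e. an
  excitatory conductance-like drive that self-limits as the target
  depolarises — the feedback that damps noise-driven fluctuations. The
  sign convention is deliberate: the opposite ("literal") sign
  `G (V_post − V_rev) H(·)` hyperpolarises the target away from a 0 mV
  reversal and cannot propagate activity; it remains available via
  `rs_sign_literal=True` for comparison.

H(0) := 0 — the threshold must be strictly exceeded; the tie has measure
zero on trajectories. A neuron with several afferents receives the
algebraic sum of their currents. Chemical synapses are strictly
unidirectional (pre → post); electrical coupling is bidirectional.

### Topologies

`build_ring(N)` is the 1→2→…→N→1 ring (undirected for gap junctions).
`build_nw_hub(N, hub=1, k=24)` adds k shortcuts from the stimulated hub to
evenly spaced non-adjacent nodes — 5, 9, …, 97 for the reference network.
The even spacing is a deterministic, reproducible stand-in for an
unspecified hand-drawn shortcut set; an explicit target list and a seeded
probabilistic Newman–Watts construction (`build_nw_random`, ring plus each
non-ring pair with probability p) are also provided. Note that neurons 25
and 45 of the correlation pairs are themselves hub targets under the
default spacing, which materially shapes the small-world correlation table.

### Stimuli

All inputs are synthesised; no external data exists. Only neuron 1 is
stimulated. The square wave is 10 µA/cm² during the first half of each
20 ms period; the sine is `60 sin(0.1πt) + 30` µA/cm² (period 20 ms); the
interference condition superimposes zero-mean Gaussian noise with
σ = 20 µA/cm². Noise is treated as a *sampled signal*: one draw per
`noise_sample_dt` (default = dt) held piecewise-constant, with no 1/√dt
diffusion scaling — changing dt therefore changes the effective noise
bandwidth, which is why `noise_sample_dt` is exposed separately. All
randomness flows through a single seed per run.

## Integration

Fixed-step classical RK4 (forward Euler available for cross-checks) on a
0.01 ms grid, by the method of steps: within one step the delayed Heaviside
gates and the noise sample are frozen, while the gap-junction and RS
driving-force terms and the smooth stimulus are evaluated at the RK4 stage
times. Delay lookups linearly interpolate the stored voltage history when
τ is not a grid multiple, and return the −65 mV prehistory for t < τ.
Divergence (|V| > 150 mV or non-finite state) aborts with the offending
neuron and time rather than emitting NaNs. Convergence was verified by
step-halving (recorded voltages move < 0.5 mV) and against an adaptive
reference solver on the smooth single-neuron problem (agreement ~5·10⁻⁴ mV
over 50 ms).

## Statistics

Spikes are upward crossings of 0 mV separated by ≥ 2 ms, with sub-step
linear interpolation of the crossing time. Synchrony is the Pearson
correlation of the full-resolution voltage traces over the whole 300 ms
window (no transient discarded; `burn_in_ms` optionally trims). Zero
variance raises an explicit undefined-correlation error and table cells
show NaN — never a silent 0. First-spike latency is reported relative to
neuron 1; the most distal neuron is 100 for directed chains and 50 for the
bidirectional ring. A neuron still silent at the end of the window has no
latency; where a single number is required the censored lower bound
(window length minus the reference first-spike time) is reported and
flagged.

Noise conditions are repeated over a seed list (default 10) and summarised
by the mean per cell; deterministic conditions consume no randomness and
rerun bit-identically.

## Two-neuron validation couplings

The square-wave two-neuron check (each synapse must conduct a complete
action potential) uses g = 0.1 for ES and RS — both conduct at the network
coupling strength — but g = 10 µA/cm² for HS, chosen equal to the
square-wave amplitude: the Hansel current *is* g, and 0.1 µA/cm² is ~60×
below the ~6 µA/cm² rheobase, so no parameter-free choice can make that
model conduct at network strength.

## Problem sizes

The reference conditions are 100 neurons × 300 ms at dt = 0.01 ms (~7 s per
run). Unit tests exercise the same code paths on 2–12 neuron networks over
20–150 ms; the acceptance suite runs the six deterministic reference
conditions, ten noise replicates and one full 12-condition grid.

## What the synthetic conditions do and do not show

The generator emulates a noiseless, perfectly homogeneous network: identical
point neurons, identical synapses, a single stimulated node, and stimulus
noise as the only stochasticity. Real tissue has heterogeneous parameters,
channel noise, distributed inputs and conduction delays that scale with
distance. Passing tests therefore demonstrate correctness of the stated
model and pipeline — not biological generality: conclusions about synapse
classes transfer only insofar as the literal threshold/gate abstractions do.

## Known limitations

* **Phase sensitivity of voltage-trace Pearson r.** With per-hop conduction
  lag (τ plus near-rheobase integration time, ~2–3 ms/hop at g = 0.1)
  longer than an action potential's width, two neurons can fire on every
  stimulus cycle yet correlate near zero or negatively. Published synchrony
  values computed from coarser data or different windows can therefore
  differ substantially from full-resolution voltage correlations; this is a
  measurement-convention sensitivity, not an integration error.
* **The HS chain stalls at network coupling strength** (gated current 0.1
  µA/cm² ≪ rheobase): downstream neurons stay subthreshold, their traces
  reduce to the tiny common relaxation transient, and any two such silent
  traces are *identical*, which pins their correlation at exactly 1 — an
  artifact to keep in mind when reading the HS table.
* **Directed-chain latency has a hard floor** of (hops × τ) plus the
  integration time per hop; for the 99-hop ring this exceeds tens of
  milliseconds for any τ ≥ 0, so small distal latencies are achievable only
  through shortcut topologies (the small-world hub cuts RS distal latency
  from 296 ms to 12 ms).
* The solver is fixed-step; stiff excursions are handled by the small dt
  rather than adaptivity, and event times are accurate only to the
  interpolation of grid crossings.
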