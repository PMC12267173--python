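"""Single-compartment Hodgkin-Huxley membrane dynamics.

The model is the classic four-variable conductance-based description of the
squid giant axon membrane: a membrane potential ``V`` (mV) driven by sodium,
potassium and leak currents, and three gating variables ``m`` (Na activation),
``h`` (Na inactivation) and ``n`` (K activation) with voltage-dependent
opening/closing rates alpha and beta (1/ms),

    C dV/dt = G_Na m^3 h (E_Na - V) + G_K n^4 (E_K - V) + G_L (E_L - V) + I
    dx/dt   = alpha_x(V) (1 - x) - beta_x(V) x        for x in {m, h, n}

All functions accept scalars or numpy arrays of membrane potentials and are
pure: parameters are passed explicitly via :class:`HHParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HHParams",
    "NeuronState",
    "RateSet",
    "rate_constants",
    "steady_state_gating",
    "resting_state",
    "hh_derivatives",
    "InvalidStateError",
]

#: Resting membrane potential (mV) used as the default initial condition.
V_REST = -65.0

# Voltage (mV) below which |V - V_singular| triggers the analytic-limit branch
# of the alpha_m / alpha_n rate expressions (removable 0/0 singularities).
_SINGULARITY_EPS = 1e-7


class InvalidStateError(ValueError):
    """A neuron state or input violates the model's domain (e.g. gating outside [0,1])."""


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters: capacitance (uF/cm^2), maximal conductances
    (mS/cm^2) and reversal potentials (mV).

    Note on ``g_k``: the canonical squid-axon value 36 mS/cm^2 is the default;
    it is the value consistent with the standard resting gating triple
    (m, h, n) = (0.05293, 0.5961, 0.3177) at V = -65 mV.  A tenfold larger
    potassium conductance suppresses firing entirely.
    """

    c: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_l: float = -54.5

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"membrane capacitance must be positive, got {self.c}")
        for name in ("g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass
class NeuronState:
    """Dynamical variables of one neuron: V (mV) and gating m, h, n in [0,1]."""

    v: float = V_REST
    m: float = 0.05293
    h: float = 0.5961
    n: float = 0.3177

    def validate(self) -> None:
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise InvalidStateError(f"gating variable {name}={x} outside [0, 1]")
        if not np.isfinite(self.v):
            raise InvalidStateError(f"non-finite membrane potential {self.v}")


@dataclass(frozen=True)
class RateSet:
    """The six voltage-dependent transition rates (1/ms)."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float


def _ramp_over_expm1(x, scale: float):
    """Evaluate x / (1 - exp(-x/scale)) with its analytic limit ``scale`` at x=0.

    This is the removable singularity shared by alpha_m and alpha_n.
    """
    x = np.asarray(x, dtype=float)
    near = np.abs(x) < _SINGULARITY_EPS
    # avoid 0/0 in the vectorised branch; the masked lanes are overwritten
    safe = np.where(near, 1.0, x)
    out = np.where(near, scale, safe / (-np.expm1(-safe / scale)))
    return out


def rate_constants(v):
    """Gating transition rates alpha/beta for m, h, n at membrane potential ``v`` (mV).

    Accepts scalars or arrays.  The removable singularities of alpha_m
    (V = -40 mV) and alpha_n (V = -55 mV) are evaluated by their analytic
    limits.  Raises :class:`InvalidStateError` for non-finite input.
    """
    v_arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v_arr)):
        raise InvalidStateError("membrane potential must be finite")
    alpha_m = 0.1 * _ramp_over_expm1(v_arr + 40.0, 10.0)
    beta_m = 4.0 * np.exp(-(v_arr + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(v_arr + 65.0) / 20.0)
    beta_h = 1.0 / (np.exp(-(v_arr + 35.0) / 10.0) + 1.0)
    alpha_n = 0.01 * _ramp_over_expm1(v_arr + 55.0, 10.0)
    beta_n = 0.125 * np.exp(-(v_arr + 65.0) / 80.0)
    if np.isscalar(v) or np.ndim(v) == 0:
        return RateSet(
            float(alpha_m), float(beta_m), float(alpha_h),
            float(beta_h), float(alpha_n), float(beta_n),
        )
    return RateSet(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)


def steady_state_gating(v):
    """Voltage-clamp steady state (m_inf, h_inf, n_inf) = alpha/(alpha+beta) at ``v``."""
    r = rate_constants(v)
    m_inf = r.alpha_m / (r.alpha_m + r.beta_m)
    h_inf = r.alpha_h / (r.alpha_h + r.beta_h)
    n_inf = r.alpha_n / (r.alpha_n + r.beta_n)
    return m_inf, h_inf, n_inf


def resting_state(v: float = V_REST) -> NeuronState:
    """Neuron state with gating at voltage-clamp steady state for ``v``."""
    m, h, n = steady_state_gating(v)
    return NeuronState(v=float(v), m=float(m), h=float(h), n=float(n))


def membrane_current(v, m, h, n, params: HHParams):
    """Total ionic current (uA/cm^2) flowing into the membrane at (v, m, h, n)."""
    i_na = params.g_na * m**3 * h * (params.e_na - v)
    i_k = params.g_k * n**4 * (params.e_k - v)
    i_l = params.g_l * (params.e_l - v)
    return i_na + i_k + i_l


def hh_derivatives(state: NeuronState, i_total: float, params: HHParams | None = None):
    """Right-hand side (dV/dt, dm/dt, dh/dt, dn/dt) for one neuron.

    ``i_total`` is the summed external plus synaptic current density
    (uA/cm^2).  Raises :class:`InvalidStateError` if a gating variable is
    outside [0, 1].
    """
    if params is None:
        params = HHParams()
    state.validate()
    if not np.isfinite(i_total):
        raise InvalidStateError(f"non-finite input current {i_total}")
    r = rate_constants(state.v)
    dv = (membrane_current(state.v, state.m, state.h, state.n, params) + i_total) / params.c
    dm = r.alpha_m * (1.0 - state.m) - r.beta_m * state.m
    dh = r.alpha_h * (1.0 - state.h) - r.beta_h * state.h
    dn = r.alpha_n * (1.0 - state.n) - r.beta_n * state.n
    return dv, dm, dh, dn
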