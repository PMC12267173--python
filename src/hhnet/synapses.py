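"""Coupling currents between neurons: gap junctions and two threshold chemical synapses.

Three models are implemented, all returning a current density (uA/cm^2)
injected into the postsynaptic membrane:

* electrical synapse (gap junction), bidirectional ohmic coupling
  ``I = g (V_pre - V_post)``;
* Hansel-type chemical synapse, a constant current delivered while the
  *delayed* presynaptic potential exceeds a threshold,
  ``I = G H(V_pre(t - tau) - V_thresh)``;
* Rabinovich-type chemical synapse, where the same Heaviside gate scales a
  driving force toward a synaptic reversal potential,
  ``I = G (V_rev - V_post) H(V_pre(t - tau) - V_thresh)``.

Chemical transmission is unidirectional (pre -> post) and delayed by ``tau``
milliseconds; :class:`DelayBuffer` provides the delayed-voltage lookup.

Sign convention for the Rabinovich synapse: with the default reversal
potential of 0 mV the gated term depolarizes the postsynaptic neuron toward
V_rev, i.e. it acts as an excitatory conductance-like drive whose magnitude
shrinks as the target approaches the reversal potential (the feedback that
limits noise-driven fluctuations).  The literal hyperpolarizing form
``G (V_post - V_rev) H(.)`` is available via ``rs_sign_literal=True``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseKind",
    "SynapseSpec",
    "DelayBuffer",
    "electrical_current",
    "hansel_current",
    "rabinovich_current",
    "delayed_lookup",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A synapse/buffer parameter combination is not usable."""


class SynapseKind(str, enum.Enum):
    ES = "ES"  # electrical synapse (gap junction)
    HS = "HS"  # Hansel chemical synapse
    RS = "RS"  # Rabinovich chemical synapse


@dataclass(frozen=True)
class SynapseSpec:
    """Parameters of one coupling model.

    ``g`` is the coupling strength: mS/cm^2 for ES and RS, and an effective
    current amplitude in uA/cm^2 for HS (whose gated output is the constant
    ``g``).  ``v_thresh`` (mV) and ``tau`` (ms) apply to the chemical models
    only; ``v_rev`` (mV) to RS only.
    """

    kind: SynapseKind
    g: float = 0.1
    v_thresh: float = -52.0
    tau: float = 1.0
    v_rev: float = 0.0
    rs_sign_literal: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SynapseKind(self.kind))
        if self.g < 0:
            raise ConfigurationError(f"coupling strength must be >= 0, got {self.g}")
        if self.tau < 0:
            raise ConfigurationError(f"transmission delay must be >= 0, got {self.tau}")

    @property
    def is_chemical(self) -> bool:
        return self.kind in (SynapseKind.HS, SynapseKind.RS)


def electrical_current(v_pre, v_post, g: float):
    """Gap-junction current g*(V_pre - V_post); antisymmetric in its endpoints."""
    return g * (np.asarray(v_pre, dtype=float) - np.asarray(v_post, dtype=float))


def _heaviside(x):
    """H(x) = 1 for x > 0 else 0; the threshold must be strictly exceeded."""
    return (np.asarray(x, dtype=float) > 0.0).astype(float)


def hansel_current(v_pre_delayed, spec: SynapseSpec):
    """Constant current ``g`` while the delayed presynaptic potential is above threshold."""
    if spec.kind is not SynapseKind.HS:
        raise ConfigurationError(f"hansel_current requires an HS spec, got {spec.kind}")
    out = spec.g * _heaviside(np.asarray(v_pre_delayed, dtype=float) - spec.v_thresh)
    return float(out) if np.ndim(v_pre_delayed) == 0 else out


def rabinovich_current(v_post, v_pre_delayed, spec: SynapseSpec):
    """Gated driving force toward the synaptic reversal potential.

    Returns ``g * (v_rev - v_post) * H(v_pre_delayed - v_thresh)`` (the
    depolarizing convention), or ``g * (v_post - v_rev) * H(.)`` when
    ``spec.rs_sign_literal`` is set.
    """
    if spec.kind is not SynapseKind.RS:
        raise ConfigurationError(f"rabinovich_current requires an RS spec, got {spec.kind}")
    gate = _heaviside(np.asarray(v_pre_delayed, dtype=float) - spec.v_thresh)
    drive = np.asarray(v_post, dtype=float) - spec.v_rev
    if not spec.rs_sign_literal:
        drive = -drive
    out = spec.g * drive * gate
    return float(out) if (np.ndim(v_post) == 0 and np.ndim(v_pre_delayed) == 0) else out


class DelayBuffer:
    """Fixed-horizon history of per-neuron membrane potentials on a uniform grid.

    Stores the most recent ``horizon`` samples at spacing ``dt`` for ``n``
    neurons in a ring buffer.  Lookups at lag ``tau`` linearly interpolate
    between grid samples; before ``tau`` milliseconds of history exist the
    initial fill value (resting potential by default) is returned, modelling
    a network at rest for t < 0.
    """

    def __init__(self, n: int, dt: float, horizon: float, fill: float = -65.0):
        if dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {dt}")
        if horizon < 0:
            raise ConfigurationError(f"horizon must be >= 0, got {horizon}")
        self.n = int(n)
        self.dt = float(dt)
        # +2 slots: one for the current sample, one so that lag == horizon
        # still has a bracketing older sample to interpolate against.
        self._slots = int(np.ceil(horizon / dt)) + 2
        self._buf = np.full((self._slots, self.n), float(fill))
        self._head = 0  # index of the most recent sample

    @property
    def horizon(self) -> float:
        """Largest lag (ms) that can be looked up."""
        return (self._slots - 2) * self.dt

    def push(self, values) -> None:
        """Append the current per-neuron potentials (advances time by dt)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError(f"expected shape ({self.n},), got {values.shape}")
        self._head = (self._head + 1) % self._slots
        self._buf[self._head] = values

    def set_current(self, values) -> None:
        """Overwrite the most recent sample without advancing time."""
        self._buf[self._head] = np.asarray(values, dtype=float)

    def lookup(self, tau: float):
        """Per-neuron potential ``tau`` ms ago, linearly interpolated."""
        if tau < 0:
            raise ConfigurationError(f"lag must be >= 0, got {tau}")
        if tau > self.horizon + 1e-12:
            raise ConfigurationError(
                f"lag {tau} ms exceeds buffer horizon {self.horizon} ms"
            )
        steps = tau / self.dt
        lo = int(np.floor(steps))
        frac = steps - lo
        if frac < 1e-12:
            return self._buf[(self._head - lo) % self._slots].copy()
        newer = self._buf[(self._head - lo) % self._slots]
        older = self._buf[(self._head - lo - 1) % self._slots]
        return (1.0 - frac) * newer + frac * older


def delayed_lookup(buffer: DelayBuffer, tau: float):
    """Functional alias for :meth:`DelayBuffer.lookup`."""
    return buffer.lookup(tau)
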