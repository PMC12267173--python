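"""Synthetic stimulation currents: square wave, offset sine, and Gaussian noise.

These are the inputs of the whole study; no external data is read.  The
defaults are the study conditions:

* square wave -- 10 uA/cm^2 during the first half of each 20 ms period
  (used for the two-neuron action-potential validation);
* sine -- I_ext(t) = 60 sin(0.1 pi t) + 30 uA/cm^2, i.e. a 50 Hz wave
  (period 20 ms, t in ms) riding on a 30 uA/cm^2 DC offset;
* interference -- zero-mean Gaussian white noise with standard deviation
  20 uA/cm^2, sampled on a grid of spacing ``noise_sample_dt`` and held
  piecewise-constant between samples (a sampled noise signal, not an SDE
  diffusion term: no 1/sqrt(dt) scaling), superimposed on the sine.

All randomness flows through ``spec.seed`` via numpy's Generator, so every
rendered trace is reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .synapses import ConfigurationError

__all__ = ["Waveform", "StimulusSpec", "square_wave", "sine_wave", "noise_samples", "render_stimulus"]


class Waveform(str, enum.Enum):
    NONE = "none"
    SQUARE = "square"
    SINE = "sine"
    SINE_PLUS_NOISE = "sine_plus_noise"


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus parameters; amplitudes/offsets in uA/cm^2, omega in rad/ms."""

    waveform: Waveform = Waveform.SINE
    amplitude: float = 60.0
    offset: float = 30.0
    omega: float = 0.1 * np.pi
    square_amplitude: float = 10.0
    square_period: float = 20.0
    noise_mean: float = 0.0
    noise_std: float = 20.0
    noise_sample_dt: float = 0.01
    seed: int | None = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", Waveform(self.waveform))
        if self.noise_std < 0:
            raise ConfigurationError(f"noise_std must be >= 0, got {self.noise_std}")
        if self.noise_sample_dt <= 0:
            raise ConfigurationError(
                f"noise_sample_dt must be positive, got {self.noise_sample_dt}"
            )

    def with_seed(self, seed: int | None) -> "StimulusSpec":
        return replace(self, seed=seed)

    def deterministic_part(self, t):
        """Noise-free waveform value at time(s) ``t`` (ms); vectorised."""
        if self.waveform is Waveform.NONE:
            return np.zeros_like(np.asarray(t, dtype=float))
        if self.waveform is Waveform.SQUARE:
            return square_wave(t, self.square_amplitude, self.square_period)
        return sine_wave(t, self)


def square_wave(t, amplitude: float = 10.0, period: float = 20.0):
    """``amplitude`` during the first half of each period, 0 during the second."""
    t = np.asarray(t, dtype=float)
    on = np.mod(t, period) < period / 2.0
    out = np.where(on, amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


def sine_wave(t, spec: StimulusSpec | None = None):
    """Offset sine ``amplitude * sin(omega t) + offset``."""
    if spec is None:
        spec = StimulusSpec()
    t = np.asarray(t, dtype=float)
    out = spec.amplitude * np.sin(spec.omega * t) + spec.offset
    return float(out) if out.ndim == 0 else out


def noise_samples(n: int, spec: StimulusSpec) -> np.ndarray:
    """``n`` i.i.d. Gaussian draws (noise_mean, noise_std), seeded by ``spec.seed``."""
    if n < 1:
        raise ConfigurationError(f"need at least one sample, got n={n}")
    rng = np.random.default_rng(spec.seed)
    return rng.normal(spec.noise_mean, spec.noise_std, size=int(n))


def render_noise(spec: StimulusSpec, t_grid: np.ndarray) -> np.ndarray:
    """Noise rendered onto ``t_grid``, held constant over each noise sample interval."""
    t_grid = np.asarray(t_grid, dtype=float)
    if spec.noise_std == 0.0:
        return np.full(t_grid.shape, spec.noise_mean)
    idx = np.floor(t_grid / spec.noise_sample_dt + 1e-9).astype(np.intp)
    draws = noise_samples(int(idx.max()) + 1, spec)
    return draws[idx]


def render_stimulus(spec: StimulusSpec, t_grid) -> np.ndarray:
    """Evaluate the stimulus on a uniform time grid (ms) -> current densities.

    For ``sine_plus_noise`` the noise term is sampled at ``noise_sample_dt``
    and held piecewise-constant.  Deterministic given (spec, grid, seed).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    det = spec.deterministic_part(t_grid)
    if spec.waveform is Waveform.SINE_PLUS_NOISE:
        det = det + render_noise(spec, t_grid)
    return np.asarray(det, dtype=float)
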