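"""Post-simulation statistics: spike detection, latency, and synchrony tables.

Synchrony between two neurons is quantified by the Pearson correlation
coefficient of their full membrane-potential traces,

    r = sum_i (x_i - xbar)(y_i - ybar)
        / sqrt( sum_i (x_i - xbar)^2 * sum_i (y_i - ybar)^2 ),

computed over the whole recorded window (no transient discarded by default;
``burn_in_ms`` trims the start when requested).  The canonical neuron pairs
reported for the 100-neuron networks are (1,25), (15,30), (20,35), (5,45).

Propagation is quantified by first-spike latency relative to the stimulated
reference neuron.  A neuron that never crosses the spike threshold is
reported as *missing* (NaN), never as zero; when censoring matters (the
neuron may simply not have fired yet), the simulation length bounds the
observable latency from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulation import SimulationResult

__all__ = [
    "REPORT_PAIRS",
    "detect_spikes",
    "pearson_r",
    "correlation_table",
    "first_spike_latency",
    "summarize_grid",
    "LatencyReport",
    "UndefinedCorrelationError",
]

#: The neuron pairs of the synchrony tables, in fixed column order.
REPORT_PAIRS: tuple[tuple[int, int], ...] = ((1, 25), (15, 30), (20, 35), (5, 45))


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (zero variance in at least one trace)."""


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by >= ``refractory``.

    A crossing is sample i with trace[i-1] < threshold <= trace[i]; the
    reported time is linearly interpolated between the two samples, so spike
    times resolve below the sampling step.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty voltage trace")
    above = trace >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - trace[idx - 1]) / (trace[idx] - trace[idx - 1])
    times = (idx - 1 + frac) * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length sequences.

    Raises :class:`UndefinedCorrelationError` when either sequence has zero
    variance (a silent, constant neuron), rather than silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need two equal-length 1-D sequences, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    # clip the last-ulp excursions outside [-1, 1]
    return min(1.0, max(-1.0, r))


def correlation_table(
    result: SimulationResult,
    pairs: tuple[tuple[int, int], ...] = REPORT_PAIRS,
    burn_in_ms: float = 0.0,
) -> dict[tuple[int, int], float]:
    """Pearson r of the recorded voltage traces for each neuron pair.

    Cells whose correlation is undefined (a constant trace) are NaN.
    """
    start = int(np.searchsorted(result.t, burn_in_ms)) if burn_in_ms > 0 else 0
    out: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        if i > result.n_neurons or j > result.n_neurons:
            raise ValueError(f"pair ({i},{j}) outside 1..{result.n_neurons}")
        try:
            out[(i, j)] = pearson_r(result.trace(i)[start:], result.trace(j)[start:])
        except UndefinedCorrelationError:
            out[(i, j)] = float("nan")
    return out


@dataclass
class LatencyReport:
    """First-spike times and latencies relative to a reference neuron.

    ``first_spike[i]`` and ``latency[i]`` are NaN for silent neurons (index
    0 is neuron 1).  ``censored_at`` is the largest observable latency given
    the simulation length: a silent neuron's true latency exceeds it.
    """

    reference: int
    first_spike: np.ndarray
    latency: np.ndarray
    censored_at: float

    def latency_of(self, neuron: int) -> float:
        return float(self.latency[neuron - 1])

    def is_silent(self, neuron: int) -> bool:
        return bool(np.isnan(self.first_spike[neuron - 1]))

    def latency_or_censor(self, neuron: int) -> float:
        """Latency, or the censoring bound for a neuron still silent at the end."""
        lat = self.latency_of(neuron)
        return lat if np.isfinite(lat) else self.censored_at


def first_spike_latency(result: SimulationResult, reference: int | None = None) -> LatencyReport:
    """Per-neuron first-spike latency relative to ``reference`` (default: stimulated node)."""
    if reference is None:
        reference = int(result.metadata.get("stimulated_node", 1))
    firsts = np.array([
        st[0] if st.size else np.nan for st in result.spike_times
    ])
    ref_first = firsts[reference - 1]
    if np.isnan(ref_first):
        raise ValueError(f"reference neuron {reference} never fired")
    return LatencyReport(
        reference=reference,
        first_spike=firsts,
        latency=firsts - ref_first,
        censored_at=float(result.t[-1] - ref_first),
    )


def _pair_label(pair: tuple[int, int]) -> str:
    return f"r({pair[0]}-{pair[1]})"


def summarize_grid(
    grid_results: dict[str, list[SimulationResult]],
    pairs: tuple[tuple[int, int], ...] = REPORT_PAIRS,
    burn_in_ms: float = 0.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Assemble per-synapse correlation tables and a latency summary.

    ``grid_results`` maps condition labels ``"{synapse}_{topology}_{stimulus}"``
    (e.g. ``"RS_ring_sine"``) to a list of replicate results (one per noise
    seed; deterministic conditions have a single entry).  Returns
    ``(tables, latency)`` where ``tables[synapse]`` is a 4-row DataFrame
    (ring/NW x sine/noise) of pair correlations averaged over replicates,
    and ``latency`` summarises the distal neuron's first-spike latency per
    condition.  Missing conditions are simply absent; failed cells are NaN.
    """
    row_labels = {
        ("ring", "sine"): "ring, sine",
        ("ring", "sine_noise"): "ring, sine + noise",
        ("nw", "sine"): "NW small-world, sine",
        ("nw", "sine_noise"): "NW small-world, sine + noise",
    }
    tables: dict[str, pd.DataFrame] = {}
    lat_rows = []
    by_synapse: dict[str, dict[str, list[SimulationResult]]] = {}
    for label, results in grid_results.items():
        synapse, topology, stim = label.split("_", 2)
        by_synapse.setdefault(synapse, {})[f"{topology}_{stim}"] = results

    for synapse, conditions in by_synapse.items():
        rows = {}
        for (topology, stim), row_name in row_labels.items():
            results = conditions.get(f"{topology}_{stim}")
            if not results:
                continue
            per_seed = [correlation_table(r, pairs, burn_in_ms) for r in results]
            rows[row_name] = {
                _pair_label(p): float(np.nanmean([tbl[p] for tbl in per_seed]))
                for p in pairs
            }
            # distal neuron: 50 for bidirectional (ES) coupling, N for directed
            n_net = results[0].n_neurons
            distal = n_net // 2 if synapse == "ES" else n_net
            lats, censored = [], []
            for r in results:
                rep = first_spike_latency(r)
                lats.append(rep.latency_or_censor(distal))
                censored.append(rep.is_silent(distal))
            lat_rows.append({
                "synapse": synapse,
                "condition": row_name,
                "distal_neuron": distal,
                "latency_ms": float(np.mean(lats)),
                "censored": bool(np.any(censored)),
                "n_replicates": len(results),
            })
        tables[synapse] = pd.DataFrame.from_dict(rows, orient="index")[
            [_pair_label(p) for p in pairs]
        ]
    latency = pd.DataFrame(lat_rows)
    return tables, latency
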