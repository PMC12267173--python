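"""Network wiring: ring lattices and Newman-Watts small-world variants.

Neurons are numbered 1..N, matching the convention that neuron 1 is the
(single) externally stimulated node.  Two constructions are provided beyond
the plain ring:

* :func:`build_nw_hub` -- the ring plus ``k`` shortcut links from the
  stimulated hub to evenly spaced non-adjacent nodes (the deterministic
  small-world variant used for the 100-neuron experiments);
* :func:`build_nw_random` -- the classic Newman-Watts construction, adding
  each non-ring pair independently with probability ``p`` (p=0 recovers the
  ring, p=1 the complete graph).

Edges carry a ``directed`` flag: chemical synapses transmit only
pre -> post, gap junctions couple both endpoints.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synapses import ConfigurationError

__all__ = ["Edge", "NetworkGraph", "build_ring", "build_nw_hub", "build_nw_random"]


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    directed: bool = True


@dataclass
class NetworkGraph:
    """Node count, edge list (1-based indices) and the stimulated node."""

    n: int
    edges: list[Edge] = field(default_factory=list)
    stimulated_node: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.stimulated_node <= self.n):
            raise ConfigurationError(
                f"stimulated node {self.stimulated_node} outside 1..{self.n}"
            )
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ConfigurationError(f"self-loop at node {e.source}")
            if not (1 <= e.source <= self.n and 1 <= e.target <= self.n):
                raise ConfigurationError(f"edge {e} outside 1..{self.n}")
            key = (e.source, e.target) if e.directed else tuple(sorted((e.source, e.target)))
            if key in seen:
                raise ConfigurationError(f"duplicate edge {e}")
            seen.add(key)

    # -- queries ---------------------------------------------------------

    @property
    def directed(self) -> bool:
        return all(e.directed for e in self.edges)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (source, target) arrays with undirected edges expanded both ways."""
        src, tgt = [], []
        for e in self.edges:
            src.append(e.source - 1)
            tgt.append(e.target - 1)
            if not e.directed:
                src.append(e.target - 1)
                tgt.append(e.source - 1)
        return np.asarray(src, dtype=np.intp), np.asarray(tgt, dtype=np.intp)

    def undirected_pairs(self) -> list[tuple[int, int]]:
        """Unordered endpoint pairs (1-based) of the undirected edges."""
        return [tuple(sorted((e.source, e.target))) for e in self.edges if not e.directed]

    def topology_hash(self) -> str:
        payload = f"{self.n};{self.stimulated_node};" + ";".join(
            f"{e.source}>{e.target}:{int(e.directed)}"
            for e in sorted(self.edges, key=lambda e: (e.source, e.target))
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- serialization ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "directed"])
            for e in self.edges:
                w.writerow([e.source, e.target, int(e.directed)])

    @classmethod
    def from_csv(cls, path: str | Path, n: int, stimulated_node: int = 1) -> "NetworkGraph":
        edges = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append(
                    Edge(int(row["source"]), int(row["target"]), bool(int(row["directed"])))
                )
        return cls(n=n, edges=edges, stimulated_node=stimulated_node)


def _ring_edges(n: int, directed: bool) -> list[Edge]:
    if n == 2 and not directed:
        # the undirected 2-ring degenerates to a single edge
        return [Edge(1, 2, False)]
    return [Edge(i, i % n + 1, directed) for i in range(1, n + 1)]


def build_ring(n: int, directed: bool = True) -> NetworkGraph:
    """Ring of ``n`` neurons: i -> i+1 and N -> 1 (undirected for gap junctions)."""
    if n < 2:
        raise ConfigurationError(f"a ring needs at least 2 nodes, got {n}")
    return NetworkGraph(n=n, edges=_ring_edges(n, directed))


def default_hub_targets(n: int, hub: int, k: int) -> list[int]:
    """Evenly spaced shortcut targets, skipping the hub and its ring neighbours.

    For the reference network (n=100, hub=1, k=24) this yields 5, 9, ..., 97:
    arithmetic spacing 4 starting two nodes past the hub's successor.
    """
    if k == 0:
        return []
    neighbours = {hub, hub % n + 1, (hub - 2) % n + 1}
    stride = max((n - 3) // k, 1)
    targets: list[int] = []
    t = hub
    while len(targets) < k:
        t = (t - 1 + stride) % n + 1
        if t in neighbours or t in targets:
            t_scan = t
            while t_scan in neighbours or t_scan in targets:
                t_scan = t_scan % n + 1
            t = t_scan
        targets.append(t)
    return sorted(targets)


def build_nw_hub(
    n: int,
    hub: int = 1,
    k: int = 24,
    directed: bool = True,
    targets: list[int] | None = None,
    bidirectional_shortcuts: bool = False,
) -> NetworkGraph:
    """Ring plus ``k`` shortcuts from the stimulated hub to non-adjacent nodes.

    Shortcut targets default to the deterministic evenly spaced set
    (5, 9, ..., 97 for the 100-neuron, k=24 reference network); an explicit
    ``targets`` list overrides it.  Chemical shortcuts are directed
    hub -> target (the hub distributes the stimulus) unless
    ``bidirectional_shortcuts`` is set.
    """
    if k > n - 3:
        raise ConfigurationError(
            f"cannot place {k} non-adjacent shortcuts in a ring of {n} nodes"
        )
    if targets is None:
        targets = default_hub_targets(n, hub, k)
    if len(targets) != k:
        raise ConfigurationError(f"expected {k} shortcut targets, got {len(targets)}")
    forbidden = {hub, hub % n + 1, (hub - 2) % n + 1}
    bad = sorted(set(targets) & forbidden)
    if bad:
        raise ConfigurationError(f"shortcut targets adjacent to hub: {bad}")
    edges = _ring_edges(n, directed)
    shortcut_directed = directed and not bidirectional_shortcuts
    edges.extend(Edge(hub, t, shortcut_directed) for t in targets)
    g = NetworkGraph(n=n, edges=edges, stimulated_node=hub)
    return g


def build_nw_random(
    n: int, p: float, seed: int | None = None, directed: bool = True
) -> NetworkGraph:
    """Newman-Watts graph: ring backbone plus each non-ring pair with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"probability must lie in [0, 1], got {p}")
    if n < 2:
        raise ConfigurationError(f"need at least 2 nodes, got {n}")
    rng = np.random.default_rng(seed)
    edges = _ring_edges(n, directed)
    ring_pairs = {tuple(sorted((e.source, e.target))) for e in edges}
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if (i, j) in ring_pairs:
                continue
            if rng.random() < p:
                edges.append(Edge(i, j, directed))
    return NetworkGraph(n=n, edges=edges)
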