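"""Network products: binned edge maps, antenna groups, composite pathways.

Time-constant bins follow the map conventions: pairwise edges are binned
fast (< 1 ps) / mid (1-10 ps) / slow (10-20 ps) with slower edges omitted;
domain-level edges are omitted beyond 25 ps.  Boundary values fall into the
slower bin.  Composite pathway times use a pluggable aggregation rule,
series-sum by default.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import PathwayError, UsageError
from .rates import RateMatrix

__all__ = [
    "BinScheme",
    "BinnedEdge",
    "BinnedEdgeList",
    "GroupPartition",
    "PathwayResult",
    "bin_edges",
    "partition_groups",
    "composite_path_time",
    "best_route_to_core",
    "AGGREGATION_RULES",
]


@dataclass(frozen=True)
class BinScheme:
    """Ordered bin upper bounds (ps) with labels; the last bound is the
    omission cutoff."""

    bounds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.labels):
            raise UsageError("bin scheme needs one label per bound")
        if list(self.bounds) != sorted(self.bounds) or min(self.bounds) <= 0:
            raise UsageError("bin bounds must be positive and ascending")

    @property
    def cutoff(self) -> float:
        return self.bounds[-1]

    def bin_of(self, tau: float) -> str | None:
        """Label for *tau*, or None when omitted. Boundaries go to the
        slower (higher) bin; tau == cutoff is omitted."""
        for bound, label in zip(self.bounds, self.labels):
            if tau < bound:
                return label
        return None

    @classmethod
    def pairwise_default(cls) -> "BinScheme":
        return cls(bounds=(1.0, 10.0, 20.0), labels=("fast", "mid", "slow"))

    @classmethod
    def domain_default(cls) -> "BinScheme":
        return cls(bounds=(25.0,), labels=("retained",))


@dataclass(frozen=True)
class BinnedEdge:
    donor: str
    acceptor: str
    tau_ps: float
    bin: str


@dataclass
class BinnedEdgeList:
    edges: list[BinnedEdge]
    scheme: BinScheme
    n_omitted: int = 0
    undirected: bool = False


def bin_edges(rates: RateMatrix, scheme: BinScheme | None = None) -> BinnedEdgeList:
    """Assign every finite-rate directed edge to a time-constant bin."""
    if scheme is None:
        scheme = (BinScheme.pairwise_default() if rates.level == "pairwise"
                  else BinScheme.domain_default())
    edges: list[BinnedEdge] = []
    omitted = 0
    tau = rates.tau
    n = len(rates.labels)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(tau[i, j]):
                continue
            label = scheme.bin_of(float(tau[i, j]))
            if label is None:
                omitted += 1
            else:
                edges.append(BinnedEdge(rates.labels[i], rates.labels[j],
                                        float(tau[i, j]), label))
    return BinnedEdgeList(edges=edges, scheme=scheme, n_omitted=omitted)


def _natural_key(label: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label)]


@dataclass
class GroupPartition:
    mapping: dict[str, int]  # label -> 1-based group id

    @property
    def n_groups(self) -> int:
        return len(set(self.mapping.values()))

    def groups(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for label, gid in self.mapping.items():
            out.setdefault(gid, []).append(label)
        return [sorted(out[g], key=_natural_key) for g in sorted(out)]


def partition_groups(
    gf: RateMatrix, cutoff_ps: float = 25.0, exclude: frozenset[str] = frozenset({"core"})
) -> GroupPartition:
    """Groups of antenna domains connected by edges with min(tau_fwd,
    tau_bwd) <= cutoff; groups are numbered by their smallest member label."""
    nodes = [l for l in gf.labels if l not in exclude]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    tau = gf.tau
    for a, b in itertools.combinations(nodes, 2):
        i, j = gf.labels.index(a), gf.labels.index(b)
        if min(tau[i, j], tau[j, i]) <= cutoff_ps:
            g.add_edge(a, b)
    components = sorted(
        (sorted(c, key=_natural_key) for c in nx.connected_components(g)),
        key=lambda c: _natural_key(c[0]),
    )
    mapping = {}
    for gid, component in enumerate(components, start=1):
        for label in component:
            mapping[label] = gid
    return GroupPartition(mapping=mapping)


def _series_sum(step_taus: list[float]) -> float:
    return float(sum(step_taus))


def _rate_limiting_step(step_taus: list[float]) -> float:
    return float(max(step_taus))


AGGREGATION_RULES = {
    "series_sum": _series_sum,
    "rate_limiting_step": _rate_limiting_step,
}


@dataclass
class PathwayResult:
    nodes: list[str]
    step_taus: list[float]
    composite_tau: float
    rule: str = "series_sum"

    def notation(self) -> str:
        """Compact ``A-B-core (tau ps)`` rendering of the pathway."""
        short = [n.replace("LHC-", "") for n in self.nodes]
        return f"{'-'.join(short)} ({self.composite_tau:.1f} ps)"


def composite_path_time(
    path: list[str], gf: RateMatrix, rule: str = "series_sum"
) -> PathwayResult:
    """Composite time constant of an explicit node path."""
    if len(path) < 2:
        raise UsageError("a pathway needs at least two nodes")
    if any(a == b for a, b in zip(path, path[1:])):
        raise UsageError("consecutive pathway nodes must be distinct")
    if rule not in AGGREGATION_RULES:
        raise UsageError(f"unknown aggregation rule {rule!r}")
    taus = []
    for donor, acceptor in zip(path, path[1:]):
        if donor not in gf.labels or acceptor not in gf.labels:
            raise PathwayError(f"unknown node in path: {donor!r} or {acceptor!r}")
        tau = gf.time_constant(donor, acceptor)
        if not np.isfinite(tau):
            raise PathwayError(f"no finite rate for step {donor} -> {acceptor}")
        taus.append(tau)
    return PathwayResult(nodes=list(path), step_taus=taus,
                         composite_tau=AGGREGATION_RULES[rule](taus), rule=rule)


def best_route_to_core(
    lhc: str, gf: RateMatrix, core_label: str = "core", rule: str = "series_sum"
) -> PathwayResult:
    """Minimum-composite-time simple path from *lhc* to the core under the
    series-sum rule (ties broken lexicographically)."""
    if lhc not in gf.labels or core_label not in gf.labels:
        raise PathwayError(f"unknown node {lhc!r} or {core_label!r}")
    g = nx.DiGraph()
    g.add_nodes_from(gf.labels)
    tau = gf.tau
    for i, donor in enumerate(gf.labels):
        for j, acceptor in enumerate(gf.labels):
            if i != j and np.isfinite(tau[i, j]):
                g.add_edge(donor, acceptor, tau=float(tau[i, j]))
    try:
        candidates = list(nx.all_shortest_paths(g, lhc, core_label, weight="tau"))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        raise PathwayError(f"core {core_label!r} unreachable from {lhc!r}") from None
    best = min(candidates)  # lexicographic tie-break
    return composite_path_time(best, gf, rule=rule)
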