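"""Gene-interaction network robustness under node removal.

Robustness of a cold-resistance-gene (CRG) interaction network is
measured as the fraction of the original nodes remaining in the largest
connected component after removing a fixed number (or percentage) of
nodes, averaged over random trials or computed once for deterministic
degree-targeted removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np


@dataclass
class RobustnessSpec:
    remove_count: int | None = None
    remove_percent: float | None = None
    selection: str = "random"  # "random" | "degree"
    trials: int = 1000
    seed: int = 0

    def resolve_count(self, n_nodes: int) -> int:
        if (self.remove_count is None) == (self.remove_percent is None):
            raise ValueError("specify exactly one of remove_count / remove_percent")
        if self.remove_count is not None:
            k = self.remove_count
        else:
            if not (0 < self.remove_percent < 100):
                raise ValueError("percent must be in (0, 100)")
            k = int(
                Decimal(str(self.remove_percent * n_nodes / 100)).quantize(
                    Decimal(1), rounding=ROUND_HALF_UP
                )
            )
        if k >= n_nodes:
            raise ValueError(f"cannot remove {k} of {n_nodes} nodes")
        if k < 0:
            raise ValueError("negative removal count")
        return k


@dataclass
class RobustnessResult:
    value: float
    per_trial: list[float]
    spec: RobustnessSpec
    n_removed: int


def _lcc_fraction(g: nx.Graph, n_original: int) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    return max(len(c) for c in nx.connected_components(g)) / n_original


def robustness(graph: nx.Graph, spec: RobustnessSpec) -> RobustnessResult:
    """Mean largest-connected-component fraction after node removal.

    ``random`` removal draws nodes without replacement per trial (seeded);
    ``degree`` removal deterministically deletes the top-degree nodes,
    ties broken by node-name order, in a single trial.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("graph must have >= 2 nodes")
    k = spec.resolve_count(n)
    if k == 0:
        v = _lcc_fraction(graph, n)
        return RobustnessResult(v, [v], spec, 0)
    if spec.selection == "degree":
        order = sorted(graph.nodes, key=lambda u: (-graph.degree[u], str(u)))
        h = graph.copy()
        h.remove_nodes_from(order[:k])
        v = _lcc_fraction(h, n)
        return RobustnessResult(v, [v], spec, k)
    if spec.selection != "random":
        raise ValueError(f"unknown selection {spec.selection!r}")
    rng = np.random.default_rng(spec.seed)
    nodes = sorted(graph.nodes, key=str)
    vals = []
    for _ in range(spec.trials):
        drop = rng.choice(len(nodes), size=k, replace=False)
        h = graph.copy()
        h.remove_nodes_from([nodes[i] for i in drop])
        vals.append(_lcc_fraction(h, n))
    return RobustnessResult(float(np.mean(vals)), vals, spec, k)
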