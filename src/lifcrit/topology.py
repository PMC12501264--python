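"""Directed weighted connectivity generators.

Three ensembles are supported, all with zero diagonal (no self-connections)
and nonzero weights drawn i.i.d. from a Gaussian with mean ``mean_weight``
and standard deviation ``mean_weight/10``:

``small_world``
    Directed Watts-Strogatz graph: a ring lattice in which every neuron
    sends edges to its beta*N nearest neighbours (beta*N/2 on each side),
    each edge's target rewired with probability ``p_rewire`` to a uniform
    non-self, non-duplicate node.
``uniform_random``
    Each ordered pair (i != j) connected independently with probability
    beta*N/(N-1), so the expected mean in-degree is beta*N.
``fully_connected``
    Complete digraph minus loops (beta is ignored for the adjacency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .params import ReservoirParams

__all__ = ["WeightMatrix", "generate_weights"]

TopologyKind = Literal["small_world", "uniform_random", "fully_connected"]


@dataclass(frozen=True)
class WeightMatrix:
    """Synaptic weights of a directed network.

    ``weights[i, j]`` is the contribution (mV) a spike of neuron ``j`` adds
    to neuron ``i``; a stored zero row means no connection.  Held as a CSC
    sparse matrix (columns are presynaptic neurons, the layout the
    simulator consumes).
    """

    weights: sp.csc_matrix
    topology_kind: TopologyKind
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def realized_degrees(self) -> np.ndarray:
        """Per-neuron in-degree counts C_i."""
        w = self.weights.tocsr()
        return np.diff(w.indptr)

    @property
    def mean_degree(self) -> float:
        return self.weights.nnz / self.n_neurons

    @property
    def mean_weight(self) -> float:
        """Mean over existing connections (not over all N^2 entries)."""
        return float(self.weights.data.mean()) if self.weights.nnz else 0.0

    def toarray(self) -> np.ndarray:
        return self.weights.toarray()

    def rescaled_to(self, target_mean: float) -> "WeightMatrix":
        """Multiplicatively rescale all connections so the mean weight equals
        ``target_mean`` (topology and relative weight structure preserved)."""
        cur = self.mean_weight
        if cur == 0:
            raise ValueError("cannot rescale a zero-mean weight matrix")
        w = self.weights.copy()
        w.data *= target_mean / cur
        return WeightMatrix(weights=w, topology_kind=self.topology_kind, seed=self.seed)

    def to_edge_tsv(self, path: str | Path) -> None:
        """Dump as 3-column edge list (source, target, weight_mV), 0-based."""
        coo = self.weights.tocoo()
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight_mV\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{j}\t{i}\t{float(w)!r}\n")


def _small_world_adjacency(n: int, k: int, p_rewire: float, rng: np.random.Generator):
    """Directed ring lattice with out-degree k, targets rewired with prob p."""
    rows = []  # targets (postsynaptic)
    cols = []  # sources (presynaptic)
    half = k // 2
    offsets = [o for o in range(-half, half + 1) if o != 0]
    for j in range(n):
        targets = {(j + o) % n for o in offsets}
        for tgt in sorted(targets):
            if p_rewire > 0 and rng.random() < p_rewire:
                new = int(rng.integers(n))
                while new == j or new in targets:
                    new = int(rng.integers(n))
                targets.discard(tgt)
                targets.add(new)
                tgt = new
            rows.append(tgt)
            cols.append(j)
    return np.array(rows), np.array(cols)


def generate_weights(
    params: ReservoirParams,
    topology_kind: TopologyKind,
    mean_weight: float,
    seed: int,
    p_rewire: float = 0.1,
) -> WeightMatrix:
    """Sample a directed weighted connectivity matrix.

    Nonzero weights are i.i.d. Gaussian(mean_weight, sd=mean_weight/10);
    negative draws are kept (they model inhibition — the theory only
    constrains the mean).  Deterministic given ``seed``.

    Raises ``ValueError`` when beta*N < 1 (degenerate graph) or, for
    ``small_world``, when beta*N is not an even integer >= 2 (the ring
    lattice needs beta*N/2 neighbours on each side).
    """
    n = params.n_neurons
    k_float = params.beta * n
    if k_float < 1:
        raise ValueError("beta*N < 1 yields a degenerate graph")
    if mean_weight < 0:
        warnings.warn(
            "negative mean_weight: generating an inhibition-dominated network",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    if topology_kind == "fully_connected":
        rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    elif topology_kind == "uniform_random":
        p = k_float / (n - 1)
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
    elif topology_kind == "small_world":
        k = int(round(k_float))
        if abs(k - k_float) > 1e-9 or k % 2 != 0 or k < 2:
            raise ValueError(
                "small_world requires beta*N to be an even integer >= 2"
            )
        rows, cols = _small_world_adjacency(n, k, p_rewire, rng)
    else:
        raise ValueError(f"unknown topology_kind: {topology_kind!r}")

    data = rng.normal(loc=mean_weight, scale=abs(mean_weight) / 10, size=rows.size)
    w = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    return WeightMatrix(weights=w, topology_kind=topology_kind, seed=seed)
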