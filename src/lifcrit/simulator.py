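"""Discrete-time simulation of the LIF reservoir.

The continuous dynamics — delta-impulse external kicks and synaptic inputs
plus exponential leak — are discretized on a grid of step ``dt`` ms:

* leak is applied as the exact per-step factor ``exp(-alpha*dt)`` (not
  forward Euler), so the discrete map matches the mean-field ODE solution
  between events;
* every step delivers ``round(dt/tau)`` external kicks, each to one
  uniformly drawn neuron (with replacement);
* spikes propagate with a one-step delay: spikes at step t reach their
  targets at step t+1;
* a neuron fires when its potential reaches threshold (v >= theta), resets
  to 0 mV and is refractory for ``ceil(tau_ref/dt)`` subsequent steps,
  during which it cannot fire.  By default refractory neurons keep
  integrating their inputs (the reading under which the simulated ISI curve
  matches the mean-field relation, whose averaged potential integrates the
  full drive over one period); ``buffer_refractory=False`` instead clamps
  the potential at 0 and discards all inputs during refractoriness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from ._kernels import lif_steps
from .params import ReservoirParams
from .topology import WeightMatrix

__all__ = ["SpikeRaster", "SimulationState", "simulate", "spike_count", "mean_isi"]


@dataclass
class SimulationState:
    """Mutable per-neuron state carried across simulation windows."""

    potentials: np.ndarray  # mV, v_i
    refractory_remaining: np.ndarray  # remaining refractory steps
    prev_spiked: np.ndarray  # spikes of the last completed step
    step_index: int = 0

    @classmethod
    def fresh(cls, n_neurons: int) -> "SimulationState":
        return cls(
            potentials=np.zeros(n_neurons),
            refractory_remaining=np.zeros(n_neurons, np.int64),
            prev_spiked=np.zeros(n_neurons, np.uint8),
        )


@dataclass(frozen=True)
class SpikeRaster:
    """Binary N x T spike matrix with its time resolution and parameters."""

    spikes: np.ndarray  # uint8, shape (N, T)
    dt: float  # ms
    params_snapshot: ReservoirParams

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def to_event_tsv(self, path: str | Path, seed: int | None = None) -> None:
        """Sparse event dump: one (neuron_id, step) row per spike, 0-based."""
        rows, cols = np.nonzero(self.spikes)
        with open(path, "w") as fh:
            fh.write(f"# dt_ms={self.dt!r} seed={seed} "
                     f"params={self.params_snapshot.to_dict()}\n")
            fh.write("neuron_id\tstep\n")
            for i, t in zip(rows, cols):
                fh.write(f"{i}\t{t}\n")


def _ri_per_neuron(params: ReservoirParams) -> np.ndarray:
    out = np.empty(params.n_neurons)
    pos = 0
    for g in params.input_groups:
        out[pos : pos + g.size] = g.ri
        pos += g.size
    return out


def run_window(
    params: ReservoirParams,
    weights: WeightMatrix,
    state: SimulationState,
    n_steps: int,
    seed: int,
    buffer_refractory: bool = True,
    poisson_events: bool = False,
) -> np.ndarray:
    """Advance ``state`` by ``n_steps`` steps; return the spike block (N, n_steps).

    Lower-level entry point used by the homeostatic loop; :func:`simulate`
    wraps it for one-shot runs.
    """
    if weights.n_neurons != params.n_neurons:
        raise ValueError("weight matrix dimension does not match n_neurons")
    w = weights.weights
    record = np.zeros((params.n_neurons, n_steps), np.uint8)
    lif_steps(
        w.indptr,
        w.indices,
        w.data,
        _ri_per_neuron(params),
        float(params.threshold),
        float(np.exp(-params.alpha * params.dt)),
        params.refractory_steps,
        params.events_per_step,
        n_steps,
        int(seed) % (2**32),
        buffer_refractory,
        poisson_events,
        float(params.dt / params.tau),
        state.potentials,
        state.refractory_remaining,
        state.prev_spiked,
        record,
    )
    state.step_index += n_steps
    if not np.all(np.isfinite(state.potentials)):
        raise FloatingPointError(
            "non-finite membrane potentials: divergent synaptic weights"
        )
    return record


def simulate(
    params: ReservoirParams,
    weights: WeightMatrix,
    n_steps: int,
    seed: int,
    buffer_refractory: bool = True,
    poisson_events: bool = False,
) -> SpikeRaster:
    """Run the network for ``n_steps`` steps from rest.

    Deterministic given ``seed``.  ``buffer_refractory`` selects whether
    refractory neurons keep integrating inputs (default, the reading under
    which the simulated ISI curve matches the mean-field relation) or
    discard them; ``poisson_events`` replaces the deterministic
    ``round(dt/tau)`` external events per step by a Poisson(dt/tau) count.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = SimulationState.fresh(params.n_neurons)
    record = run_window(params, weights, state, n_steps, seed,
                        buffer_refractory=buffer_refractory,
                        poisson_events=poisson_events)
    return SpikeRaster(spikes=record, dt=params.dt, params_snapshot=params)


def spike_count(raster: SpikeRaster) -> int:
    """Total number of spikes in the raster."""
    return int(raster.spikes.sum())


def _pooled_isis_steps(spikes: np.ndarray) -> Iterator[np.ndarray]:
    for row in spikes:
        t = np.flatnonzero(row)
        if t.size >= 2:
            yield np.diff(t)


def mean_isi(raster: SpikeRaster) -> float:
    """Network-pooled mean inter-spike interval in ms.

    All consecutive same-neuron spike-time differences are pooled across the
    network and averaged.  Raises ``ValueError`` when no neuron spikes twice
    (callers sweeping into the silent regime may map this to +inf).
    """
    gaps = list(_pooled_isis_steps(raster.spikes))
    if not gaps:
        raise ValueError("mean ISI undefined: no neuron emitted two spikes")
    return float(np.concatenate(gaps).mean() * raster.dt)
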