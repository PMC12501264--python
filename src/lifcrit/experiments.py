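"""Sweep orchestration: observables vs. mean synaptic weight, and validity
reports across hyperparameter configurations.

A sweep regenerates the topology and simulates ``n_reps`` times per grid
weight with independently derived child seeds, then aggregates medians and
interquartile ranges.  For the complexity observable the peak of the median
normalized LZW curve is located and compared with the closed-form critical
weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .complexity import DEFAULT_N_NULL, raster_complexity
from .params import ReservoirParams
from .simulator import mean_isi, simulate, spike_count
from .soqc import SoqcConfig, run_soqc
from .theory import check_validity, critical_weight
from .topology import TopologyKind, generate_weights

__all__ = ["SweepResult", "sweep", "default_weight_grid", "validity_grid_report", "soqc_grid"]

Observable = Literal["spike_count", "mean_isi", "complexity"]


def child_seed(master_seed: int, weight_index: int, rep: int) -> int:
    """Deterministic per-(weight, replicate) seed: any cell is re-runnable
    on its own from (master_seed, weight_index, rep)."""
    ss = np.random.SeedSequence(
        entropy=(int(master_seed), weight_index + 1, rep)
    )
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class SweepResult:
    """Aggregated outcome of one observable-vs-weight sweep."""

    observable: Observable
    weight_grid: np.ndarray
    values: np.ndarray  # (n_weights, n_reps); NaN marks failed cells
    medians: np.ndarray
    iqrs: np.ndarray
    w_critical: float
    peak_weight: float | None = None
    relative_error_vs_theory: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mean_weight_mV": self.weight_grid,
                "median": self.medians,
                "iqr": self.iqrs,
            }
        )
        for r in range(self.values.shape[1]):
            df[f"rep{r}"] = self.values[:, r]
        return df


def default_weight_grid(params: ReservoirParams, n_points: int = 21,
                        lo: float = 0.5, hi: float = 1.5) -> np.ndarray:
    """Grid of ``n_points`` weights log-spaced over [lo, hi] x W_crit."""
    wc = critical_weight(params)
    return np.geomspace(lo * wc, hi * wc, n_points)


def _observe(observable: Observable, raster, n_null: int, null_seed: int) -> float:
    if observable == "spike_count":
        return float(spike_count(raster))
    if observable == "mean_isi":
        try:
            return mean_isi(raster)
        except ValueError:  # silent network: report +inf, not a failure
            return float("inf")
    if observable == "complexity":
        return raster_complexity(raster, n_null=n_null, seed=null_seed).normalized
    raise ValueError(f"unknown observable: {observable!r}")


def sweep(
    params: ReservoirParams,
    observable: Observable,
    weight_grid: Sequence[float] | np.ndarray | None = None,
    n_reps: int = 4,
    seed: int = 0,
    n_steps: int = 10_000,
    topology_kind: TopologyKind = "small_world",
    n_null: int = DEFAULT_N_NULL,
) -> SweepResult:
    """Simulate ``n_reps`` replicates per grid weight and aggregate.

    Each (weight, replicate) cell regenerates the topology and simulates
    with its own derived seed.  Simulator failures in single cells are
    recorded as NaN and skipped in the aggregation rather than aborting the
    sweep.  For ``observable="complexity"`` the peak of the median curve is
    located (ties broken toward the lower weight) and its relative error
    against the closed-form critical weight is reported.
    """
    if weight_grid is None:
        weight_grid = default_weight_grid(params)
    grid = np.asarray(weight_grid, float)
    if grid.size == 0:
        raise ValueError("weight grid must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    wc = critical_weight(params)
    null_seed = child_seed(seed, -1, 0) % (2**31)

    values = np.full((grid.size, n_reps), np.nan)
    for wi, w in enumerate(grid):
        for rep in range(n_reps):
            s = child_seed(seed, wi, rep)
            try:
                wm = generate_weights(params, topology_kind, float(w), s)
                raster = simulate(params, wm, n_steps, s)
                values[wi, rep] = _observe(observable, raster, n_null, null_seed)
            except (FloatingPointError, ValueError):
                pass  # failed cell stays NaN

    with np.errstate(invalid="ignore"):
        medians = np.nanmedian(values, axis=1)
        q75 = np.nanpercentile(values, 75, axis=1)
        q25 = np.nanpercentile(values, 25, axis=1)
    iqrs = q75 - q25

    peak = rel_err = None
    if observable == "complexity" and np.isfinite(medians).any():
        # argmax returns the first (lowest-weight) index among ties
        peak = float(grid[int(np.nanargmax(medians))])
        rel_err = abs(peak - wc) / wc
    return SweepResult(
        observable=observable,
        weight_grid=grid,
        values=values,
        medians=medians,
        iqrs=iqrs,
        w_critical=wc,
        peak_weight=peak,
        relative_error_vs_theory=rel_err,
    )


def validity_grid_report(
    configs: Sequence[ReservoirParams],
    seed: int = 0,
    n_reps: int = 4,
    n_steps: int = 10_000,
    n_grid: int = 21,
    topology_kind: TopologyKind = "small_world",
) -> pd.DataFrame:
    """Condition values, W_crit, complexity peak and error per configuration.

    Invalid configurations (un-drivable, degenerate graphs, ...) are flagged
    in the table rather than raised.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    rows = []
    for ci, p in enumerate(configs):
        row: dict = {"config_index": ci, "n_neurons": p.n_neurons,
                     "threshold_mV": p.threshold, "ri_mV": p.effective_drive}
        try:
            rep = check_validity(p)
            row.update(
                leak_refractory=rep.leak_refractory_value,
                drive_ratio=rep.drive_ratio_value,
                leak_drive=rep.leak_drive_value,
                all_valid=rep.all_valid,
            )
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                row["w_critical_mV"] = critical_weight(p)
                res = sweep(
                    p,
                    "complexity",
                    n_reps=n_reps,
                    seed=child_seed(seed, ci, 0),
                    n_steps=n_steps,
                    weight_grid=default_weight_grid(p, n_grid),
                    topology_kind=topology_kind,
                )
            row["peak_weight_mV"] = res.peak_weight
            row["relative_error"] = res.relative_error_vs_theory
        except (ValueError, FloatingPointError) as exc:
            row["all_valid"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def soqc_grid(
    thresholds: Sequence[float],
    drives: Sequence[float],
    seed: int = 0,
    n_updates: int = 2000,
    gamma: float = 0.1,
    initial_mean_weight: float = 0.5,
    params_factory=None,
) -> pd.DataFrame:
    """Run the homeostatic experiment over a (threshold, drive) grid.

    Returns one row per cell with the settled weight, the closed-form
    critical weight and their relative error.
    """
    from .params import soqc_params as _soqc_params

    factory = params_factory or _soqc_params
    rows = []
    for ti, th in enumerate(thresholds):
        for ri_i, ri in enumerate(drives):
            p = factory(threshold=float(th), ri=float(ri))
            cfg = SoqcConfig(
                params=p,
                gamma=gamma,
                initial_mean_weight=initial_mean_weight,
                n_updates=n_updates,
                seed=child_seed(seed, ti, ri_i),
            )
            traj = run_soqc(cfg)
            rows.append(
                {
                    "threshold_mV": th,
                    "ri_mV": ri,
                    "settled_weight_mV": traj.settled_weight,
                    "w_critical_mV": traj.w_critical,
                    "relative_error": traj.final_relative_error,
                }
            )
    return pd.DataFrame(rows)
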