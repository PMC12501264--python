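"""Mean-field theory of the LIF reservoir and its critical point.

The mean-field approximation replaces per-synapse weights, per-neuron
in-degrees and per-neuron inter-spike intervals (ISIs) by their population
averages <W>, beta*N and <Delta>.  The average membrane potential then obeys
a scalar linear ODE whose periodicity condition <v(<Delta>)> = theta yields a
closed-form relation <W>(<Delta>) for the leaky network.  In the regime
alpha*<Delta> << 1 this relation collapses onto the leak-free one, which is
analytically invertible; the weight at which the inverse branch
<Delta>(<W>) is steepest — the order/disorder transition of the reservoir —
has the closed form

    W_crit = theta/(beta*N) - 2*R*I*tau_ref/(tau*beta*N**2)

with the matching critical ISI

    Delta_crit = tau_ref * (1 + sqrt(tau*N*theta/(R*I*tau_ref) - 1)).

Three validity conditions bound the regime in which the approximation holds:
alpha*tau_ref < 1/2, theta*tau*N/(R*I*tau_ref) >= 2 and
theta*tau*N*alpha/(R*I) < 1.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .params import ReservoirParams

__all__ = [
    "ConditionReport",
    "CriticalPoint",
    "MeanFieldCurve",
    "check_validity",
    "critical_isi",
    "critical_point",
    "critical_weight",
    "delta_of_w_leakfree",
    "mean_field_curve",
    "mean_potential",
    "w_of_delta_leakfree",
    "w_of_delta_leaky",
]

CurveSource = Literal["leaky_theory", "leakfree_theory", "simulation"]


@dataclass(frozen=True)
class ConditionReport:
    """Values and verdicts of the three mean-field validity conditions."""

    leak_refractory_value: float  # alpha * tau_ref, must be < 1/2
    drive_ratio_value: float  # theta*tau*N/(R I tau_ref), must be >= 2
    leak_drive_value: float  # theta*tau*N*alpha/(R I), must be < 1
    cond_leak_refractory: bool
    cond_drive_ratio: bool
    cond_leak_drive: bool

    @property
    def all_valid(self) -> bool:
        return (
            self.cond_leak_refractory
            and self.cond_drive_ratio
            and self.cond_leak_drive
        )


@dataclass(frozen=True)
class CriticalPoint:
    """Critical mean synaptic weight (mV) and critical mean ISI (ms)."""

    w_critical: float
    isi_critical: float


@dataclass(frozen=True)
class MeanFieldCurve:
    """Sampled (<Delta> in ms, <W> in mV) pairs from theory or simulation."""

    mean_isi: np.ndarray
    mean_weight: np.ndarray
    source: CurveSource

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_isi", np.asarray(self.mean_isi, float))
        object.__setattr__(self, "mean_weight", np.asarray(self.mean_weight, float))
        if self.mean_isi.shape != self.mean_weight.shape:
            raise ValueError("mean_isi and mean_weight must have equal length")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["mean_isi_ms", "mean_weight_mV"])
            for d, wt in zip(self.mean_isi, self.mean_weight):
                w.writerow([repr(float(d)), repr(float(wt))])


def check_validity(params: ReservoirParams) -> ConditionReport:
    """Evaluate the three validity conditions of the mean-field analysis.

    Raises ``ValueError`` if the network has no positive drive (the
    conditions involve 1/I).  Violated conditions are reported, not raised,
    so off-regime parameter sweeps remain runnable.
    """
    ri = params.effective_drive
    if ri <= 0:
        raise ValueError("un-drivable network: effective drive I must be > 0")
    n, th = params.n_neurons, params.threshold
    a = params.alpha * params.tau_ref
    if params.tau_ref > 0:
        b = th * params.tau * n / (ri * params.tau_ref)
    else:
        b = np.inf
    c = th * params.tau * n * params.alpha / ri
    return ConditionReport(
        leak_refractory_value=a,
        drive_ratio_value=b,
        leak_drive_value=c,
        cond_leak_refractory=a < 0.5,
        cond_drive_ratio=b >= 2,
        cond_leak_drive=c < 1,
    )


def _check_isi_domain(mean_isi, params: ReservoirParams) -> np.ndarray:
    d = np.asarray(mean_isi, dtype=float)
    if np.any(d <= params.tau_ref):
        raise ValueError(
            f"mean_isi must exceed tau_ref={params.tau_ref} ms (pole of the relation)"
        )
    return d


def w_of_delta_leaky(mean_isi, params: ReservoirParams):
    """Mean synaptic weight sustaining a given mean ISI, leaky network.

    <W>(<Delta>) = (alpha*theta*D^2/(1-exp(-alpha*D)) - R*I*D^2/(tau*N))
                   / (beta*N*(D - tau_ref))

    Requires ``alpha > 0`` (use :func:`w_of_delta_leakfree` otherwise) and
    ``mean_isi > tau_ref``.  Accepts scalars or arrays.
    """
    if params.alpha <= 0:
        raise ValueError("w_of_delta_leaky requires alpha > 0")
    d = _check_isi_domain(mean_isi, params)
    n, ri = params.n_neurons, params.effective_drive
    num = (
        params.alpha * params.threshold * d**2 / (-np.expm1(-params.alpha * d))
        - ri * d**2 / (params.tau * n)
    )
    out = num / (params.beta * n * (d - params.tau_ref))
    return out if out.ndim else float(out)


def w_of_delta_leakfree(mean_isi, params: ReservoirParams):
    """Mean synaptic weight sustaining a given mean ISI, leak-free limit.

    <W>(<Delta>) = (theta*D - R*I*D^2/(tau*N)) / (beta*N*(D - tau_ref))
    """
    d = _check_isi_domain(mean_isi, params)
    n, ri = params.n_neurons, params.effective_drive
    num = params.threshold * d - ri * d**2 / (params.tau * n)
    out = num / (params.beta * n * (d - params.tau_ref))
    return out if out.ndim else float(out)


def delta_of_w_leakfree(mean_weight, params: ReservoirParams):
    """Mean ISI as a function of mean weight on the valid (physical) branch.

    <Delta>(<W>) = tau*N/(2*R*I) * ((theta - W*beta*N)
                   + sqrt((theta - W*beta*N)^2 + 4*beta*R*I*W*tau_ref/tau))

    Strictly decreasing and > tau_ref whenever theta*tau*N/(R*I*tau_ref) > 1.
    """
    w = np.asarray(mean_weight, dtype=float)
    n, ri = params.n_neurons, params.effective_drive
    a = params.threshold - w * params.beta * n
    disc = a**2 + 4 * params.beta * ri * w * params.tau_ref / params.tau
    if np.any(disc < 0):
        raise ValueError("negative discriminant: weight outside the real branch")
    out = params.tau * n / (2 * ri) * (a + np.sqrt(disc))
    return out if out.ndim else float(out)


def critical_weight(params: ReservoirParams) -> float:
    """Closed-form critical mean synaptic weight (mV).

    W_crit = theta/(beta*N) - 2*R*I*tau_ref/(tau*beta*N^2).  Warns (does not
    fail) when the validity conditions are violated, so that sweeps across
    the validity boundary remain runnable.
    """
    rep = check_validity(params)
    if not rep.all_valid:
        warnings.warn(
            "mean-field validity conditions violated; the critical-weight "
            f"approximation may be unreliable ({rep})",
            stacklevel=2,
        )
    n, ri = params.n_neurons, params.effective_drive
    return params.threshold / (params.beta * n) - 2 * ri * params.tau_ref / (
        params.tau * params.beta * n**2
    )


def critical_isi(params: ReservoirParams) -> float:
    """Closed-form critical mean ISI (ms).

    Delta_crit = tau_ref * (1 + sqrt(tau*N*theta/(R*I*tau_ref) - 1)).
    For tau_ref = 0 the expression degenerates; the limit is returned via
    the leak-free branch at W_crit.
    """
    n, ri = params.n_neurons, params.effective_drive
    if params.tau_ref == 0:
        return delta_of_w_leakfree(critical_weight(params), params)
    arg = params.tau * n * params.threshold / (ri * params.tau_ref) - 1
    if arg < 0:
        raise ValueError(
            "critical ISI undefined: theta*tau*N/(R*I*tau_ref) < 1"
        )
    return params.tau_ref * (1 + np.sqrt(arg))


def critical_point(params: ReservoirParams) -> CriticalPoint:
    """Bundle of critical weight and critical ISI."""
    return CriticalPoint(
        w_critical=critical_weight(params), isi_critical=critical_isi(params)
    )


def mean_potential(t, mean_isi: float, mean_weight: float, params: ReservoirParams):
    """Average membrane potential at time ``t`` ms after reset.

    <v(t)> = (1/alpha) * (R*I/(tau*N)
             + <W>*beta*N/<Delta>*(1 - tau_ref/<Delta>)) * (1 - exp(-alpha*t))

    assuming <v(0)> = v_reset = 0 and alpha > 0.
    """
    if params.alpha <= 0:
        raise ValueError("mean_potential requires alpha > 0")
    if mean_isi <= params.tau_ref:
        raise ValueError("mean_isi must exceed tau_ref")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    n, ri = params.n_neurons, params.effective_drive
    rate = ri / (params.tau * n) + mean_weight * params.beta * n / mean_isi * (
        1 - params.tau_ref / mean_isi
    )
    out = rate / params.alpha * (-np.expm1(-params.alpha * t))
    return out if out.ndim else float(out)


def mean_field_curve(
    params: ReservoirParams,
    mean_isis: Sequence[float] | np.ndarray | None = None,
    source: CurveSource = "leaky_theory",
    n_points: int = 200,
) -> MeanFieldCurve:
    """Sample a theoretical (<Delta>, <W>) curve.

    By default the ISI grid spans (tau_ref, tau*N*theta/(R*I)] — from just
    above the refractory pole out to the zero-weight ISI.
    """
    if mean_isis is None:
        n, ri = params.n_neurons, params.effective_drive
        hi = params.tau * n * params.threshold / ri
        lo = params.tau_ref + (hi - params.tau_ref) / n_points
        mean_isis = np.linspace(lo, hi, n_points)
    d = np.asarray(mean_isis, float)
    if source == "leaky_theory":
        w = w_of_delta_leaky(d, params)
    elif source == "leakfree_theory":
        w = w_of_delta_leakfree(d, params)
    else:
        raise ValueError("mean_field_curve samples theory curves only")
    return MeanFieldCurve(mean_isi=d, mean_weight=np.asarray(w), source=source)
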