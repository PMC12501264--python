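"""Network hyperparameters for the LIF reservoir.

A reservoir is a directed network of *N* leaky integrate-and-fire neurons.
Each neuron fires when its membrane potential reaches the threshold ``theta``
(mV), resets to 0 mV and stays refractory for ``tau_ref`` ms.  External
current kicks of size ``R*I_k`` (mV) are delivered to uniformly chosen
neurons every ``tau`` ms; the network may be partitioned into input groups
with different drive intensities.  ``alpha`` (1/ms) is the membrane leak
rate and ``beta`` the connection-density fraction, so the mean in-degree is
``beta * N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = ["InputGroup", "ReservoirParams", "load_params"]


@dataclass(frozen=True)
class InputGroup:
    """A group of ``size`` neurons each receiving external kicks of ``ri`` mV."""

    size: int
    ri: float


@dataclass(frozen=True)
class ReservoirParams:
    """All hyperparameters of a LIF reservoir.

    Parameters
    ----------
    n_neurons:
        Network size N.
    threshold:
        Firing threshold theta in mV (reset potential is fixed at 0 mV).
    tau_ref:
        Refractory period in ms (>= 0).
    tau:
        Interval between external input events in ms (> 0); one uniformly
        chosen neuron receives a kick every ``tau`` ms.
    alpha:
        Leak rate in 1/ms (>= 0).
    beta:
        Connection-density fraction in (0, 1); mean in-degree is beta*N.
    input_groups:
        Partition of the network into drive groups; sizes must sum to N and
        every non-zero drive must satisfy 0 < ri < threshold.  The default
        (``None``) is a single group with ``ri = 1`` mV.
    dt:
        Simulation step in ms.
    """

    n_neurons: int
    threshold: float
    tau_ref: float
    tau: float
    alpha: float
    beta: float
    input_groups: tuple[InputGroup, ...] = field(default=None)  # type: ignore[assignment]
    dt: float = 0.1
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if self.input_groups is None:
            object.__setattr__(
                self, "input_groups", (InputGroup(self.n_neurons, 1.0),)
            )
        else:
            object.__setattr__(
                self,
                "input_groups",
                tuple(
                    g if isinstance(g, InputGroup) else InputGroup(*g)
                    for g in self.input_groups
                ),
            )
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be a positive integer")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_ref > 0 and self.dt > self.tau_ref:
            raise ValueError(
                "dt must not exceed tau_ref: the step has to resolve the "
                "refractory period"
            )
        if self.v_reset != 0.0:
            raise ValueError("the model fixes the reset potential at 0 mV")
        sizes = sum(g.size for g in self.input_groups)
        if sizes != self.n_neurons:
            raise ValueError(
                f"input group sizes sum to {sizes}, expected N={self.n_neurons}"
            )
        for g in self.input_groups:
            if g.size < 0:
                raise ValueError("group sizes must be non-negative")
            if g.ri != 0 and not 0 < g.ri < self.threshold:
                raise ValueError(
                    "every non-zero group drive must satisfy 0 < R*I_k < theta"
                )
        # a network with zero total drive is constructible (the simulator can
        # run it); the mean-field theory rejects it via check_validity

    @property
    def effective_drive(self) -> float:
        """Population-averaged drive I = sum(n_k * RI_k) / N in mV."""
        return sum(g.size * g.ri for g in self.input_groups) / self.n_neurons

    @property
    def refractory_steps(self) -> int:
        """Number of simulation steps spanned by the refractory period."""
        import math

        return int(math.ceil(self.tau_ref / self.dt)) if self.tau_ref > 0 else 0

    @property
    def events_per_step(self) -> int:
        """External input events delivered per simulation step, round(dt/tau)."""
        return max(0, round(self.dt / self.tau))

    def with_(self, **changes) -> "ReservoirParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "threshold": self.threshold,
            "tau_ref": self.tau_ref,
            "tau": self.tau,
            "alpha": self.alpha,
            "beta": self.beta,
            "input_groups": [[g.size, g.ri] for g in self.input_groups],
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReservoirParams":
        d = dict(d)
        groups = d.pop("input_groups", None)
        # flat single-drive shorthand: "ri": 1.0
        ri = d.pop("ri", None)
        if groups is None and ri is not None:
            groups = [[d["n_neurons"], ri]]
        return cls(
            n_neurons=int(d["n_neurons"]),
            threshold=float(d["threshold"]),
            tau_ref=float(d["tau_ref"]),
            tau=float(d["tau"]),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            input_groups=tuple(tuple(g) for g in groups) if groups else None,
            dt=float(d.get("dt", 0.1)),
        )


def load_params(path: str | Path) -> ReservoirParams:
    """Read reservoir parameters from a flat JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return ReservoirParams.from_dict(d)


def methods_params(**overrides) -> ReservoirParams:
    """The main experimental configuration: N=1000, theta=5 mV, tau_ref=1 ms,
    tau=0.01 ms, alpha=0.01 /ms, beta=0.1, uniform drive RI=1 mV, dt=0.1 ms."""
    base = dict(
        n_neurons=1000,
        threshold=5.0,
        tau_ref=1.0,
        tau=0.01,
        alpha=0.01,
        beta=0.1,
        input_groups=((1000, 1.0),),
        dt=0.1,
    )
    if "n_neurons" in overrides and "input_groups" not in overrides:
        n = overrides["n_neurons"]
        base["input_groups"] = ((n, 1.0),)
    base.update(overrides)
    return ReservoirParams(**base)


def soqc_params(threshold: float = 10.0, ri: float = 2.0, **overrides) -> ReservoirParams:
    """The self-organized quasi-criticality configuration: N=1000, tau=0.1 ms,
    alpha=1e-4 /ms, tau_ref=1 ms, beta=0.1, dt=0.1 ms; threshold and drive vary."""
    base = dict(
        n_neurons=1000,
        threshold=threshold,
        tau_ref=1.0,
        tau=0.1,
        alpha=1e-4,
        beta=0.1,
        input_groups=((1000, ri),),
        dt=0.1,
    )
    if "n_neurons" in overrides and "input_groups" not in overrides:
        n = overrides["n_neurons"]
        base["input_groups"] = ((n, ri),)
    base.update(overrides)
    return ReservoirParams(**base)
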