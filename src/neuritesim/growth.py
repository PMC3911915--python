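"""Growth-cone kinetics: elongation, retraction, forced replay.

A neurite elongates at a rate set by the tubulin concentration C in
its growth-cone compartment,

    dL/dt = m * p * C - q

where p is the microtubule polymerization rate, q the (concentration-
independent) depolymerization rate, and m a per-growth-cone multiplier
used to perturb polymerization (m = 1.5 is a "+50%" perturbation).
Negative rates retract the neurite.  Elongation consumes tubulin from
the growth-cone compartment (X per metre grown) and retraction
releases it there — depolymerized tubulin becomes free again.

The growth cone compartment itself keeps a constant size; the shaft
compartment directly proximal to it stretches or shrinks and is
remeshed by the morphology layer.  In forced (replay) mode a growth
cone follows a recorded path-length trace instead of the rate law; a
forced step that would require more tubulin than the growth cone holds
is skipped, leaving the length unchanged for that step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .morphology import CompartmentTree
from .transport import TransportParameters
from .units import MINUTE, UM

__all__ = [
    "GrowthConeState",
    "PerturbationEvent",
    "GrowthTrace",
    "elongation_rate",
    "grow_step",
    "forced_growth_step",
    "apply_perturbation",
    "read_trace",
    "write_trace",
]

FREE = "free"
FORCED = "forced"


@dataclass
class GrowthConeState:
    """Per-growth-cone dynamic state."""

    compartment_id: int
    poly_rate_multiplier: float = 1.0
    mode: str = FREE  # 'free' or 'forced'
    trace: "GrowthTrace | None" = None

    def __post_init__(self) -> None:
        if self.poly_rate_multiplier <= 0:
            raise ValueError("poly_rate_multiplier must be positive")
        if self.mode not in (FREE, FORCED):
            raise ValueError("mode must be 'free' or 'forced'")
        if self.mode == FORCED and self.trace is None:
            raise ValueError("forced mode requires a trace")


@dataclass(frozen=True)
class PerturbationEvent:
    """At ``time`` [s], set growth cone ``growth_cone_id``'s
    polymerization multiplier to ``new_multiplier``."""

    time: float
    growth_cone_id: int
    new_multiplier: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.new_multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclass
class GrowthTrace:
    """Observed (or synthetic) soma-to-tip path length versus time."""

    times: np.ndarray  # [s], strictly increasing
    path_lengths: np.ndarray  # [m], >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.path_lengths = np.asarray(self.path_lengths, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.path_lengths.shape:
            raise ValueError("times and path_lengths must be 1-D and equal length")
        if self.times.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.path_lengths < 0):
            raise ValueError("path lengths must be non-negative")

    def length_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation; held constant beyond either end."""
        return np.interp(t, self.times, self.path_lengths)


def elongation_rate(
    conc: float, p: float, q: float, multiplier: float = 1.0
) -> float:
    """Neurite elongation rate [m/s]: ``multiplier * p * conc - q``.

    ``conc`` in mol/m^3 (== mM), ``p`` in m/(s*mM), ``q`` in m/s.  The
    result is negative (retraction) below conc = q / (multiplier * p).
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return multiplier * p * conc - q


def apply_perturbation(
    growth_cones: dict[int, GrowthConeState], event: PerturbationEvent
) -> dict[int, GrowthConeState]:
    """Set the target growth cone's multiplier; all others untouched."""
    if event.growth_cone_id not in growth_cones:
        raise KeyError(f"unknown growth cone id {event.growth_cone_id}")
    growth_cones[event.growth_cone_id].poly_rate_multiplier = event.new_multiplier
    return growth_cones


def grow_step(
    tree: CompartmentTree,
    gc: GrowthConeState,
    params: TransportParameters,
    dt: float,
) -> CompartmentTree:
    """Advance one free-growth step for one growth cone (including the
    tubulin ledger update and remeshing).  Mutates and returns ``tree``."""
    from .simulate import Simulator

    if gc.mode != FREE:
        raise ValueError("grow_step requires a free-mode growth cone")
    sim = Simulator(tree, params, growth_cones={gc.compartment_id: gc})
    sim.growth_step(dt)
    sim.remesh()
    sim.writeback()
    return tree


def forced_growth_step(
    tree: CompartmentTree,
    gc: GrowthConeState,
    trace: GrowthTrace,
    t: float,
    dt: float,
    params: TransportParameters | None = None,
) -> CompartmentTree:
    """Advance one forced-replay step: move the growth cone toward the
    trace's path length at ``t + dt``.  Elongation with insufficient
    tubulin is skipped; retraction always proceeds and releases tubulin.
    Mutates and returns ``tree``."""
    from .simulate import Simulator

    params = params or TransportParameters()
    state = GrowthConeState(
        compartment_id=gc.compartment_id,
        poly_rate_multiplier=gc.poly_rate_multiplier,
        mode=FORCED,
        trace=trace,
    )
    sim = Simulator(tree, params, growth_cones={gc.compartment_id: state})
    sim.time = t
    sim.growth_step(dt)
    sim.remesh()
    sim.writeback()
    return tree


# ---------------------------------------------------------------------
# trace I/O: two-column text, time [minutes] and path length [um]
# ---------------------------------------------------------------------


def write_trace(trace: GrowthTrace, path: str | Path) -> None:
    """Write a trace as two-column text (time_minutes, path_length_micron)."""
    with open(path, "w") as fh:
        fh.write("# time_minutes\tpath_length_micron\n")
        for t, length in zip(trace.times, trace.path_lengths):
            fh.write(f"{t / MINUTE:.6f}\t{length / UM:.6f}\n")


def read_trace(path: str | Path) -> GrowthTrace:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (minutes, microns)")
    return GrowthTrace(times=data[:, 0] * MINUTE, path_lengths=data[:, 1] * UM)
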