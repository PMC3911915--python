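"""Experiment protocols: perturbation runs, sweeps, replay fitting.

Three suites are provided, mirroring how competitive outgrowth is
usually probed:

* **Perturbation on a Y-morphology** — grow a soma + trunk + two-branch
  tree, then raise the polymerization rate in one growth cone and watch
  the sibling branch retract; sweeps over the diffusion constant, the
  active-transport rate, and the (d_A, d_B) geometry quantify how
  competition depends on transport and path distances.
* **Perturbation on a complex tree** — the same protocol on a branched
  morphology, summarised by the total relative retraction statistic
  (summed retraction of unperturbed tips divided by the extra growth of
  the perturbed tip, both against a control run).
* **Forced-growth replay** — some neurites are forced to follow
  recorded path-length traces (consuming and releasing tubulin as they
  go) while a free neurite obeys the model; an exhaustive grid search
  over (D, v, b, soma concentration) minimises the RMS deviation of the
  free neurite from its observed trace.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import (
    FORCED,
    FREE,
    GrowthConeState,
    GrowthTrace,
    PerturbationEvent,
    apply_perturbation,
)
from .morphology import (
    CompartmentTree,
    YTreeSpec,
    build_branched_fixture,
    build_star_tree,
    build_y_tree,
    read_swc,
    set_uniform_concentration,
)
from .simulate import MassLedger, Simulator
from .transport import TransportParameters
from .units import HOUR, MINUTE, UM, UMOLAR, molar_conc_to_um

__all__ = [
    "Protocol",
    "SimulationResult",
    "GridSearchSpec",
    "run_simulation",
    "competition_sweep",
    "total_relative_retraction",
    "error_measure",
    "grid_search_fit",
    "make_synthetic_traces",
    "steady_state_profile",
    "write_timeseries_csv",
    "dendrogram_table",
]


@dataclass
class Protocol:
    """Everything needed to reproduce one simulation run."""

    tree_source: CompartmentTree | YTreeSpec | str | Path
    duration: float  # [s]
    params: TransportParameters = field(default_factory=TransportParameters)
    burn_in: float = 0.0  # [s] time before the (first) perturbation
    events: list[PerturbationEvent] = field(default_factory=list)
    forced_traces: dict[int, GrowthTrace] = field(default_factory=dict)
    output_interval: float = 300.0  # [s]
    initial_concentration: float | None = None  # default: clamp value
    growth_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.output_interval > self.duration:
            raise ValueError("output_interval must not exceed duration")

    def build_tree(self) -> CompartmentTree:
        src = self.tree_source
        if isinstance(src, CompartmentTree):
            return src.copy()
        if isinstance(src, YTreeSpec):
            return build_y_tree(src)
        if src == "branched":
            return build_branched_fixture()
        return read_swc(src)


@dataclass
class SimulationResult:
    """Recorded time series of one run (SI units internally)."""

    times: np.ndarray  # [s], shape (T,)
    gc_ids: list[int]
    lengths: np.ndarray  # [m], shape (T, G): soma-to-tip path lengths
    concentrations: np.ndarray  # [mol/m^3], shape (T, G): growth-cone conc
    ledger: MassLedger
    final_tree: CompartmentTree
    protocol: Protocol

    def gc_column(self, gc_id: int) -> int:
        return self.gc_ids.index(gc_id)

    def length_series(self, gc_id: int) -> np.ndarray:
        return self.lengths[:, self.gc_column(gc_id)]

    def length_at(self, gc_id: int, t: float) -> float:
        return float(np.interp(t, self.times, self.length_series(gc_id)))

    def trace_of(self, gc_id: int) -> GrowthTrace:
        return GrowthTrace(self.times.copy(), self.length_series(gc_id).copy())


def run_simulation(protocol: Protocol) -> SimulationResult:
    """Run one protocol to completion.  Deterministic: identical
    protocols produce bit-identical results.

    Event ordering within a step: transport -> growth -> remesh ->
    (soma clamp is part of transport) -> record.
    """
    tree = protocol.build_tree()
    p = protocol.params
    c0 = (
        p.c_soma if protocol.initial_concentration is None
        else protocol.initial_concentration
    )
    set_uniform_concentration(tree, c0)
    if p.soma_clamp:
        tree.soma.tubulin_quantity = p.c_soma * tree.soma.volume

    growth_cones: dict[int, GrowthConeState] = {}
    if protocol.growth_enabled:
        for gc_id in tree.growth_cone_ids:
            if gc_id in protocol.forced_traces:
                growth_cones[gc_id] = GrowthConeState(
                    gc_id, mode=FORCED, trace=protocol.forced_traces[gc_id]
                )
            else:
                growth_cones[gc_id] = GrowthConeState(gc_id, mode=FREE)

    sim = Simulator(tree, p, growth_cones)
    gc_ids = tree.growth_cone_ids
    events = sorted(protocol.events, key=lambda e: (e.time, e.growth_cone_id))
    pending = list(events)

    n_steps = int(round(protocol.duration / p.dt))
    record_every = max(1, int(round(protocol.output_interval / p.dt)))

    times = [0.0]
    lengths = [[sim.neurite_length_of(g) for g in gc_ids]]
    concs = [_gc_concentrations(sim, gc_ids)]

    for k in range(n_steps):
        while pending and pending[0].time <= sim.time + 1e-9:
            apply_perturbation(sim.growth_cones, pending.pop(0))
        sim.step()
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append(sim.time)
            lengths.append([sim.neurite_length_of(g) for g in gc_ids])
            concs.append(_gc_concentrations(sim, gc_ids))

    sim.writeback()
    return SimulationResult(
        times=np.array(times),
        gc_ids=gc_ids,
        lengths=np.array(lengths),
        concentrations=np.array(concs),
        ledger=sim.ledger,
        final_tree=tree,
        protocol=protocol,
    )


def _gc_concentrations(sim: Simulator, gc_ids: list[int]) -> list[float]:
    out = []
    for g in gc_ids:
        k = sim.idx[g]
        out.append(sim.quantity[k] / (sim.area[k] * sim.length[k]))
    return out


# ---------------------------------------------------------------------
# Y-tree perturbation sweeps
# ---------------------------------------------------------------------


def _control_of(protocol: Protocol) -> Protocol:
    return replace(protocol, events=[])


def _y_protocol_for(
    base: Protocol, spec: YTreeSpec, multiplier: float | None = None
) -> Protocol:
    """Rebuild a Y-tree protocol for a new geometry, retargeting the
    perturbation onto the first growth cone of the new tree."""
    tree = build_y_tree(spec)
    mod_gc = tree.growth_cone_ids[0]
    mult = multiplier
    if mult is None:
        mult = base.events[0].new_multiplier if base.events else 1.5
    t0 = base.events[0].time if base.events else base.burn_in
    events = [PerturbationEvent(t0, mod_gc, mult)]
    return replace(base, tree_source=spec, events=events)


def competition_sweep(
    base_protocol: Protocol,
    axis: str,
    grid,
    readout_time: float | None = None,
) -> pd.DataFrame:
    """Sweep one axis of the Y-tree perturbation experiment.

    ``axis`` is one of ``'D'`` (diffusion constant, m^2/s), ``'v'``
    (active transport speed, m/s) or ``'d_AxB'`` (an iterable of
    (d_A, d_B) tuples in metres, rebuilding the tree per point).  Each
    row reports the modified and neighbouring branch lengths at the
    read-out time, the neighbour's length change since the perturbation,
    and the neighbour's retraction relative to a control run without
    the perturbation.  Failures are recorded per row (NaN) and the
    sweep continues.
    """
    if axis not in ("D", "v", "d_AxB"):
        raise ValueError("axis must be 'D', 'v' or 'd_AxB'")
    if not base_protocol.events:
        raise ValueError("base protocol must define the perturbation event")
    rows = []
    for point in grid:
        if axis == "d_AxB":
            d_a, d_b = point
            spec = (
                replace(base_protocol.tree_source, d_a=d_a, d_b=d_b)
                if isinstance(base_protocol.tree_source, YTreeSpec)
                else YTreeSpec(d_a=d_a, d_b=d_b)
            )
            proto = _y_protocol_for(base_protocol, spec)
            label = {"d_A": d_a, "d_B": d_b}
        elif axis == "D":
            proto = replace(
                base_protocol, params=base_protocol.params.with_(diffusion=point)
            )
            label = {"D": point}
        else:
            proto = replace(
                base_protocol, params=base_protocol.params.with_(active_speed=point)
            )
            label = {"v": point}
        try:
            row = _competition_row(proto, readout_time)
        except Exception as exc:  # keep sweeping; record the failure
            warnings.warn(f"sweep point {label} failed: {exc}")
            row = {
                "length_modified": np.nan,
                "length_neighbor": np.nan,
                "neighbor_change_since_perturbation": np.nan,
                "neighbor_retraction_vs_control": np.nan,
            }
        rows.append({**label, **row})
    return pd.DataFrame(rows)


def _competition_row(protocol: Protocol, readout_time: float | None) -> dict:
    t_read = protocol.duration if readout_time is None else readout_time
    t_pert = protocol.events[0].time
    mod_gc = protocol.events[0].growth_cone_id
    perturbed = run_simulation(protocol)
    control = run_simulation(_control_of(protocol))
    neighbors = [g for g in perturbed.gc_ids if g != mod_gc]
    neigh = neighbors[0]
    l_mod = perturbed.length_at(mod_gc, t_read)
    l_nb = perturbed.length_at(neigh, t_read)
    return {
        "length_modified": l_mod,
        "length_neighbor": l_nb,
        "neighbor_change_since_perturbation": l_nb
        - perturbed.length_at(neigh, t_pert),
        "neighbor_retraction_vs_control": control.length_at(neigh, t_read) - l_nb,
    }


def total_relative_retraction(
    control: SimulationResult, perturbed: SimulationResult, modified_gc: int
) -> float:
    """Summed retraction of all unperturbed tips, relative to the
    control run at the same horizon, divided by the extra growth of the
    modified growth cone.  Non-negative; raises if the modified branch
    did not outgrow its control."""
    if control.gc_ids != perturbed.gc_ids:
        raise ValueError("control and perturbed runs must share the tree")
    t = float(min(control.times[-1], perturbed.times[-1]))
    growth = perturbed.length_at(modified_gc, t) - control.length_at(modified_gc, t)
    if growth <= 0:
        raise ValueError("modified growth cone did not grow; metric undefined")
    retraction = 0.0
    for g in control.gc_ids:
        if g == modified_gc:
            continue
        retraction += max(0.0, control.length_at(g, t) - perturbed.length_at(g, t))
    return retraction / growth


# ---------------------------------------------------------------------
# forced-replay fitting
# ---------------------------------------------------------------------


def error_measure(simulated: GrowthTrace, observed: GrowthTrace) -> float:
    """Replay error [m]: square root of the summed squared deviation of
    the simulated path length from the observed one at each observed
    sample time."""
    if observed.times.size == 0:
        raise ValueError("empty observed trace")
    if (
        observed.times[0] < simulated.times[0] - 1e-9
        or observed.times[-1] > simulated.times[-1] + 1e-9
    ):
        raise ValueError("observed times outside the simulated support")
    sim_at = simulated.length_at(observed.times)
    return float(np.sqrt(np.sum((sim_at - observed.path_lengths) ** 2)))


@dataclass
class GridSearchSpec:
    """Exhaustive-search grids (SI units) for the replay fit.

    Default ranges: D in 1e-13..0.5e-10 m^2/s (log-spaced), v in
    0..440e-7 m/s (linear, including zero), b in 5.67e-7..5.67e-4 1/s
    (log-spaced), soma concentration 5.5..50 uM (linear).
    """

    traces: dict[int, GrowthTrace]  # observed trace per growth cone
    free_gc: int  # the growth cone left to the model
    d_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-13, 0.5e-10, 8)
    )
    v_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 440e-7, 8)
    )
    b_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(5.67e-7, 5.67e-4, 8)
    )
    c_soma_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(5.5e-3, 50e-3, 8)
    )
    max_points: int = 10000

    def __post_init__(self) -> None:
        if self.free_gc not in self.traces:
            raise ValueError("free growth cone needs an observed trace")
        n = (
            len(self.d_grid)
            * len(self.v_grid)
            * len(self.b_grid)
            * len(self.c_soma_grid)
        )
        if n > self.max_points:
            raise ValueError(
                f"grid of {n} points exceeds the cap of {self.max_points}"
            )
        if n > 2000:
            warnings.warn(f"large grid: {n} simulations will be run")


def grid_search_fit(spec: GridSearchSpec, protocol: Protocol) -> pd.DataFrame:
    """Evaluate every grid point with the replay protocol (all growth
    cones forced except ``spec.free_gc``) and rank by replay error.

    Returns a DataFrame with columns D, v, b, c_soma, error [m], sorted
    by error (stable in grid order on ties).  A failed simulation gets
    infinite error.
    """
    forced = {g: tr for g, tr in spec.traces.items() if g != spec.free_gc}
    observed = spec.traces[spec.free_gc]
    rows = []
    for d, v, b, c in itertools.product(
        spec.d_grid, spec.v_grid, spec.b_grid, spec.c_soma_grid
    ):
        params = protocol.params.with_(
            diffusion=float(d), active_speed=float(v), decay=float(b),
            c_soma=float(c),
        )
        proto = replace(protocol, params=params, forced_traces=forced, events=[])
        try:
            result = run_simulation(proto)
            err = error_measure(result.trace_of(spec.free_gc), observed)
        except Exception as exc:
            warnings.warn(f"grid point (D={d:g}, v={v:g}, b={b:g}, c={c:g}) "
                          f"failed: {exc}")
            err = np.inf
        rows.append({"D": d, "v": v, "b": b, "c_soma": c, "error": err})
    table = pd.DataFrame(rows)
    return table.sort_values("error", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------
# synthetic growth traces
# ---------------------------------------------------------------------

# onsets of the three neurites in the time-lapse recording emulated by
# the "culture-like" template [minutes]
TRACE_ONSETS_MIN = (0.0, 980.0, 1650.0)
TRACE_DURATION_MIN = 3000.0
TRACE_SAMPLE_MIN = 10.0


def make_synthetic_traces(
    seed: int = 0,
    template: str = "culture-like",
    params: TransportParameters | None = None,
    initial_length: float = 2.0e-6,
) -> list[GrowthTrace]:
    """Three synthetic growth-cone traces with staggered onsets at 0,
    980 and 1650 minutes.

    ``'culture-like'`` emulates a developing neuron in culture: the
    first two neurites grow out and stall, the third grows slowly and
    then exhibits a late growth spurt at the expense of the others.
    ``'model-generated'`` instead runs the simulator on a three-neurite
    star morphology with ``params`` and records the true model traces
    (useful for parameter-recovery tests).  Deterministic per seed.
    """
    if template == "model-generated":
        proto = Protocol(
            tree_source=build_star_tree(3, initial_length),
            duration=TRACE_DURATION_MIN * MINUTE,
            params=params or TransportParameters(),
            output_interval=TRACE_SAMPLE_MIN * MINUTE,
            seed=seed,
        )
        result = run_simulation(proto)
        return [result.trace_of(g) for g in result.gc_ids]
    if template != "culture-like":
        raise ValueError("template must be 'culture-like' or 'model-generated'")

    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, TRACE_DURATION_MIN + 0.5, TRACE_SAMPLE_MIN)
    l0 = initial_length / UM

    # piecewise-linear skeletons [minutes -> um]
    skeletons = [
        # first neurite: grows out immediately, then stalls, slight
        # late give-back during the third neurite's spurt
        ([0, 900, 2400, 3000], [l0, 55.0, 54.0, 50.0]),
        # second neurite: onset 980 min, grows in parallel, stalls,
        # retracts a little at the end
        ([0, 980, 1600, 2400, 3000], [l0, l0, 40.0, 40.5, 36.0]),
        # third neurite: onset 1650 min, slow start, late growth spurt
        ([0, 1650, 2400, 3000], [l0, l0, 12.0, 60.0]),
    ]
    traces = []
    for onset, (tk, lk) in zip(TRACE_ONSETS_MIN, skeletons):
        base = np.interp(t_min, tk, lk)
        noise = rng.normal(0.0, 0.35, t_min.size)
        # smooth the jitter so the trace looks like tracked positions
        kernel = np.ones(5) / 5.0
        noise = np.convolve(noise, kernel, mode="same")
        noise[t_min <= onset] = 0.0
        lengths = np.maximum(base + noise, 0.3 * l0)
        traces.append(GrowthTrace(t_min * MINUTE, lengths * UM))
    return traces


# ---------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------


def steady_state_profile(
    x: np.ndarray, cable_length: float, params: TransportParameters
) -> np.ndarray:
    """Closed-form steady state of a sealed unbranched cable with a
    clamped concentration at x = 0 and no active transport:

        C(x) = C_soma * cosh((L - x)/lambda) / cosh(L/lambda),
        lambda = sqrt(D / b)

    With b = 0 the profile is uniform at the clamp value.
    """
    x = np.asarray(x, dtype=float)
    if params.decay == 0.0:
        return np.full_like(x, params.c_soma)
    lam = np.sqrt(params.diffusion / params.decay)
    return (
        params.c_soma
        * np.cosh((cable_length - x) / lam)
        / np.cosh(cable_length / lam)
    )


# ---------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------


def write_timeseries_csv(result: SimulationResult, path: str | Path) -> None:
    """Tidy per-growth-cone time series: time_h, growth_cone,
    path_length_um, concentration_uM."""
    frames = []
    for j, g in enumerate(result.gc_ids):
        frames.append(
            pd.DataFrame(
                {
                    "time_h": result.times / HOUR,
                    "growth_cone": g,
                    "path_length_um": result.lengths[:, j] / UM,
                    "concentration_uM": result.concentrations[:, j] / UMOLAR,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6f"
    )


def dendrogram_table(tree: CompartmentTree) -> pd.DataFrame:
    """Per-compartment path intervals and concentrations, enough to
    draw a branch-length-preserving dendrogram colored by tubulin."""
    rows = []
    for cid in sorted(tree.compartments):
        comp = tree.compartments[cid]
        if comp.kind == "soma":
            continue
        end = tree.depth(cid)
        rows.append(
            {
                "compartment": cid,
                "parent": comp.parent_id,
                "path_start_um": (end - comp.length) / UM,
                "path_end_um": end / UM,
                "diameter_um": comp.diameter / UM,
                "concentration_uM": molar_conc_to_um(comp.concentration),
                "kind": comp.kind,
            }
        )
    return pd.DataFrame(rows)
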