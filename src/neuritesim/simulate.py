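"""Stepping engine coupling transport, growth and remeshing.

The engine keeps a flat array view of the compartment tree (quantities,
lengths, interface geometry) and assembles the linear transport
operator as a sparse matrix each step; topology changes (compartment
splits and merges) trigger a cheap rebuild of the array view.  One full
step is, in order: transport -> growth -> remesh -> soma clamp
(inside transport) -> record, i.e. first-order operator splitting with
the growth law evaluated at the post-transport concentration.

A mass ledger tracks production (mass injected by the soma clamp),
decay, and growth consumption, so that

    initial_total + produced - decayed - consumed == current total

holds to machine precision at every step; positivity guards (a growth
cone cannot consume more tubulin than it holds) are counted in the
ledger rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .growth import FORCED, FREE, GrowthConeState, elongation_rate
from .morphology import (
    GROWTH_CONE,
    SOMA,
    CompartmentTree,
    _remesh_events,
)
from .transport import TransportParameters

__all__ = ["Simulator", "MassLedger", "NumericalError"]


class NumericalError(RuntimeError):
    """Raised when the integrator detects an unstable update."""


@dataclass
class MassLedger:
    """Cumulative tubulin bookkeeping [mol] and event counters."""

    initial_total: float = 0.0
    produced: float = 0.0
    decayed: float = 0.0
    consumed: float = 0.0  # net: growth consumes (+), retraction releases (-)
    capped_growth_events: int = 0
    skipped_forced_steps: int = 0
    n_splits: int = 0
    n_merges: int = 0

    def expected_total(self) -> float:
        return self.initial_total + self.produced - self.decayed - self.consumed


class Simulator:
    """Advance a compartment tree in time under the transport and
    growth dynamics given by ``params``.

    ``growth_cones`` maps growth-cone compartment id to its
    :class:`~neuritesim.growth.GrowthConeState`; growth cones without a
    state entry are sealed tips (no growth, no consumption).
    """

    def __init__(
        self,
        tree: CompartmentTree,
        params: TransportParameters,
        growth_cones: dict[int, GrowthConeState] | None = None,
    ) -> None:
        tree.validate()
        self.tree = tree
        self.params = params
        self.growth_cones = dict(growth_cones or {})
        self.time = 0.0
        self.ledger = MassLedger(initial_total=tree.total_tubulin())
        self._lu = None  # cached factorization, valid while geometry is static
        self._rebuild()

    # -- array view ----------------------------------------------------

    def _rebuild(self) -> None:
        """Re-derive the flat array view from the tree (after topology
        changes)."""
        tree = self.tree
        self.ids = sorted(tree.compartments)
        self.idx = {cid: k for k, cid in enumerate(self.ids)}
        n = len(self.ids)
        comps = [tree.compartments[cid] for cid in self.ids]
        self.length = np.array([c.length for c in comps])
        self.area = np.array([c.cross_section_area for c in comps])
        self.quantity = np.array([c.tubulin_quantity for c in comps])
        self.parent = np.array(
            [self.idx[c.parent_id] if c.parent_id is not None else -1 for c in comps],
            dtype=np.intp,
        )
        self.is_soma = np.array([c.kind == SOMA for c in comps])
        self.soma_idx = self.idx[tree.soma_id]
        self.soma_volume = tree.soma.volume
        self.soma_radius = tree.soma.half_length
        self.is_gc = np.array([c.kind == GROWTH_CONE for c in comps])

        # edges: one per non-root compartment, child <- parent
        self.e_child = np.flatnonzero(self.parent >= 0)
        self.e_parent = self.parent[self.e_child]
        if self.params.interface_area == "mean":
            self.e_area = 0.5 * (self.area[self.e_child] + self.area[self.e_parent])
        else:  # 'distal': the child's cross-section limits the interface
            self.e_area = self.area[self.e_child]

        # fixed sparsity pattern: 4 diffusion + 2 advection entries per
        # edge plus a decay/identity diagonal
        ec, ep = self.e_child, self.e_parent
        diag = np.arange(n)
        self._rows = np.concatenate([ec, ec, ep, ep, ec, ep, diag])
        self._cols = np.concatenate([ec, ep, ep, ec, ep, ep, diag])
        self._soma_row_mask = self._rows == self.soma_idx
        self._lu = None

    def _volumes(self) -> np.ndarray:
        vol = self.area * self.length
        vol[self.soma_idx] = self.soma_volume
        return vol

    def _assemble(self, vol: np.ndarray) -> np.ndarray:
        """Entry data of the transport operator M (dQ/dt = M Q + clamp)."""
        p = self.params
        half = 0.5 * self.length
        half[self.soma_idx] = self.soma_radius
        dist = half[self.e_parent] + half[self.e_child]
        g = p.diffusion * self.e_area / dist  # diffusive conductance [m^3/s]
        a = p.active_fraction * p.active_speed * self.e_area
        v_c = vol[self.e_child]
        v_p = vol[self.e_parent]
        n = len(self.ids)
        return np.concatenate(
            [
                -g / v_c,  # (c,c) diffusion out of child
                g / v_p,  # (c,p) diffusion into child
                -g / v_p,  # (p,p) diffusion out of parent
                g / v_c,  # (p,c) diffusion into parent
                a / v_p,  # (c,p) anterograde advection into child
                -a / v_p,  # (p,p) advection out of parent
                np.full(n, -p.decay),  # decay
            ]
        )

    # -- transport -----------------------------------------------------

    def transport_step(self, dt: float) -> None:
        """One transport update of ``dt`` seconds (diffusion, active
        transport, decay, soma clamp); growth is separate."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        n = len(self.ids)
        vol = self._volumes()
        q_old = self.quantity
        total_old = q_old.sum()

        if p.integrator == "explicit":
            data = self._assemble(vol)
            if p.soma_clamp:
                data = np.where(self._soma_row_mask, 0.0, data)
            m_op = sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsr()
            q_new = q_old + dt * (m_op @ q_old)
            scale = max(q_old.max(), p.c_soma * self.soma_volume)
            if np.any(q_new < -1e-9 * scale):
                k = int(np.argmin(q_new))
                raise NumericalError(
                    f"explicit transport step went negative in compartment "
                    f"{self.ids[k]}; reduce dt (currently {dt} s)"
                )
        else:
            if self._lu is None:
                data = self._assemble(vol)
                if p.soma_clamp:
                    data = np.where(self._soma_row_mask, 0.0, data)
                b_data = -dt * data
                # add identity on the diagonal (last n pattern slots)
                b_data[-n:] += 1.0
                b_op = sp.coo_matrix(
                    (b_data, (self._rows, self._cols)), shape=(n, n)
                ).tocsc()
                self._lu = spla.splu(b_op)
                self._lu_dt = dt
            elif self._lu_dt != dt:
                self._lu = None
                return self.transport_step(dt)
            rhs = q_old.copy()
            if p.soma_clamp:
                rhs[self.soma_idx] = p.c_soma * self.soma_volume
            q_new = self._lu.solve(rhs)
            if np.any(q_new < 0):
                scale = max(q_new.max(), 1e-300)
                if q_new.min() < -1e-9 * scale:
                    k = int(np.argmin(q_new))
                    raise NumericalError(
                        f"transport solve went negative in compartment "
                        f"{self.ids[k]}; reduce dt (currently {dt} s)"
                    )
                q_new = np.maximum(q_new, 0.0)

        if p.soma_clamp:
            q_new[self.soma_idx] = p.c_soma * self.soma_volume
            decayed = p.decay * dt * (
                q_new.sum() - q_new[self.soma_idx]
                if p.integrator != "explicit"
                else q_old.sum() - q_old[self.soma_idx]
            )
        else:
            decayed = p.decay * dt * (
                q_new.sum() if p.integrator != "explicit" else q_old.sum()
            )
        self.quantity = q_new
        self.ledger.decayed += decayed
        # clamp injection booked as somatic production (sole source)
        self.ledger.produced += q_new.sum() - total_old + decayed

    # -- growth --------------------------------------------------------

    def _elongating_idx(self, gc_idx: int) -> int:
        return int(self.parent[gc_idx])

    def neurite_length_of(self, gc_id: int) -> float:
        """Soma-to-tip cable length [m] from the array view."""
        k = self.idx[gc_id]
        total = 0.0
        while k >= 0 and not self.is_soma[k]:
            total += self.length[k]
            k = self.parent[k]
        return total

    def growth_step(self, dt: float) -> None:
        """Apply the growth law (or forced replay) at every registered
        growth cone: update the elongating shaft's length and exchange
        tubulin with the growth-cone compartment."""
        p = self.params
        for gc_id in sorted(self.growth_cones):
            state = self.growth_cones[gc_id]
            gi = self.idx[gc_id]
            vol_gc = self.area[gi] * self.length[gi]
            conc = self.quantity[gi] / vol_gc

            if state.mode == FREE:
                rate = elongation_rate(
                    conc, p.poly_rate, p.depoly_rate, state.poly_rate_multiplier
                )
                dl = rate * dt
                if dl > 0 and p.x_per_length * dl > self.quantity[gi]:
                    dl = self.quantity[gi] / p.x_per_length
                    self.ledger.capped_growth_events += 1
            else:  # forced replay
                target = float(state.trace.length_at(self.time + dt))
                dl = target - self.neurite_length_of(gc_id)
                if dl > 0 and p.x_per_length * dl > self.quantity[gi]:
                    # not enough tubulin: the neurite may not grow out
                    dl = 0.0
                    self.ledger.skipped_forced_steps += 1

            if dl == 0.0:
                continue
            ei = self._elongating_idx(gi)
            if dl < 0:
                # retraction: the elongating shaft may shrink through the
                # merge floor (remeshing absorbs it into its parent), but
                # a neurite is clamped at one floor-length shaft when its
                # shaft's parent is the soma or a branch point
                pe = int(self.parent[ei])
                mergeable = (
                    not self.is_soma[pe]
                    and not self.is_gc[pe]
                    and np.count_nonzero(self.parent == pe) == 1
                )
                floor = 0.5 * p.l_merge if mergeable else p.l_merge
                dl = max(dl, min(0.0, floor - self.length[ei]))
                if dl == 0.0:
                    continue
            self.length[ei] += dl
            self.quantity[gi] -= p.x_per_length * dl
            self.ledger.consumed += p.x_per_length * dl
            self._lu = None  # geometry changed

    # -- remeshing -----------------------------------------------------

    def remesh(self) -> None:
        """Split/merge out-of-range shafts (only elongating shafts can
        drift out of range).  Rebuilds the array view when needed."""
        p = self.params
        needs = False
        for gc_id in self.tree.growth_cone_ids:
            ei = self._elongating_idx(self.idx[gc_id])
            if self.is_soma[ei]:
                continue
            if not (p.l_merge <= self.length[ei] <= p.l_split * (1 + 1e-12)):
                needs = True
                break
        if not needs:
            return
        self.writeback()
        n_split, n_merge = _remesh_events(self.tree, p.l_split, p.l_merge)
        self.ledger.n_splits += n_split
        self.ledger.n_merges += n_merge
        self._rebuild()

    # -- full step and synchronization ---------------------------------

    def step(self, dt: float | None = None) -> None:
        """One full operator-split step: transport, growth, remesh."""
        dt = self.params.dt if dt is None else dt
        self.transport_step(dt)
        if self.growth_cones:
            self.growth_step(dt)
            self.remesh()
        self.time += dt

    def writeback(self) -> CompartmentTree:
        """Push the array state back into the tree and return it."""
        for k, cid in enumerate(self.ids):
            comp = self.tree.compartments[cid]
            comp.tubulin_quantity = float(self.quantity[k])
            if not self.is_soma[k]:
                comp.length = float(self.length[k])
        return self.tree

    def total_tubulin(self) -> float:
        return float(self.quantity.sum())

    def concentrations(self) -> np.ndarray:
        """Per-compartment concentration [mol/m^3], in ``self.ids`` order."""
        return self.quantity / self._volumes()
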