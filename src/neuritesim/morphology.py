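"""Compartmental representation of a neuron as a rooted tree of cylinders.

The neuron is modelled as a single soma compartment (the root) that
connects to one or more neurites, each a chain of cylindrical shaft
compartments terminated by a constant-size growth-cone compartment.
Shaft compartments are kept between a merge floor (0.5 um) and a split
ceiling (2.5 um): as a neurite elongates, the shaft compartment just
proximal to the growth cone stretches and is split in two when it grows
past the ceiling; when a neurite retracts, that compartment shrinks and
is merged into its parent when it drops below the floor.  Splitting and
merging conserve cable length and tubulin exactly.

Distances between two points of the tree are path distances measured
along the cable (never Euclidean).  Each compartment's reference point
is its distal end, so the distance from the soma to a growth cone is
the neurite's full cable length, and the distance between two sibling
growth cones is the sum of their branch lengths from the fork.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SOMA",
    "SHAFT",
    "GROWTH_CONE",
    "L_SPLIT_DEFAULT",
    "L_MERGE_DEFAULT",
    "Compartment",
    "CompartmentTree",
    "YTreeSpec",
    "SWCError",
    "build_y_tree",
    "build_cable",
    "build_star_tree",
    "build_branched_fixture",
    "read_swc",
    "write_swc",
    "remesh",
    "set_uniform_concentration",
]

SOMA = "soma"
SHAFT = "shaft"
GROWTH_CONE = "growth_cone"

L_SPLIT_DEFAULT = 2.5e-6  # shaft split ceiling [m]
L_MERGE_DEFAULT = 0.5e-6  # shaft merge floor [m]
GC_LENGTH_DEFAULT = 1.0e-6  # fixed growth-cone compartment length [m]
SOMA_DIAMETER_DEFAULT = 10e-6  # sphere-equivalent soma [m]


class SWCError(ValueError):
    """Raised for malformed or structurally invalid SWC input."""


@dataclass
class Compartment:
    """One cylindrical segment of the tree (or the spherical soma root).

    ``length`` and ``diameter`` are in metres; ``tubulin_quantity`` is
    the amount of free tubulin Q_i in the compartment, in moles.
    """

    id: int
    kind: str
    length: float
    diameter: float
    parent_id: int | None = None
    child_ids: list[int] = field(default_factory=list)
    tubulin_quantity: float = 0.0

    @property
    def cross_section_area(self) -> float:
        """Cross-sectional area [m^2] of the cylinder."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def volume(self) -> float:
        """Compartment volume [m^3]; the soma is a sphere of its diameter."""
        if self.kind == SOMA:
            return math.pi * self.diameter**3 / 6.0
        return self.cross_section_area * self.length

    @property
    def half_length(self) -> float:
        """Distance from the compartment centre to either interface [m].

        For the spherical soma this is its radius, so a centre-to-centre
        distance to a child starts at the soma membrane.
        """
        if self.kind == SOMA:
            return self.diameter / 2.0
        return self.length / 2.0

    @property
    def concentration(self) -> float:
        """Tubulin concentration Q/V [mol/m^3]."""
        return self.tubulin_quantity / self.volume


class CompartmentTree:
    """Rooted tree of compartments: soma root, growth-cone leaves."""

    def __init__(self) -> None:
        self.compartments: dict[int, Compartment] = {}
        self.soma_id: int | None = None
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add(
        self,
        kind: str,
        length: float,
        diameter: float,
        parent_id: int | None = None,
        tubulin_quantity: float = 0.0,
        comp_id: int | None = None,
    ) -> Compartment:
        if comp_id is None:
            comp_id = self._next_id
        if comp_id in self.compartments:
            raise ValueError(f"duplicate compartment id {comp_id}")
        self._next_id = max(self._next_id, comp_id + 1)
        comp = Compartment(
            id=comp_id,
            kind=kind,
            length=length,
            diameter=diameter,
            parent_id=parent_id,
            tubulin_quantity=tubulin_quantity,
        )
        if kind == SOMA:
            if self.soma_id is not None:
                raise ValueError("tree already has a soma")
            if parent_id is not None:
                raise ValueError("soma must be the root")
            self.soma_id = comp_id
        else:
            if parent_id is None:
                raise ValueError("non-soma compartment needs a parent")
            self.compartments[parent_id].child_ids.append(comp_id)
        self.compartments[comp_id] = comp
        return comp

    # -- queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.compartments)

    def __contains__(self, comp_id: int) -> bool:
        return comp_id in self.compartments

    def __getitem__(self, comp_id: int) -> Compartment:
        return self.compartments[comp_id]

    @property
    def soma(self) -> Compartment:
        return self.compartments[self.soma_id]

    @property
    def growth_cone_ids(self) -> list[int]:
        return sorted(
            c.id for c in self.compartments.values() if c.kind == GROWTH_CONE
        )

    def path_to_soma(self, comp_id: int) -> list[int]:
        """Ids from ``comp_id`` up to and including the soma."""
        if comp_id not in self.compartments:
            raise KeyError(f"unknown compartment id {comp_id}")
        path = [comp_id]
        node = self.compartments[comp_id]
        while node.parent_id is not None:
            path.append(node.parent_id)
            node = self.compartments[node.parent_id]
        return path

    def depth(self, comp_id: int) -> float:
        """Cable distance [m] from the soma surface to the compartment's
        distal end (0 for the soma itself)."""
        return sum(
            self.compartments[i].length
            for i in self.path_to_soma(comp_id)
            if self.compartments[i].kind != SOMA
        )

    def path_distance(self, a: int, b: int) -> float:
        """Path distance [m] along the tree between the distal ends of
        compartments ``a`` and ``b``; zero iff a == b."""
        pa = self.path_to_soma(a)
        pb = set(self.path_to_soma(b))
        lca = next(i for i in pa if i in pb)
        return self.depth(a) + self.depth(b) - 2.0 * self.depth(lca)

    def neurite_length(self, gc_id: int) -> float:
        """Soma-to-tip cable length [m] of the neurite ending in ``gc_id``."""
        return self.path_distance(self.soma_id, gc_id)

    def total_cable_length(self) -> float:
        return sum(
            c.length for c in self.compartments.values() if c.kind != SOMA
        )

    def total_tubulin(self) -> float:
        return sum(c.tubulin_quantity for c in self.compartments.values())

    def validate(self) -> None:
        """Structural sanity checks; raises ``ValueError`` on violation."""
        if self.soma_id is None:
            raise ValueError("tree has no soma")
        seen: set[int] = set()
        for comp in self.compartments.values():
            if comp.length <= 0 or comp.diameter <= 0:
                raise ValueError(f"compartment {comp.id} has non-positive size")
            if comp.tubulin_quantity < -1e-30:
                raise ValueError(f"compartment {comp.id} has negative tubulin")
            for cid in comp.child_ids:
                if self.compartments[cid].parent_id != comp.id:
                    raise ValueError("parent/child pointers inconsistent")
            # cycle check by walking to the root
            node, hops = comp, 0
            while node.parent_id is not None:
                node = self.compartments[node.parent_id]
                hops += 1
                if hops > len(self.compartments):
                    raise ValueError("cycle in parent links")
            seen.add(comp.id)
        for comp in self.compartments.values():
            if comp.kind == GROWTH_CONE and comp.child_ids:
                raise ValueError("growth cone must be a leaf")
            if comp.kind != GROWTH_CONE and not comp.child_ids and comp.kind != SOMA:
                raise ValueError(f"leaf shaft {comp.id} is not a growth cone")

    def copy(self) -> "CompartmentTree":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class YTreeSpec:
    """Geometry of the simple branched morphology: a trunk of length
    ``d_a`` from the soma to a fork, then two daughter branches of
    initial length ``d_b`` each (growth cone included)."""

    d_a: float  # soma -> branch point [m]
    d_b: float  # branch point -> growth-cone tip [m]
    neurite_diameter: float = 1.0e-6
    soma_diameter: float = SOMA_DIAMETER_DEFAULT
    gc_length: float = GC_LENGTH_DEFAULT

    def __post_init__(self) -> None:
        if self.d_a <= 0 or self.d_b <= 0:
            raise ValueError("d_a and d_b must be positive")
        if self.d_b <= self.gc_length:
            raise ValueError("d_b must exceed the growth-cone length")


def _add_chain(
    tree: CompartmentTree,
    parent_id: int,
    length: float,
    diameter: float,
    max_len: float = L_SPLIT_DEFAULT,
) -> int:
    """Append a chain of shaft compartments of total ``length`` below
    ``parent_id``; pieces are equal and never exceed ``max_len``.
    Returns the distal compartment id."""
    n = max(1, math.ceil(length / max_len - 1e-12))
    piece = length / n
    pid = parent_id
    for _ in range(n):
        pid = tree.add(SHAFT, piece, diameter, parent_id=pid).id
    return pid


def _add_terminal_branch(
    tree: CompartmentTree,
    parent_id: int,
    length: float,
    diameter: float,
    gc_length: float = GC_LENGTH_DEFAULT,
) -> int:
    """Append a terminal branch: shafts plus a growth cone carved from
    the distal ``gc_length`` of the branch.  Returns the gc id."""
    shaft_len = length - gc_length
    if shaft_len < L_MERGE_DEFAULT:
        # very short terminal branch: the whole branch is the growth cone
        return tree.add(GROWTH_CONE, length, diameter, parent_id=parent_id).id
    pid = _add_chain(tree, parent_id, shaft_len, diameter)
    return tree.add(GROWTH_CONE, gc_length, diameter, parent_id=pid).id


def build_y_tree(spec: YTreeSpec) -> CompartmentTree:
    """Soma -> trunk of length d_a -> fork -> two daughters of length d_b."""
    tree = CompartmentTree()
    soma = tree.add(SOMA, spec.soma_diameter, spec.soma_diameter)
    fork = _add_chain(tree, soma.id, spec.d_a, spec.neurite_diameter)
    for _ in range(2):
        _add_terminal_branch(
            tree, fork, spec.d_b, spec.neurite_diameter, spec.gc_length
        )
    return tree


def build_cable(
    length: float,
    diameter: float = 1.0e-6,
    soma_diameter: float = SOMA_DIAMETER_DEFAULT,
    max_comp_length: float = L_SPLIT_DEFAULT,
    tip_growth_cone: bool = True,
    gc_length: float = GC_LENGTH_DEFAULT,
) -> CompartmentTree:
    """Unbranched soma + single neurite, mainly for solver validation."""
    tree = CompartmentTree()
    soma = tree.add(SOMA, soma_diameter, soma_diameter)
    if tip_growth_cone:
        pid = _add_chain(tree, soma.id, length - gc_length, diameter, max_comp_length)
        tree.add(GROWTH_CONE, gc_length, diameter, parent_id=pid)
    else:
        pid = _add_chain(tree, soma.id, length, diameter, max_comp_length)
        # mark the tip as a (sealed) growth cone so the tree validates
        tree.compartments[pid].kind = GROWTH_CONE
    return tree


def build_star_tree(
    n_neurites: int = 3,
    neurite_length: float = 2.0e-6,
    diameter: float = 1.0e-6,
    soma_diameter: float = SOMA_DIAMETER_DEFAULT,
) -> CompartmentTree:
    """Soma with ``n_neurites`` short unbranched neurites, the initial
    condition for replaying staggered outgrowth of a cultured neuron."""
    tree = CompartmentTree()
    soma = tree.add(SOMA, soma_diameter, soma_diameter)
    for _ in range(n_neurites):
        _add_terminal_branch(tree, soma.id, neurite_length, diameter)
    return tree


# (length [um], diameter [um], children) -- a deterministic branched
# morphology with 9 terminal tips whose soma->tip path distances span
# 45-180 um, loosely shaped like a pyramidal-cell dendritic tree.
_BRANCHED_SPEC = [
    (
        30.0,
        2.0,
        [
            (
                40.0,
                1.5,
                [
                    (30.0, 1.0, [(25.0, 1.0, []), (35.0, 1.0, [])]),
                    (50.0, 1.2, [(30.0, 1.0, []), (60.0, 1.0, [])]),
                ],
            ),
            (
                20.0,
                1.5,
                [
                    (15.0, 1.0, []),
                    (25.0, 1.2, [(20.0, 1.0, []), (30.0, 1.0, [])]),
                ],
            ),
        ],
    ),
    (25.0, 1.5, [(20.0, 1.0, []), (30.0, 1.0, [])]),
]


def build_branched_fixture() -> CompartmentTree:
    """Deterministic pyramidal-like tree with 9 growth cones at a wide
    range of path distances from the soma."""
    tree = CompartmentTree()
    soma = tree.add(SOMA, SOMA_DIAMETER_DEFAULT, SOMA_DIAMETER_DEFAULT)

    def rec(parent_id: int, node: tuple) -> None:
        length_um, diam_um, children = node
        if not children:
            _add_terminal_branch(tree, parent_id, length_um * 1e-6, diam_um * 1e-6)
            return
        tip = _add_chain(tree, parent_id, length_um * 1e-6, diam_um * 1e-6)
        for child in children:
            rec(tip, child)

    for trunk in _BRANCHED_SPEC:
        rec(soma.id, trunk)
    return tree


def set_uniform_concentration(tree: CompartmentTree, conc: float) -> None:
    """Set every compartment's tubulin quantity to ``conc * volume``."""
    for comp in tree.compartments.values():
        comp.tubulin_quantity = conc * comp.volume


# ---------------------------------------------------------------------
# SWC input / output
# ---------------------------------------------------------------------


def _parse_swc(path: str | Path) -> dict[int, tuple]:
    nodes: dict[int, tuple] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                ntype = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCError(f"{path}: line {lineno}: {exc}") from None
            if nid in nodes:
                raise SWCError(f"{path}: line {lineno}: duplicate node id {nid}")
            nodes[nid] = (ntype, x, y, z, radius, parent)
    if not nodes:
        raise SWCError(f"{path}: no SWC records found")
    return nodes


def read_swc(
    path: str | Path,
    max_comp_length: float = L_SPLIT_DEFAULT,
    gc_length: float = GC_LENGTH_DEFAULT,
) -> CompartmentTree:
    """Read an SWC reconstruction into a compartment tree.

    Coordinates are in micrometres (SWC convention).  Each unbranched
    SWC section is re-sampled into equal compartments no longer than
    ``max_comp_length``; terminal tips become growth-cone compartments
    carved from the distal end of the terminal section.  Total cable
    length is preserved exactly by construction.
    """
    nodes = _parse_swc(path)

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid, (_, _, _, _, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise SWCError(f"node {nid} references unknown parent {parent}")
            children[parent].append(nid)
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root node, found {len(roots)}")
    root = roots[0]

    # cycle detection: every node must reach the root
    for nid in nodes:
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise SWCError(f"cyclic parent links involving node {nid}")
            seen.add(cur)
            cur = nodes[cur][5]

    tree = CompartmentTree()
    root_radius = nodes[root][4] * 1e-6
    soma = tree.add(SOMA, 2 * root_radius, 2 * root_radius)

    def seg_length(a: int, b: int) -> float:
        _, xa, ya, za, _, _ = nodes[a]
        _, xb, yb, zb, _, _ = nodes[b]
        return math.dist((xa, ya, za), (xb, yb, zb)) * 1e-6

    def build_section(start: int, parent_comp: int) -> None:
        """Walk one unbranched section beginning at SWC node ``start``
        (a child of a branch node / the root) and emit compartments."""
        pts = [start]
        while len(children[pts[-1]]) == 1:
            pts.append(children[pts[-1]][0])
        prev = nodes[start][5]
        arc = [seg_length(prev, start)]
        for a, b in zip(pts, pts[1:]):
            arc.append(seg_length(a, b))
        total = sum(arc)
        if total <= 0:
            raise SWCError(f"zero-length section starting at node {start}")
        diam = 2e-6 * sum(nodes[p][4] for p in pts) / len(pts)
        is_tip = not children[pts[-1]]
        if is_tip:
            shaft_len = total - gc_length
            if shaft_len >= L_MERGE_DEFAULT:
                pid = _add_chain(tree, parent_comp, shaft_len, diam, max_comp_length)
                tree.add(GROWTH_CONE, gc_length, diam, parent_id=pid)
            else:
                tree.add(GROWTH_CONE, total, diam, parent_id=parent_comp)
        else:
            pid = _add_chain(tree, parent_comp, total, diam, max_comp_length)
            for nxt in children[pts[-1]]:
                build_section(nxt, pid)

    for child in children[root]:
        build_section(child, soma.id)
    tree.validate()
    return tree


def write_swc(tree: CompartmentTree, path: str | Path) -> None:
    """Write the tree as SWC (micrometre coordinates, one node per
    compartment distal end).  Coordinates are synthesized in the plane
    purely to encode segment lengths; only path metrics are meaningful.
    """
    lines = ["# generated by neuritesim", "# id type x y z radius parent"]
    node_of: dict[int, int] = {}
    next_node = 1
    soma = tree.soma
    lines.append(f"1 1 0.0 0.0 0.0 {soma.diameter / 2 * 1e6:.6f} -1")
    node_of[soma.id] = 1
    next_node = 2

    # depth-first layout; each branch gets its own direction
    def walk(comp_id: int, x: float, y: float, angle: float) -> None:
        nonlocal next_node
        comp = tree.compartments[comp_id]
        children = comp.child_ids
        spread = 0.9  # radians between sibling branches
        for k, cid in enumerate(children):
            child = tree.compartments[cid]
            if len(children) > 1:
                ang = angle + spread * (k - (len(children) - 1) / 2.0)
            else:
                ang = angle
            cx = x + child.length * 1e6 * math.cos(ang)
            cy = y + child.length * 1e6 * math.sin(ang)
            swc_type = 1 if child.kind == SOMA else 3
            lines.append(
                f"{next_node} {swc_type} {cx:.6f} {cy:.6f} 0.0 "
                f"{child.diameter / 2 * 1e6:.6f} {node_of[comp_id]}"
            )
            node_of[cid] = next_node
            next_node += 1
            walk(cid, cx, cy, ang)

    k0 = len(soma.child_ids)
    for k, cid in enumerate(list(soma.child_ids)):
        base_angle = 2 * math.pi * k / max(k0, 1)
        child = tree.compartments[cid]
        cx = child.length * 1e6 * math.cos(base_angle)
        cy = child.length * 1e6 * math.sin(base_angle)
        lines.append(
            f"{next_node} 3 {cx:.6f} {cy:.6f} 0.0 "
            f"{child.diameter / 2 * 1e6:.6f} 1"
        )
        node_of[cid] = next_node
        next_node += 1
        walk(cid, cx, cy, base_angle)

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# dynamic remeshing
# ---------------------------------------------------------------------


def remesh(
    tree: CompartmentTree,
    l_split: float = L_SPLIT_DEFAULT,
    l_merge: float = L_MERGE_DEFAULT,
) -> CompartmentTree:
    """Split shaft compartments longer than ``l_split`` into two halves
    (half length, half tubulin each) and merge shafts shorter than
    ``l_merge`` into their parent (lengths and tubulin summed).  Both
    operations conserve total cable length and total tubulin exactly.

    A shaft whose parent is the soma or a branch point is never merged:
    the growth step clamps retraction so a neurite can shrink to a
    growth cone plus one floor-length shaft but never vanishes.
    Mutates and returns ``tree``.
    """
    _remesh_events(tree, l_split, l_merge)
    return tree


def _remesh_events(
    tree: CompartmentTree,
    l_split: float = L_SPLIT_DEFAULT,
    l_merge: float = L_MERGE_DEFAULT,
) -> tuple[int, int]:
    """Remesh in place; returns (n_splits, n_merges)."""
    n_split = n_merge = 0
    changed = True
    while changed:
        changed = False
        for comp in list(tree.compartments.values()):
            if comp.kind != SHAFT:
                continue
            if comp.length > l_split * (1 + 1e-12):
                _split(tree, comp)
                n_split += 1
                changed = True
            elif comp.length < l_merge * (1 - 1e-12):
                parent = tree.compartments[comp.parent_id]
                if parent.kind == SOMA or len(parent.child_ids) > 1:
                    continue  # clamped at the branch point / soma
                _merge_into_parent(tree, comp)
                n_merge += 1
                changed = True
    return n_split, n_merge


def _split(tree: CompartmentTree, comp: Compartment) -> None:
    """Split ``comp`` into two halves; the distal half is a new
    compartment inheriting the children."""
    half_len = comp.length / 2.0
    half_q = comp.tubulin_quantity / 2.0
    old_children = comp.child_ids
    comp.length = half_len
    comp.tubulin_quantity = half_q
    comp.child_ids = []
    distal = tree.add(
        SHAFT, half_len, comp.diameter, parent_id=comp.id, tubulin_quantity=half_q
    )
    distal.child_ids = old_children
    for cid in old_children:
        tree.compartments[cid].parent_id = distal.id


def _merge_into_parent(tree: CompartmentTree, comp: Compartment) -> None:
    parent = tree.compartments[comp.parent_id]
    parent.length += comp.length
    parent.tubulin_quantity += comp.tubulin_quantity
    parent.child_ids = [c for c in parent.child_ids if c != comp.id]
    parent.child_ids.extend(comp.child_ids)
    for cid in comp.child_ids:
        tree.compartments[cid].parent_id = parent.id
    del tree.compartments[comp.id]
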