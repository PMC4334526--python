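"""Spatial discretization of neurites: the element tree.

A neurite (axon or dendritic tree) is discretized into *elements*, each a
short cylinder with a membrane model tag (``CT`` for passive cable regions,
``HH`` for active Hodgkin-Huxley regions such as nodes of Ranvier), a length
``dx``, a diameter ``d``, a membrane thickness ``h`` and an optional myelin
wrap (``n_my`` layers of thickness ``h_my``).

Elements are linked into a binary tree: every element has a parent ``pa``, a
right child ``rc`` and possibly a left child ``lc``.  "Right" denotes the
first branch; ``lc`` only exists at a branching point (``fb`` true).  A
terminal element's ``rc`` points to itself.  Enumeration is a depth-first
preorder that always descends the right child first and resumes at the most
recent unfinished branching, so that for every branching element ``b``,
``rc[b] == b + 1``; this yields the quasi-tridiagonal structure the implicit
solver relies on.  Branching at element 0 is not allowed.

All lengths are SI metres; SWC files (micrometres) are converted on load.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import SimpleNamespace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CT",
    "HH",
    "Element",
    "ElementSpec",
    "NeuriteTree",
    "SWCPoint",
    "MorphologyError",
    "SWCFormatError",
    "tree_from_specs",
    "reenumerate",
    "build_myelinated_axon",
    "build_symmetric_tree",
    "load_swc",
    "read_swc_points",
    "write_swc",
    "validate_tree",
    "count_branching_points",
    "count_elements",
]

CT = "CT"
HH = "HH"

#: default membrane thickness (m) when a builder is not given one
DEFAULT_MEMBRANE_THICKNESS = 1.0e-8


class MorphologyError(ValueError):
    """Invalid geometry or tree topology."""


class SWCFormatError(MorphologyError):
    """Malformed SWC content (bad columns, cycles, missing parents)."""


@dataclass
class Element:
    """One spatial compartment of the discretization.

    ``dx``/``d`` are the current (possibly strained) length and diameter;
    ``dx0``/``d0`` the reference (unstrained) values.  ``axial_pos`` is the
    arc distance of the element's centre from the start of element 0, used
    for probe placement and conduction-velocity measurements.
    """

    index: int
    mm: str
    dx: float
    d: float
    h: float
    n_my: int = 0
    h_my: float = 0.0
    pa: int = 0
    rc: int = 0
    lc: int | None = None
    fb: bool = False
    dx0: float = 0.0
    d0: float = 0.0
    axial_pos: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.dx0 == 0.0:
            self.dx0 = self.dx
        if self.d0 == 0.0:
            self.d0 = self.d

    @property
    def is_terminal(self) -> bool:
        return self.rc == self.index


@dataclass
class ElementSpec:
    """Pre-enumeration element: geometry plus child links by object reference.

    Builders assemble :class:`ElementSpec` trees and hand the root to
    :func:`tree_from_specs`, which performs the canonical right-first
    depth-first enumeration.  Children are ordered: ``children[0]`` becomes
    the right child (first branch), ``children[1]`` the left child.
    """

    mm: str
    dx: float
    d: float
    h: float = DEFAULT_MEMBRANE_THICKNESS
    n_my: int = 0
    h_my: float = 0.0
    label: str | None = None
    children: list["ElementSpec"] = field(default_factory=list)


@dataclass(frozen=True)
class SWCPoint:
    """One sample point of an SWC reconstruction (coordinates in µm)."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


class NeuriteTree:
    """Ordered element list obeying the enumeration invariants.

    The list order *is* the solver ordering: indices run 0..N-1 in a
    right-first depth-first preorder, parents precede children, and the right
    subtree of a branching element starts immediately after it.
    """

    def __init__(self, elements: Sequence[Element], build_info: dict | None = None):
        self.elements: list[Element] = list(elements)
        self.build_info: dict = dict(build_info or {})
        self._arrays: SimpleNamespace | None = None

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i: int) -> Element:
        return self.elements[i]

    # -- derived views -------------------------------------------------

    def arrays(self) -> SimpleNamespace:
        """Per-element numpy arrays (cached); invalidate after mutation."""
        if self._arrays is None:
            els = self.elements
            n = len(els)
            self._arrays = SimpleNamespace(
                dx=np.array([e.dx for e in els], float),
                d=np.array([e.d for e in els], float),
                h=np.array([e.h for e in els], float),
                n_my=np.array([e.n_my for e in els], int),
                h_my=np.array([e.h_my for e in els], float),
                pa=np.array([e.pa for e in els], int),
                rc=np.array([e.rc for e in els], int),
                lc=np.array([-1 if e.lc is None else e.lc for e in els], int),
                fb=np.array([e.fb for e in els], bool),
                is_hh=np.array([e.mm == HH for e in els], bool),
                axial_pos=np.array([e.axial_pos for e in els], float),
                n=n,
            )
        return self._arrays

    def invalidate(self) -> None:
        self._arrays = None

    @property
    def total_length(self) -> float:
        return float(sum(e.dx for e in self.elements))

    def hh_indices(self) -> np.ndarray:
        return np.nonzero(self.arrays().is_hh)[0]

    def terminal_indices(self) -> np.ndarray:
        a = self.arrays()
        return np.nonzero(a.rc == np.arange(a.n))[0]

    def children_of(self, i: int) -> list[int]:
        e = self.elements[i]
        out = []
        if e.rc != i:
            out.append(e.rc)
        if e.lc is not None:
            out.append(e.lc)
        return out

    def copy(self) -> "NeuriteTree":
        return NeuriteTree([replace(e) for e in self.elements], dict(self.build_info))


# ----------------------------------------------------------------------
# Enumeration
# ----------------------------------------------------------------------

def tree_from_specs(root: ElementSpec, build_info: dict | None = None) -> NeuriteTree:
    """Enumerate an :class:`ElementSpec` tree into a :class:`NeuriteTree`.

    Depth-first preorder, right (first) child before left (second) child:
    the entire right subtree of a branching element is enumerated before its
    left subtree, so ``rc[b] == b + 1`` for every branching ``b``.

    Raises
    ------
    MorphologyError
        If any spec has more than two children (binarize first — see
        :func:`load_swc`), if the root itself branches, or geometry is
        non-positive.
    """
    order: list[tuple[ElementSpec, int]] = []  # (spec, parent index)
    stack: list[tuple[ElementSpec, int]] = [(root, 0)]
    while stack:
        spec, pa = stack.pop()
        if len(spec.children) > 2:
            raise MorphologyError(
                f"element with {len(spec.children)} children: only binary "
                "branchings are representable (expand n-furcations first)"
            )
        idx = len(order)
        order.append((spec, pa))
        # push left child first so the right child is popped (visited) first
        for child in reversed(spec.children):
            stack.append((child, idx))

    if root.children and len(root.children) > 1:
        raise MorphologyError("branching at the first element is not allowed")

    # map spec -> assigned index to wire rc/lc
    index_of = {id(spec): i for i, (spec, _) in enumerate(order)}
    elements: list[Element] = []
    for i, (spec, pa) in enumerate(order):
        if spec.dx <= 0 or spec.d <= 0 or spec.h <= 0:
            raise MorphologyError(
                f"non-positive geometry at element {i}: dx={spec.dx}, d={spec.d}, h={spec.h}"
            )
        if spec.n_my < 0 or (spec.n_my > 0 and spec.h_my <= 0):
            raise MorphologyError(f"invalid myelin specification at element {i}")
        if spec.mm not in (CT, HH):
            raise MorphologyError(f"unknown membrane model {spec.mm!r} at element {i}")
        if spec.mm == HH and spec.n_my > 0:
            raise MorphologyError(f"HH element {i} cannot carry myelin (n_my > 0)")
        kids = [index_of[id(c)] for c in spec.children]
        rc = kids[0] if kids else i
        lc = kids[1] if len(kids) == 2 else None
        el = Element(
            index=i, mm=spec.mm, dx=spec.dx, d=spec.d, h=spec.h,
            n_my=spec.n_my, h_my=spec.h_my, pa=pa, rc=rc, lc=lc,
            fb=lc is not None, label=spec.label,
        )
        elements.append(el)

    # centre-based arc distance from the proximal end of element 0
    for el in elements:
        if el.index == 0:
            el.axial_pos = el.dx / 2.0
        else:
            parent = elements[el.pa]
            el.axial_pos = parent.axial_pos + (parent.dx + el.dx) / 2.0
    return NeuriteTree(elements, build_info)


def _specs_from_tree(tree: NeuriteTree) -> ElementSpec:
    """Convert back to linked specs (children ordered rc, lc)."""
    specs = [
        ElementSpec(mm=e.mm, dx=e.dx, d=e.d, h=e.h, n_my=e.n_my, h_my=e.h_my,
                    label=e.label)
        for e in tree.elements
    ]
    for e in tree.elements:
        if e.rc != e.index:
            specs[e.index].children.append(specs[e.rc])
        if e.lc is not None:
            specs[e.index].children.append(specs[e.lc])
    return specs[0]


def reenumerate(tree: NeuriteTree) -> NeuriteTree:
    """Re-run the canonical enumeration; identity on already-valid trees."""
    return tree_from_specs(_specs_from_tree(tree), dict(tree.build_info))


# ----------------------------------------------------------------------
# Builders
# ----------------------------------------------------------------------

def _segment_pieces(length: float, dx: float, what: str) -> tuple[int, float]:
    """Number of pieces and (possibly rescaled) piece length for a segment.

    If ``length`` is an integer multiple of ``dx`` (within 1e-9 relative) that
    count is used; otherwise the count is rounded and ``dx`` rescaled so the
    total length is preserved exactly.
    """
    if length <= 0 or dx <= 0:
        raise MorphologyError(f"non-positive {what} geometry: length={length}, dx={dx}")
    ratio = length / dx
    n = max(1, int(round(ratio)))
    # element size is always recomputed as length/n: preserves the total
    # length exactly whether or not the division was integral
    return n, length / n


def build_myelinated_axon(
    n_nodes: int,
    len_NR: float,
    len_IR: float = 0.0,
    dx_NR: float | None = None,
    dx_IR: float | None = None,
    d: float = 1e-6,
    h: float = DEFAULT_MEMBRANE_THICKNESS,
    n_my: int = 20,
    h_my: float = 1e-8,
) -> NeuriteTree:
    """Unbranched chain alternating active nodes of Ranvier and myelinated
    internodes: NR, IR, NR, ..., IR, NR.

    Parameters are SI metres.  ``n_nodes`` nodes of Ranvier (HH, bare
    membrane) of length ``len_NR`` split into elements of size ``dx_NR``,
    separated by ``n_nodes - 1`` internodal regions (CT, ``n_my`` myelin
    layers) of length ``len_IR`` at ``dx_IR``.  Segment lengths that are not
    integer multiples of the element size are preserved by rescaling the
    element size (reported in ``tree.build_info``).
    """
    if n_nodes < 1:
        raise MorphologyError("n_nodes must be >= 1")
    if d <= 0 or h <= 0:
        raise MorphologyError("non-positive diameter or membrane thickness")
    dx_NR = dx_NR if dx_NR is not None else len_NR
    n_nr, dx_nr = _segment_pieces(len_NR, dx_NR, "node of Ranvier")
    if n_nodes > 1:
        if len_IR <= 0:
            raise MorphologyError("len_IR must be positive when n_nodes > 1")
        dx_IR = dx_IR if dx_IR is not None else len_IR
        n_ir, dx_ir = _segment_pieces(len_IR, dx_IR, "internode")
    else:
        n_ir, dx_ir = 0, 0.0

    root = ElementSpec(mm=HH, dx=dx_nr, d=d, h=h, label="NR")
    tip = root
    for j in range(n_nodes):
        start = 1 if j == 0 else 0
        for _ in range(start, n_nr):
            nxt = ElementSpec(mm=HH, dx=dx_nr, d=d, h=h, label="NR")
            tip.children.append(nxt)
            tip = nxt
        if j < n_nodes - 1:
            for _ in range(n_ir):
                nxt = ElementSpec(mm=CT, dx=dx_ir, d=d, h=h, n_my=n_my,
                                  h_my=h_my, label="IR")
                tip.children.append(nxt)
                tip = nxt
    info = {
        "builder": "myelinated_axon",
        "n_nodes": n_nodes,
        "elements_per_NR": n_nr,
        "elements_per_IR": n_ir,
        "dx_NR": dx_nr,
        "dx_IR": dx_ir,
        "dx_NR_rescaled": not math.isclose(dx_nr, dx_NR, rel_tol=1e-9),
        "dx_IR_rescaled": n_ir > 0 and not math.isclose(dx_ir, dx_IR, rel_tol=1e-9),
        "total_length": n_nodes * len_NR + max(0, n_nodes - 1) * len_IR,
    }
    return tree_from_specs(root, info)


def build_symmetric_tree(
    depth: int,
    seg_len: float,
    dx: float,
    d_root: float = 2e-6,
    taper: float = 0.8,
    seed: int = 0,
    h: float = DEFAULT_MEMBRANE_THICKNESS,
    jitter: float = 0.1,
) -> NeuriteTree:
    """Random symmetric dendritic tree: a full binary tree of passive (CT)
    segments.

    Every segment is a chain of elements of size ``dx``; every non-terminal
    segment ends in a branching element with two children.  ``depth`` is the
    number of branching generations (depth 0 is an unbranched chain).
    Diameters shrink by ``taper`` per generation.  ``seed`` drives a mild
    per-segment length jitter (uniform ±``jitter`` relative), making the tree
    "random" yet fully deterministic for a given seed.
    """
    if depth < 0:
        raise MorphologyError("depth must be >= 0")
    if taper <= 0:
        raise MorphologyError("taper must be > 0")
    if dx > seg_len:
        raise MorphologyError("dx larger than segment length")
    n_root = int(round(seg_len / dx))
    if depth >= 1 and n_root < 2:
        raise MorphologyError(
            "root segment needs >= 2 elements (branching at the first element "
            "is not allowed); decrease dx or seg_len"
        )
    rng = np.random.default_rng(seed)

    def make_segment(gen: int) -> tuple[ElementSpec, ElementSpec]:
        length = seg_len * (1.0 + jitter * float(rng.uniform(-1, 1)))
        n_el, dx_el = _segment_pieces(length, dx, "segment")
        diam = d_root * taper**gen
        head = ElementSpec(mm=CT, dx=dx_el, d=diam, h=h, label=f"gen{gen}")
        tip = head
        for _ in range(1, n_el):
            nxt = ElementSpec(mm=CT, dx=dx_el, d=diam, h=h, label=f"gen{gen}")
            tip.children.append(nxt)
            tip = nxt
        return head, tip

    root, tip = make_segment(0)
    frontier = [(tip, 0)]
    for _ in range(depth):
        new_frontier = []
        for tip, gen in frontier:
            for _ in range(2):
                head, sub_tip = make_segment(gen + 1)
                tip.children.append(head)
                new_frontier.append((sub_tip, gen + 1))
        frontier = new_frontier
    info = {"builder": "symmetric_tree", "depth": depth, "seed": seed}
    return tree_from_specs(root, info)


# ----------------------------------------------------------------------
# SWC
# ----------------------------------------------------------------------

def read_swc_points(path: str | Path) -> list[SWCPoint]:
    """Parse a standard 7-column SWC file ('#' comments allowed)."""
    points: list[SWCPoint] = []
    seen: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCFormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
        try:
            pid, tc = int(cols[0]), int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCFormatError(f"{path}:{lineno}: {exc}") from None
        if pid in seen:
            raise SWCFormatError(f"{path}:{lineno}: duplicate point id {pid}")
        if r <= 0:
            raise SWCFormatError(f"{path}:{lineno}: non-positive radius")
        seen.add(pid)
        points.append(SWCPoint(pid, tc, x, y, z, r, parent))
    return points


def write_swc(points: Iterable[SWCPoint], path: str | Path) -> None:
    """Emit a minimal SWC file (test-fixture writer)."""
    lines = ["# id type x y z radius parent"]
    for p in points:
        lines.append(f"{p.id} {p.type_code} {p.x:.6g} {p.y:.6g} {p.z:.6g} {p.radius:.6g} {p.parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")


_UM = 1e-6


def load_swc(
    path: str | Path,
    include_types: set[int] | Sequence[int] = (1, 2, 3, 4),
    dx_target: float | None = None,
    mm: str = CT,
    h: float = DEFAULT_MEMBRANE_THICKNESS,
) -> NeuriteTree:
    """Load an SWC reconstruction and adapt it to the element-tree enumeration.

    Each retained parent→child SWC segment becomes one or more elements:
    length is the 3D inter-point distance (split into ``ceil(len/dx_target)``
    equal pieces when ``dx_target`` is given), diameter is twice the child
    point's radius.  The 3D structure is flattened: coordinates survive only
    as arc length (``axial_pos``) and topology.  Points with more than two
    children are expanded into cascaded binary branchings joined by short
    connector elements; a multi-child root point likewise gets a short
    lead-in connector so that element 0 never branches.

    Raises :class:`SWCFormatError` on cyclic parent links and
    :class:`MorphologyError` when type filtering leaves several disconnected
    components (candidate roots are listed).  Zero-length segments are
    dropped with a warning.
    """
    include_types = set(include_types)
    if not include_types:
        raise MorphologyError("include_types must be non-empty")
    points = {p.id: p for p in read_swc_points(path)}
    retained = {p.id: p for p in points.values() if p.type_code in include_types}
    if not retained:
        raise MorphologyError("no points retained after type filtering")

    # cycle check over the full file (parent chains must terminate at -1)
    state: dict[int, int] = {}
    for pid in points:
        chain = []
        cur = pid
        while cur != -1 and state.get(cur) != 2:
            if state.get(cur) == 1:
                raise SWCFormatError(f"cyclic parent links involving point {cur}")
            state[cur] = 1
            chain.append(cur)
            cur = points[cur].parent_id if cur in points else -1
        for c in chain:
            state[c] = 2

    # children among retained points (parent must also be retained to form an edge)
    children: dict[int, list[int]] = {pid: [] for pid in retained}
    roots: list[int] = []
    for p in retained.values():
        if p.parent_id in retained:
            children[p.parent_id].append(p.id)
        else:
            roots.append(p.id)
    for kids in children.values():
        kids.sort()
    roots.sort()
    if len(roots) > 1:
        raise MorphologyError(
            "type filtering left multiple disconnected components; candidate "
            f"roots (SWC ids): {roots}. Include a connecting type (e.g. the "
            "soma, type 1) or restrict include_types."
        )
    root_pid = roots[0]

    dx_min = min(1e-7, dx_target / 10.0) if dx_target else 1e-7

    def dist(a: SWCPoint, b: SWCPoint) -> float:
        return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z)) * _UM

    dropped = 0

    def edge_chain(parent_pt: SWCPoint, child_pt: SWCPoint) -> tuple[ElementSpec, ElementSpec] | None:
        """Elements for one SWC edge; None if the edge has zero length."""
        nonlocal dropped
        length = dist(parent_pt, child_pt)
        diam = 2.0 * child_pt.radius * _UM
        if length <= 0:
            dropped += 1
            return None
        n_pieces = max(1, math.ceil(length / dx_target)) if dx_target else 1
        dx_el = length / n_pieces
        label = f"swc_type_{child_pt.type_code}"
        head = ElementSpec(mm=mm, dx=dx_el, d=diam, h=h, label=label)
        tip = head
        for _ in range(1, n_pieces):
            nxt = ElementSpec(mm=mm, dx=dx_el, d=diam, h=h, label=label)
            tip.children.append(nxt)
            tip = nxt
        return head, tip

    def binarize(tip: ElementSpec, heads: list[ElementSpec], diam: float) -> None:
        """Attach child chains to ``tip``, cascading n-furcations into binary
        branchings joined by dx_min connectors."""
        while len(heads) > 2:
            first = heads.pop(0)
            connector = ElementSpec(mm=mm, dx=dx_min, d=diam, h=h, label="connector")
            tip.children.extend([first, connector])
            tip = connector
        tip.children.extend(heads)

    def subtree_heads(pid: int) -> list[ElementSpec]:
        """Element chains for all edges leaving SWC point ``pid``."""
        heads = []
        for cid in children[pid]:
            chain = edge_chain(retained[pid], retained[cid])
            if chain is None:
                # zero-length edge: splice grandchildren directly onto pid
                heads.extend(subtree_heads(cid))
                continue
            head, tip = chain
            kid_heads = subtree_heads(cid)
            binarize(tip, kid_heads, 2.0 * retained[cid].radius * _UM)
            heads.append(head)
        return heads

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * len(retained) + 1000))
    try:
        top_heads = subtree_heads(root_pid)
    finally:
        sys.setrecursionlimit(old_limit)
    if dropped:
        warnings.warn(f"dropped {dropped} zero-length SWC segment(s)", stacklevel=2)
    if not top_heads:
        raise MorphologyError("no usable segments after filtering")
    root_diam = 2.0 * retained[root_pid].radius * _UM
    if len(top_heads) == 1:
        root = top_heads[0]
    else:
        root = ElementSpec(mm=mm, dx=dx_min, d=root_diam, h=h, label="connector")
        binarize(root, top_heads, root_diam)
    if len(root.children) > 1:
        # branching may not sit at the first element: short lead-in connector
        lead = ElementSpec(mm=mm, dx=dx_min, d=root_diam, h=h, label="connector")
        lead.children.append(root)
        root = lead
    info = {
        "builder": "swc",
        "path": str(path),
        "include_types": sorted(include_types),
        "dx_target": dx_target,
        "root_swc_id": root_pid,
        "dropped_zero_length": dropped,
    }
    return tree_from_specs(root, info)


# ----------------------------------------------------------------------
# Validation and counts
# ----------------------------------------------------------------------

def validate_tree(tree: NeuriteTree) -> list[str]:
    """Check every enumeration/geometry invariant; returns the list of
    violations (empty = valid).  Reports, never raises."""
    v: list[str] = []
    els = tree.elements
    n = len(els)
    if n == 0:
        return ["empty tree"]
    for i, e in enumerate(els):
        if e.index != i:
            v.append(f"element at position {i} carries index {e.index}")
    if els[0].pa != 0:
        v.append("root parent must be itself (index 0)")
    if els[0].fb or els[0].lc is not None:
        v.append("branch at first element")
    for e in els[1:]:
        if not (0 <= e.pa < e.index):
            v.append(f"parent after child: pa[{e.index}] = {e.pa}")
    child_refs: dict[int, int] = {}
    for e in els:
        if e.rc != e.index:
            child_refs[e.rc] = child_refs.get(e.rc, 0) + 1
        if e.lc is not None:
            child_refs[e.lc] = child_refs.get(e.lc, 0) + 1
    for i in range(1, n):
        c = child_refs.get(i, 0)
        if c != 1:
            v.append(f"element {i} referenced as a child {c} times (expected once)")
    for e in els:
        if e.fb != (e.lc is not None):
            v.append(f"fb/lc mismatch at element {e.index}")
        if e.fb and e.rc != e.index + 1:
            v.append(f"branching element {e.index} has rc {e.rc} != {e.index + 1}")
        if e.rc == e.index and e.lc is not None:
            v.append(f"terminal element {e.index} carries a left child")
        if e.dx <= 0 or e.d <= 0 or e.h <= 0:
            v.append(f"non-positive geometry at element {e.index}")
        if e.n_my > 0 and e.h_my <= 0:
            v.append(f"n_my > 0 with h_my <= 0 at element {e.index}")
        if e.mm == HH and e.n_my > 0:
            v.append(f"HH element {e.index} carries myelin")
        if e.mm not in (CT, HH):
            v.append(f"unknown membrane model at element {e.index}")
    # enumeration order: preorder DFS, right child first
    expected: list[int] = []
    stack = [0]
    seen: set[int] = set()
    while stack and len(expected) <= n:
        i = stack.pop()
        if i in seen or not (0 <= i < n):
            v.append(f"broken child links at element {i}")
            break
        seen.add(i)
        expected.append(i)
        e = els[i]
        if e.lc is not None:
            stack.append(e.lc)
        if e.rc != i:
            stack.append(e.rc)
    if expected != list(range(len(expected))) or (not v and len(expected) != n):
        v.append("enumeration is not a right-first depth-first preorder")
    return v


def count_branching_points(tree: NeuriteTree) -> int:
    return sum(1 for e in tree.elements if e.fb)


def count_elements(tree: NeuriteTree) -> int:
    return len(tree.elements)
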