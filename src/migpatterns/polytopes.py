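"""Linear systems attached to migration graphs, and the polytope complex.

For a migration graph ``G`` with labeled edges and per-population total
loads ``T``, the *load system* puts one variable ``x_e`` per edge, bounded
in [0, 1] (the closed relaxation of the open condition 0 < x < 1), and one
equality per population: the incident edge variables sum to that
population's load.  Its solution set is a polytope in the unit hypercube
whose relative interior is the space of admissible weight assignments for
that graph.  The *angle system* is the analogous closed form of the
circle-pattern conditions: per-population equalities summing to 2*pi, plus
one inequality >= 2*pi for every non-facial closed path of the Voronoi
graph (truncated at a configurable cycle length, giving an outer
approximation of the full angle polytope).

Cubic graphs with a common edge labeling, connected by Whitehead moves,
carry polytopes that glue along shared facets: contracting the pivot edge
``e`` identifies the facet ``x_e = 0`` of both neighbouring polytopes with
the load system of the contracted graph.  The resulting finite complex is
the state space on which a metapopulation's history traces a path.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .combmaps import (
    CombinatorialMap,
    MapError,
    all_whiteheads,
    canonical_code,
    contract_edge,
    dual,
    whitehead_move,
)

LP_TOL = 1e-9


class PolytopeError(ValueError):
    pass


@dataclass
class HPolytope:
    """Equalities plus box bounds over ordered edge variables.

    ``strict`` records that the modelled pattern space is the relative
    interior of this closed polytope.
    """

    variables: list
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: list[tuple[float, float]]
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    row_names: list = field(default_factory=list)
    strict: bool = True

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def index(self, var) -> int:
        return self.variables.index(var)

    def contains(self, x, tol: float = 1e-6) -> bool:
        x = np.asarray(x, dtype=float)
        if len(self.A_eq) and np.max(np.abs(self.A_eq @ x - self.b_eq)) > tol:
            return False
        for xi, (lo, hi) in zip(x, self.bounds):
            if xi < lo - tol or xi > hi + tol:
                return False
        if self.A_ub is not None and len(self.A_ub):
            if np.max(self.A_ub @ x - self.b_ub) > tol:
                return False
        return True


def ensure_edge_labels(cm: CombinatorialMap) -> CombinatorialMap:
    """Return a copy with integer edge labels 1..E if none are present."""
    if cm.edge_labels:
        return cm
    out = cm.copy()
    for lab, (d, t) in enumerate(cm.edges(), start=1):
        out.edge_labels[d] = out.edge_labels[t] = lab
    return out


def _face_keys(cm: CombinatorialMap) -> list[tuple[object, tuple[int, ...]]]:
    """(key, face darts) pairs; keys are face names when present, else the
    index of the face in smallest-dart order."""
    faces = cm.faces()
    out = []
    for i, f in enumerate(faces):
        names = {cm.face_names[d] for d in f if d in cm.face_names}
        key = names.pop() if len(names) == 1 else i
        out.append((key, f))
    return out


def _loads_for(keys: list, T) -> dict:
    if isinstance(T, (int, float)):
        return {k: float(T) for k in keys}
    T = dict(T)
    missing = [k for k in keys if k not in T]
    if missing:
        raise PolytopeError(f"no load given for faces {missing}")
    return {k: float(T[k]) for k in keys}


def build_load_system(cm: CombinatorialMap, T) -> HPolytope:
    """The load system of a migration graph: one [0,1]-bounded variable per
    edge, one equality per face (population) summing its incident edge
    variables to the face's total load.

    ``T`` may be a scalar (uniform load) or a mapping keyed like the face
    keys (face names when the map carries them).  Non-positive loads are
    rejected; a load exceeding the face's degree is flagged as trivially
    infeasible but still returned.
    """
    cm = ensure_edge_labels(cm)
    labels = sorted({cm.edge_labels[d] for d in cm.rotation}, key=str)
    col = {lab: i for i, lab in enumerate(labels)}
    fk = _face_keys(cm)
    loads = _loads_for([k for k, _ in fk], T)
    rows, rhs, names = [], [], []
    for key, f in fk:
        t = loads[key]
        if t <= 0:
            raise PolytopeError(f"load for face {key!r} must be positive, got {t}")
        row = np.zeros(len(labels))
        for d in f:
            row[col[cm.edge_labels[d]]] += 1.0
        if t > row.sum():
            warnings.warn(
                f"load {t} for face {key!r} exceeds its degree {int(row.sum())}; "
                "system is trivially infeasible",
                stacklevel=2,
            )
        rows.append(row)
        rhs.append(t)
        names.append(key)
    return HPolytope(
        variables=labels,
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=[(0.0, 1.0)] * len(labels),
        row_names=names,
    )


def build_angle_system(cm: CombinatorialMap, max_cycle_len: int = 8) -> HPolytope:
    """The closed angle system of a migration graph.

    Variables theta_e in [0, pi]; per-face equalities sum to 2*pi; one
    inequality (angle sum >= 2*pi) for each non-facial simple cycle of the
    graph up to ``max_cycle_len`` — a truncated outer approximation of the
    full circle-pattern polytope.
    """
    import networkx as nx

    cm = ensure_edge_labels(cm)
    labels = sorted({cm.edge_labels[d] for d in cm.rotation}, key=str)
    col = {lab: i for i, lab in enumerate(labels)}
    rows, rhs, names = [], [], []
    for key, f in _face_keys(cm):
        row = np.zeros(len(labels))
        for d in f:
            row[col[cm.edge_labels[d]]] += 1.0
        rows.append(row)
        rhs.append(2.0 * math.pi)
        names.append(key)
    facial = {frozenset(labs) for labs in cm.face_label_sets().values()}
    verts = cm.vertices()
    vid = {d: i for i, v in enumerate(verts) for d in v}
    gx = nx.Graph()
    gx.add_nodes_from(range(len(verts)))
    cyc_rows = []
    seen_parallel = set()
    for d, t in cm.edges():
        a, b = vid[d], vid[t]
        if gx.has_edge(a, b):
            pair = frozenset((cm.edge_labels[gx.edges[a, b]["dart"]], cm.edge_labels[d]))
            if pair not in facial and pair not in seen_parallel:
                seen_parallel.add(pair)
                row = np.zeros(len(labels))
                for lab in pair:
                    row[col[lab]] += 1.0
                cyc_rows.append(row)
        else:
            gx.add_edge(a, b, dart=d)
    for cycle in nx.simple_cycles(gx, length_bound=min(max_cycle_len, cm.n_edges)):
        labs = [
            cm.edge_labels[gx.edges[a, b]["dart"]]
            for a, b in zip(cycle, cycle[1:] + cycle[:1])
        ]
        if frozenset(labs) in facial:
            continue
        row = np.zeros(len(labels))
        for lab in labs:
            row[col[lab]] += 1.0
        cyc_rows.append(row)
    A_ub = -np.array(cyc_rows) if cyc_rows else None
    b_ub = np.full(len(cyc_rows), -2.0 * math.pi) if cyc_rows else None
    return HPolytope(
        variables=labels,
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=[(0.0, math.pi)] * len(labels),
        A_ub=A_ub,
        b_ub=b_ub,
        row_names=names,
    )


def is_feasible(P: HPolytope) -> tuple[bool, np.ndarray | None]:
    """Linear-programming feasibility of the closed system, with witness."""
    res = linprog(
        c=np.zeros(P.n_vars),
        A_eq=P.A_eq if len(P.A_eq) else None,
        b_eq=P.b_eq if len(P.A_eq) else None,
        A_ub=P.A_ub,
        b_ub=P.b_ub,
        bounds=P.bounds,
        method="highs",
    )
    return (res.status == 0, res.x if res.status == 0 else None)


def interior_point(P: HPolytope, tol: float = LP_TOL) -> np.ndarray | None:
    """Max-min-slack point of the bounds within the equality subspace.

    Maximizes a uniform slack s with ``lo + s <= x_i <= hi - s`` (and slack
    on any inequality rows), a Chebyshev-style center.  Returns ``None``
    when the relative interior with respect to the bounds is empty.
    """
    m = P.n_vars
    c = np.zeros(m + 1)
    c[-1] = -1.0  # maximize s
    rows, rhs = [], []
    for i, (lo, hi) in enumerate(P.bounds):
        r = np.zeros(m + 1)
        r[i], r[-1] = -1.0, 1.0   # -x_i + s <= -lo
        rows.append(r)
        rhs.append(-lo)
        r = np.zeros(m + 1)
        r[i], r[-1] = 1.0, 1.0    # x_i + s <= hi
        rows.append(r)
        rhs.append(hi)
    if P.A_ub is not None and len(P.A_ub):
        for row, b in zip(P.A_ub, P.b_ub):
            r = np.concatenate([row, [1.0]])
            rows.append(r)
            rhs.append(b)
    A_eq = None
    b_eq = None
    if len(P.A_eq):
        A_eq = np.hstack([P.A_eq, np.zeros((len(P.A_eq), 1))])
        b_eq = P.b_eq
    res = linprog(
        c, A_ub=np.array(rows), b_ub=np.array(rhs), A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * m + [(0.0, None)], method="highs",
    )
    if res.status != 0 or res.x[-1] <= tol:
        return None
    return res.x[:-1]


def enumerate_vertices(P: HPolytope, tol: float = LP_TOL) -> list[np.ndarray]:
    """All vertices of an equality-plus-bounds polytope, by brute force.

    For each way of pinning enough variables to their bounds to make the
    combined linear system uniquely solvable, solve and keep the feasible
    solutions, deduplicating within ``tol``.  Exact but exponential; capped
    at 24 variables and about a million candidate pinnings.
    """
    if P.A_ub is not None and len(P.A_ub):
        raise PolytopeError("vertex enumeration supports equality+bounds systems only")
    m = P.n_vars
    if m > 24:
        raise PolytopeError(f"too many variables for brute-force enumeration ({m})")
    A = P.A_eq if len(P.A_eq) else np.zeros((0, m))
    r = np.linalg.matrix_rank(A) if len(A) else 0
    d = m - r
    n_cand = math.comb(m, d) * (2 ** d)
    if n_cand > 1 << 20:
        raise PolytopeError(
            f"brute-force enumeration would examine {n_cand} pinnings; "
            "system too large"
        )
    out: list[np.ndarray] = []

    def push(x):
        for y in out:
            if np.max(np.abs(x - y)) <= 1e-9:
                return
        out.append(x)

    lo = np.array([b[0] for b in P.bounds])
    hi = np.array([b[1] for b in P.bounds])
    if d == 0:
        x, *_ = np.linalg.lstsq(A, P.b_eq, rcond=None)
        if P.contains(x, tol=1e-9):
            push(x)
        return out
    for subset in itertools.combinations(range(m), d):
        base = np.zeros((d, m))
        for i, j in enumerate(subset):
            base[i, j] = 1.0
        M = np.vstack([A, base])
        if np.linalg.matrix_rank(M) < m:
            continue
        for pick in itertools.product((0, 1), repeat=d):
            vals = [hi[j] if s else lo[j] for j, s in zip(subset, pick)]
            rhs = np.concatenate([P.b_eq, vals])
            x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            if np.max(np.abs(M @ x - rhs)) > 1e-9:
                continue
            if np.all(x >= lo - 1e-9) and np.all(x <= hi + 1e-9):
                push(np.clip(x, lo, hi))
    return out


def contraction_facet(P: HPolytope, var) -> HPolytope:
    """The facet ``x_var = 0``: the load system of the contracted graph,
    lifted by the vanishing coordinate."""
    i = P.index(var)
    bounds = list(P.bounds)
    bounds[i] = (0.0, 0.0)
    return HPolytope(
        variables=list(P.variables),
        A_eq=P.A_eq.copy(),
        b_eq=P.b_eq.copy(),
        bounds=bounds,
        A_ub=None if P.A_ub is None else P.A_ub.copy(),
        b_ub=None if P.b_ub is None else P.b_ub.copy(),
        row_names=list(P.row_names),
    )


@dataclass
class ComplexNode:
    code: str                      # labeled canonical code
    map: CombinatorialMap
    polytope: HPolytope


@dataclass
class ComplexMove:
    node_a: str
    node_b: str
    pivot: object                  # edge label of the pivot edge
    shared_code: str               # labeled code of the common contracted map


@dataclass
class PolytopeComplex:
    """Labeled cubic maps connected by Whitehead moves, each carrying its
    load polytope, with shared contraction facets recorded per move."""

    nodes: dict[str, ComplexNode]
    moves: list[ComplexMove]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_complex(seed: CombinatorialMap, T=1.0, n_cap: int = 6) -> PolytopeComplex:
    """Close a labeled cubic seed under Whitehead moves and attach polytopes.

    Labels are inherited through each move (the pivot edge keeps its label
    on the re-expanded edge), so every node's polytope lives in coordinates
    indexed by the same label set.  Nodes are identified by labeled
    canonical code: symmetric relabelings appear as distinct nodes, mirroring
    the redundancy of coordinates in the full complex.  Each move records
    the common contracted map and the shared facet ``x_pivot = 0``.
    """
    if not seed.is_cubic():
        raise PolytopeError("complex seed must be cubic")
    if seed.n_faces > n_cap:
        raise PolytopeError(f"face count {seed.n_faces} exceeds cap {n_cap}")
    seed = ensure_edge_labels(seed)
    code0 = canonical_code(seed, with_labels=True)
    nodes = {code0: ComplexNode(code0, seed, build_load_system(seed, T))}
    moves: list[ComplexMove] = []
    seen_moves: set[frozenset] = set()
    frontier = [seed]
    while frontier:
        m = frontier.pop()
        ca = canonical_code(m, with_labels=True)
        for d, _ in m.edges():
            try:
                moved = whitehead_move(m, d)
            except MapError:
                continue
            cb = canonical_code(moved, with_labels=True)
            if cb not in nodes:
                nodes[cb] = ComplexNode(cb, moved, build_load_system(moved, T))
                frontier.append(moved)
            pivot = m.edge_labels.get(d)
            key = frozenset((ca, cb, pivot))
            if key not in seen_moves:
                seen_moves.add(key)
                shared = canonical_code(contract_edge(m, d), with_labels=True)
                moves.append(ComplexMove(ca, cb, pivot, shared))
    return PolytopeComplex(nodes, moves)
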