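"""Sphere-embedded multigraphs as combinatorial maps, and the moves between them.

A combinatorial map (rotation system) encodes a graph embedded in an oriented
surface by two permutations on a finite set of *darts* (half-edges):

* ``rotation`` sends each dart to the next dart counterclockwise around its
  vertex, so vertices are the orbits of ``rotation``;
* ``twin`` is a fixed-point-free involution pairing the two darts of each
  edge, so edges are the orbits of ``twin``;
* faces are the orbits of the composite ``d -> rotation[twin[d]]``.

The map lives on the sphere exactly when Euler's relation ``V - E + F = 2``
holds, which is enforced at construction.  Migration graphs additionally have
no self-loops (the two ends of every edge are distinct vertices): a population
cannot be completely enclosed by a single other population.

Three moves connect migration graphs with the same number of faces
(populations): *contraction* collapses an edge and fuses its endpoints,
*expansion* splits a vertex of degree >= 4 into two vertices joined by a new
edge, and the *Whitehead move* on an edge of a cubic (all degrees 3) map is a
contraction followed by the unique alternative expansion.  The space of all
such maps with ``n`` faces, up to orientation-preserving or -reversing sphere
homeomorphism, is stratified into layers by *depth*: the number of
contractions separating a map from the cubic stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


class MapError(ValueError):
    """Raised when an operation would produce an invalid migration graph."""


def _orbits(perm: dict[int, int]) -> list[tuple[int, ...]]:
    seen: set[int] = set()
    out = []
    for d in sorted(perm):
        if d in seen:
            continue
        orb = [d]
        seen.add(d)
        x = perm[d]
        while x != d:
            orb.append(x)
            seen.add(x)
            x = perm[x]
        out.append(tuple(orb))
    return out


@dataclass
class CombinatorialMap:
    """A connected multigraph embedded in the sphere, as a rotation system.

    Parameters
    ----------
    rotation
        Permutation of darts: next dart counterclockwise around the vertex.
    twin
        Fixed-point-free involution pairing the darts of each edge.
    edge_labels
        Optional map from *each* dart to the label of its edge (both darts of
        an edge carry the same label).
    vertex_names, face_names
        Optional names, stored per dart and constant on the vertex (resp.
        face) orbit containing the dart.  For a Voronoi map the faces are the
        populations; for a Delaunay map the vertices are.
    """

    rotation: dict[int, int]
    twin: dict[int, int]
    edge_labels: dict[int, object] = field(default_factory=dict)
    vertex_names: dict[int, str] = field(default_factory=dict)
    face_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -------------------------------------------------------
    def darts(self) -> list[int]:
        return sorted(self.rotation)

    def vertices(self) -> list[tuple[int, ...]]:
        return _orbits(self.rotation)

    def edges(self) -> list[tuple[int, int]]:
        return [(d, self.twin[d]) for d in sorted(self.twin) if d < self.twin[d]]

    def face_permutation(self) -> dict[int, int]:
        return {d: self.rotation[self.twin[d]] for d in self.rotation}

    def faces(self) -> list[tuple[int, ...]]:
        return _orbits(self.face_permutation())

    @property
    def n_vertices(self) -> int:
        return len(self.vertices())

    @property
    def n_edges(self) -> int:
        return len(self.twin) // 2

    @property
    def n_faces(self) -> int:
        return len(self.faces())

    def vertex_cycle(self, d: int) -> tuple[int, ...]:
        """The rotation orbit through dart ``d``, starting at ``d``."""
        orb = [d]
        x = self.rotation[d]
        while x != d:
            orb.append(x)
            x = self.rotation[x]
        return tuple(orb)

    def degree(self, d: int) -> int:
        return len(self.vertex_cycle(d))

    def is_cubic(self) -> bool:
        return all(len(v) == 3 for v in self.vertices())

    def edge_label(self, d: int):
        return self.edge_labels.get(d)

    def darts_of_label(self, label) -> tuple[int, int]:
        for d, lab in self.edge_labels.items():
            if lab == label:
                return (d, self.twin[d]) if d < self.twin[d] else (self.twin[d], d)
        raise KeyError(f"no edge with label {label!r}")

    def face_label_sets(self) -> dict[int, list]:
        """Edge labels around each face, keyed by the face's smallest dart."""
        return {f[0]: [self.edge_labels[d] for d in f] for f in self.faces()}

    def depth(self) -> int:
        """Number of contractions separating this map from the cubic stratum.

        For ``n`` faces a cubic map has ``3n - 6`` edges, and each contraction
        removes one edge, so depth is ``(3n - 6) - E``.
        """
        return (3 * self.n_faces - 6) - self.n_edges

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        darts = set(self.rotation)
        if not darts:
            raise MapError("empty map")
        if set(self.rotation.values()) != darts or set(self.twin) != darts:
            raise MapError("rotation/twin are not permutations of the same darts")
        for d, t in self.twin.items():
            if t == d:
                raise MapError(f"twin has fixed point at dart {d}")
            if self.twin[t] != d:
                raise MapError("twin is not an involution")
        verts = self.vertices()
        if len(verts) < 2:
            raise MapError("a migration graph has at least two vertices")
        dart_vertex = {d: i for i, v in enumerate(verts) for d in v}
        for d, t in self.twin.items():
            if dart_vertex[d] == dart_vertex[t]:
                raise MapError(f"self-loop at edge ({d},{t}): edge ends must differ")
        if len(verts) - self.n_edges + self.n_faces != 2:
            raise MapError("map is not spherical: V - E + F != 2")
        # connectivity under the group generated by rotation and twin
        seen = {next(iter(darts))}
        stack = list(seen)
        while stack:
            d = stack.pop()
            for x in (self.rotation[d], self.twin[d]):
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        if seen != darts:
            raise MapError("map is not connected")

    # -- convenience -----------------------------------------------------
    def copy(self) -> "CombinatorialMap":
        return CombinatorialMap(
            dict(self.rotation),
            dict(self.twin),
            dict(self.edge_labels),
            dict(self.vertex_names),
            dict(self.face_names),
        )

    def counts(self) -> tuple[int, int, int]:
        return (self.n_vertices, self.n_edges, self.n_faces)


# -- generators ----------------------------------------------------------

def make_Cn(n: int) -> CombinatorialMap:
    """The deepest map with ``n`` faces: two vertices joined by ``n`` edges.

    This is the pattern of ``n`` populations strung along a single great
    circle; every face is a bigon.
    """
    if n < 2:
        raise MapError("C_n needs n >= 2")
    rotation: dict[int, int] = {}
    twin: dict[int, int] = {}
    for i in range(n):
        a, b = 2 * i, 2 * i + 1
        twin[a], twin[b] = b, a
        rotation[a] = 2 * ((i + 1) % n)
        rotation[b] = 2 * ((i - 1) % n) + 1
    return CombinatorialMap(rotation, twin)


def make_CLn(n: int) -> CombinatorialMap:
    """The prism over an (n-2)-gon: the cubic generator with ``n`` faces.

    Two concentric copies of a regular (n-2)-gon joined rung by rung; it has
    ``2n - 4`` vertices, ``3n - 6`` edges and ``n`` faces, all degrees 3, and
    generates the whole cubic stratum under Whitehead moves.
    """
    if n < 4:
        raise MapError("CL_n needs n >= 4")
    m = n - 2
    rotation: dict[int, int] = {}
    twin: dict[int, int] = {}
    # edge dart ids: outer o_i -> (6i, 6i+1), inner i_i -> (6i+2, 6i+3),
    # spoke s_i -> (6i+4 at u_i, 6i+5 at v_i); indices mod m.
    for i in range(m):
        twin[6 * i], twin[6 * i + 1] = 6 * i + 1, 6 * i
        twin[6 * i + 2], twin[6 * i + 3] = 6 * i + 3, 6 * i + 2
        twin[6 * i + 4], twin[6 * i + 5] = 6 * i + 5, 6 * i + 4
    for i in range(m):
        j = (i - 1) % m
        # outer vertex u_i, counterclockwise seen from outside the prism
        rotation[6 * i] = 6 * i + 4          # o_i -> s_i
        rotation[6 * i + 4] = 6 * j + 1      # s_i -> o_{i-1} (far end)
        rotation[6 * j + 1] = 6 * i          # o_{i-1} (far end) -> o_i
        # inner vertex v_i, opposite chirality
        rotation[6 * i + 2] = 6 * j + 3      # i_i -> i_{i-1} (far end)
        rotation[6 * j + 3] = 6 * i + 5      # i_{i-1} (far end) -> s_i
        rotation[6 * i + 5] = 6 * i + 2      # s_i -> i_i
    cm = CombinatorialMap(rotation, twin)
    assert cm.counts() == (2 * n - 4, 3 * n - 6, n)
    return cm


def make_tetrahedron() -> CombinatorialMap:
    """The complete graph on four vertices embedded as a tetrahedron."""
    # vertices 0..3; edge (i,j) i<j gets a dart pair
    pairs = list(itertools.combinations(range(4), 2))
    dart_at = {}
    twin = {}
    for k, (i, j) in enumerate(pairs):
        twin[2 * k], twin[2 * k + 1] = 2 * k + 1, 2 * k
        dart_at[(i, j)] = 2 * k
        dart_at[(j, i)] = 2 * k + 1
    # rotations chosen as the boundary orientation of a geometric tetrahedron
    cycles = {
        0: [dart_at[(0, 1)], dart_at[(0, 2)], dart_at[(0, 3)]],
        1: [dart_at[(1, 0)], dart_at[(1, 3)], dart_at[(1, 2)]],
        2: [dart_at[(2, 0)], dart_at[(2, 1)], dart_at[(2, 3)]],
        3: [dart_at[(3, 0)], dart_at[(3, 2)], dart_at[(3, 1)]],
    }
    rotation = {}
    for cyc in cycles.values():
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            rotation[a] = b
    cm = CombinatorialMap(rotation, twin)
    assert cm.counts() == (4, 6, 4)
    return cm


# -- moves ---------------------------------------------------------------

def contract_edge(cm: CombinatorialMap, d: int) -> CombinatorialMap:
    """Collapse the edge through dart ``d``, fusing its two endpoints.

    The rotation at the fused vertex concatenates the cyclic order at each
    endpoint starting just after the contracted darts, so all other edges are
    topologically preserved.  Contraction is refused when it would fuse the
    last two vertices or turn a parallel edge into a self-loop.
    """
    d2 = cm.twin[d]
    ucyc = cm.vertex_cycle(d)
    if d2 in ucyc:
        raise MapError("cannot contract a self-loop")
    vcyc = cm.vertex_cycle(d2)
    if cm.n_vertices == 2:
        raise MapError("contraction would leave a single vertex")
    vset = set(vcyc)
    for a in ucyc:
        if a != d and cm.twin[a] in vset:
            raise MapError(
                f"edge ({d},{d2}) has a parallel edge; contraction would "
                "create a self-loop"
            )
    rotation = dict(cm.rotation)
    twin = dict(cm.twin)
    labels = dict(cm.edge_labels)
    for x in (d, d2):
        del rotation[x], twin[x]
        labels.pop(x, None)
    merged = list(ucyc[1:]) + list(vcyc[1:])
    for a, b in zip(merged, merged[1:] + merged[:1]):
        rotation[a] = b
    vertex_names = {k: v for k, v in cm.vertex_names.items() if k in rotation}
    nu, nv = cm.vertex_names.get(d), cm.vertex_names.get(d2)
    if nu is not None and nv is not None:
        fused = nu if nu == nv else f"{nu}|{nv}"
        for a in merged:
            vertex_names[a] = fused
    face_names = {k: v for k, v in cm.face_names.items() if k in rotation}
    return CombinatorialMap(rotation, twin, labels, vertex_names, face_names)


def expand_vertex(
    cm: CombinatorialMap,
    arc1: tuple[int, ...],
    arc2: tuple[int, ...],
    label=None,
) -> CombinatorialMap:
    """Split a vertex of degree >= 4 into two vertices joined by a new edge.

    ``arc1`` and ``arc2`` are the two contiguous arcs (each of >= 2 darts)
    into which the vertex's rotation is cut; each keeps its cyclic order and
    receives one dart of the new edge, so the two new valences sum to the old
    valence plus two.  Exact inverse of :func:`contract_edge`.
    """
    arc1, arc2 = tuple(arc1), tuple(arc2)
    if len(arc1) < 2 or len(arc2) < 2:
        raise MapError("each arc of a vertex split needs at least 2 darts")
    cyc = cm.vertex_cycle(arc1[0])
    if len(cyc) != len(arc1) + len(arc2):
        raise MapError("arcs do not partition the vertex rotation")
    k = len(arc1)
    rotations = [cyc[i:] + cyc[:i] for i in range(len(cyc))]
    if tuple(arc1 + arc2) not in rotations:
        raise MapError("arcs are not contiguous in the vertex rotation")
    nd1 = max(cm.rotation) + 1
    nd2 = nd1 + 1
    rotation = dict(cm.rotation)
    twin = dict(cm.twin)
    twin[nd1], twin[nd2] = nd2, nd1
    for arc, nd in ((arc1, nd1), (arc2, nd2)):
        chain = list(arc) + [nd]
        for a, b in zip(chain, chain[1:] + chain[:1]):
            rotation[a] = b
    labels = dict(cm.edge_labels)
    if label is not None:
        labels[nd1] = labels[nd2] = label
    vertex_names = dict(cm.vertex_names)
    old = cm.vertex_names.get(arc1[0])
    if old is not None:
        vertex_names[nd1] = vertex_names[nd2] = old
    out = CombinatorialMap(rotation, twin, labels, vertex_names, dict(cm.face_names))
    # new darts join existing faces; propagate that face's name if it has one
    for f in out.faces():
        names = {out.face_names[x] for x in f if x in out.face_names}
        if len(names) == 1:
            nm = names.pop()
            for x in f:
                out.face_names[x] = nm
    return out


def whitehead_move(cm: CombinatorialMap, d: int) -> CombinatorialMap:
    """Contract the edge through ``d`` and re-expand the other way.

    Defined on cubic maps only; the result is again cubic with the same
    vertex, edge and face counts, and the new edge inherits the old edge's
    label.  Applying the move to the new edge undoes it.
    """
    if not cm.is_cubic():
        raise MapError("Whitehead moves are defined on cubic maps only")
    d2 = cm.twin[d]
    ucyc = cm.vertex_cycle(d)
    vcyc = cm.vertex_cycle(d2)
    if d2 in ucyc:
        raise MapError("cannot perform a Whitehead move on a self-loop")
    label = cm.edge_labels.get(d)
    contracted = contract_edge(cm, d)  # fused cycle (a, b, c, e)
    a, b = ucyc[1], ucyc[2]
    c, e = vcyc[1], vcyc[2]
    return expand_vertex(contracted, (b, c), (e, a), label=label)


def dual(cm: CombinatorialMap) -> CombinatorialMap:
    """The dual map: faces and vertices exchange, edges (and labels) persist.

    One vertex is marked inside each face and each edge is redrawn between
    the marks on its two sides.  An involution: ``dual(dual(m))`` has exactly
    the original permutations.
    """
    rotation = {d: cm.rotation[cm.twin[d]] for d in cm.rotation}
    return CombinatorialMap(
        rotation,
        dict(cm.twin),
        dict(cm.edge_labels),
        vertex_names=dict(cm.face_names),
        face_names=dict(cm.vertex_names),
    )


# -- equivalence ---------------------------------------------------------

def _encode(cm: CombinatorialMap, start: int, rot: dict[int, int],
            with_labels: bool) -> tuple:
    index = {start: 0}
    order = [start]
    out = []
    i = 0
    while i < len(order):
        d = order[i]
        i += 1
        for nxt in (rot[d], cm.twin[d]):
            if nxt not in index:
                index[nxt] = len(order)
                order.append(nxt)
        if with_labels:
            out.append((index[rot[d]], index[cm.twin[d]], cm.edge_labels.get(d)))
        else:
            out.append((index[rot[d]], index[cm.twin[d]]))
    return tuple(out)


def canonical_code(cm: CombinatorialMap, with_labels: bool = False) -> str:
    """A string invariant of the map under dart relabeling and reflection.

    The breadth-first encoding from a starting dart relabels darts in
    traversal order, which makes it independent of dart identities; taking
    the minimum over all starting darts and both orientations (the reversed
    rotation is the mirror image) yields a canonical form.  Two maps are
    equivalent as sphere embeddings iff their codes are equal.  With
    ``with_labels`` the edge labels enter the encoding, distinguishing
    labeled maps.
    """
    rot = cm.rotation
    rinv = {v: k for k, v in rot.items()}
    best = None
    for r in (rot, rinv):
        for start in cm.rotation:
            code = _encode(cm, start, r, with_labels)
            if best is None or code < best:
                best = code
    return ";".join(",".join(str(x) for x in t) for t in best)


# -- move enumeration and the layered space ------------------------------

def all_contractions(cm: CombinatorialMap):
    """Yield ``(dart, contracted_map)`` for every admissible contraction."""
    for d, d2 in cm.edges():
        try:
            yield d, contract_edge(cm, d)
        except MapError:
            continue


def all_expansions(cm: CombinatorialMap):
    """Yield ``(arcs, expanded_map)`` over all vertices and contiguous splits."""
    for v in cm.vertices():
        k = len(v)
        if k < 4:
            continue
        for start in range(k):
            cyc = v[start:] + v[:start]
            for s in range(2, k - 1):
                arc1, arc2 = cyc[:s], cyc[s:]
                yield (arc1, arc2), expand_vertex(cm, arc1, arc2)


def all_whiteheads(cm: CombinatorialMap):
    """Yield ``(dart, moved_map)`` for every admissible Whitehead move."""
    if not cm.is_cubic():
        return
    for d, d2 in cm.edges():
        try:
            yield d, whitehead_move(cm, d)
        except MapError:
            continue


def enumerate_combms(n: int, max_depth: int | None = None) -> list[dict[str, CombinatorialMap]]:
    """All migration graphs with ``n`` faces, stratified by depth.

    Layer 0 is the closure of the prism generator under Whitehead moves (for
    ``n = 3`` the unique cubic map is already the two-vertex theta graph);
    deeper layers are the images of the layer above under all admissible
    contractions, deduplicated by canonical code.  The deepest layer, at
    depth ``2n - 6``, contains the single two-vertex map.

    Returns a list indexed by depth of ``{canonical_code: map}`` dicts.
    """
    if not 3 <= n <= 8:
        raise MapError("enumeration supported for 3 <= n <= 8")
    seed = make_Cn(3) if n == 3 else make_CLn(n)
    layer0: dict[str, CombinatorialMap] = {canonical_code(seed): seed}
    frontier = list(layer0.items())
    while frontier:
        code, m = frontier.pop()
        for _, moved in all_whiteheads(m):
            c = canonical_code(moved)
            if c not in layer0:
                layer0[c] = moved
                frontier.append((c, moved))
    depth_max = 3 * n - 6 - n  # edges of a cubic map down to the n of C_n
    if max_depth is not None:
        depth_max = min(depth_max, max_depth)
    layers = [layer0]
    for _ in range(depth_max):
        nxt: dict[str, CombinatorialMap] = {}
        for m in layers[-1].values():
            for _, mc in all_contractions(m):
                nxt[canonical_code(mc)] = mc
        layers.append(nxt)
    return layers


def random_map(n: int, n_moves: int, rng) -> CombinatorialMap:
    """A random map with ``n`` faces, by a random walk of admissible moves."""
    cm = make_CLn(n) if n >= 4 else make_Cn(3)
    for _ in range(n_moves):
        moves = [m for _, m in all_whiteheads(cm)]
        moves += [m for _, m in all_contractions(cm)]
        moves += [m for _, m in all_expansions(cm)]
        if not moves:
            break
        cm = moves[rng.integers(len(moves))]
    return cm
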