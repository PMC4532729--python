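"""Spherical geometry: Delaunay triangulation of population points on the
unit sphere, circumscribed caps, inner intersection angles, and the Voronoi
dual map.

Populations are given as geographic coordinates in decimal degrees and placed
on the unit sphere (angles are scale invariant, so no Earth radius enters).
The Delaunay cell decomposition is computed by brute force: a triple of
points is a Delaunay triangle iff all remaining points lie strictly on one
side of the plane through the three points — equivalently, one of the two
spherical caps bounded by the triangle's circumscribed circle is empty.  The
test examines all C(n,3) triples, which is entirely adequate at the scales
this package targets (n up to a few tens) and remains correct in the
clustered regime — points confined to a small cap — where the far side of
the sphere is covered by a few very large triangles.

Each Delaunay edge separates two triangles whose circumscribed circles meet
at the edge's endpoints; the inner intersection angle θ of the two circles,
computed from the spherical law of cosines, is the edge's geometric weight.
Around every population the incident θ sum to 2π — the face condition of
Rivin's circle-pattern theorem — which the pattern module checks explicitly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .combmaps import CombinatorialMap, dual

PLANE_TOL = 1e-12  # sidedness tolerance on signed plane distance
CLAMP_TOL = 1e-9   # numerical-conditioning tolerance for arccos arguments


class DegenerateGeometryError(ValueError):
    """Raised for polar/coincident points or near-cocircular quadruples."""


@dataclass(frozen=True)
class GeoPopulation:
    """A named population at geographic coordinates (decimal degrees).

    Longitudes in [-180, 360] are accepted and normalized to (-180, 180];
    the poles are rejected as degenerate for tangent-plane constructions.
    """

    name: str
    longitude: float
    latitude: float

    def __post_init__(self):
        if not (math.isfinite(self.longitude) and math.isfinite(self.latitude)):
            raise DegenerateGeometryError(f"{self.name}: non-finite coordinates")
        if not -90 < self.latitude < 90:
            raise DegenerateGeometryError(
                f"{self.name}: latitude {self.latitude} is polar or out of range"
            )
        lon = self.longitude
        if not -180 <= lon <= 360:
            raise DegenerateGeometryError(f"{self.name}: longitude {lon} out of range")
        lon = (lon + 180.0) % 360.0 - 180.0
        if lon == -180.0:
            lon = 180.0
        object.__setattr__(self, "longitude", lon)

    @property
    def xyz(self) -> np.ndarray:
        return latlon_to_unit(self.longitude, self.latitude)


def latlon_to_unit(lon: float, lat: float) -> np.ndarray:
    """Cartesian unit vector for geographic coordinates in degrees."""
    if not (math.isfinite(lon) and math.isfinite(lat)) or not -90 < lat < 90:
        raise DegenerateGeometryError(f"degenerate coordinates ({lon}, {lat})")
    lo, la = math.radians(lon), math.radians(lat)
    return np.array(
        [math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)]
    )


def angular_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Great-circle arc length between two unit vectors, in [0, pi]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    for w in (u, v):
        if abs(np.linalg.norm(w) - 1.0) > 1e-9:
            raise ValueError("angular_distance expects unit vectors")
    return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))


@dataclass(frozen=True)
class Circumcircle:
    """Circumscribed circle of a spherical triangle: the pole of its empty
    cap and the spherical radius (radians) to the triangle's vertices."""

    center: np.ndarray
    radius: float


@dataclass
class DelaunayComplex:
    """The spherical Delaunay triangulation of a set of populations.

    ``triangles`` maps sorted vertex-index triples to circumcircles;
    ``edges`` maps sorted index pairs to ``(label, (tri1, tri2))`` where the
    integer labels are assigned in lexicographic order of the sorted
    population-name pairs; ``angles`` maps labels to inner intersection
    angles.  For ``n`` points in general position there are ``2n - 4``
    triangles and ``3n - 6`` edges, each edge adjacent to exactly two
    triangles.
    """

    populations: list[GeoPopulation]
    points: np.ndarray
    triangles: dict[tuple[int, int, int], Circumcircle]
    edges: dict[tuple[int, int], tuple[int, tuple[tuple[int, int, int], tuple[int, int, int]]]]
    angles: dict[int, float]
    n_candidates: int

    _name_idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._name_idx = {p.name: i for i, p in enumerate(self.populations)}

    def index(self, name: str) -> int:
        return self._name_idx[name]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def label_pairs(self) -> dict[int, tuple[str, str]]:
        """Edge label -> sorted population-name pair."""
        return {
            lab: tuple(sorted((self.names[i], self.names[j])))
            for (i, j), (lab, _) in self.edges.items()
        }

    def pair_labels(self) -> dict[frozenset, int]:
        return {
            frozenset((self.names[i], self.names[j])): lab
            for (i, j), (lab, _) in self.edges.items()
        }

    def incident_labels(self, name: str) -> list[int]:
        i = self.index(name)
        return sorted(lab for (a, b), (lab, _) in self.edges.items() if i in (a, b))


def _plane(points: np.ndarray, tri: tuple[int, int, int]):
    i, j, k = tri
    n = np.cross(points[j] - points[i], points[k] - points[i])
    norm = np.linalg.norm(n)
    if norm < PLANE_TOL:
        raise DegenerateGeometryError(f"collinear triangle vertices {tri}")
    n = n / norm
    return n, float(n @ points[i])


def circumcircle(tri: tuple[int, int, int], points: np.ndarray) -> Circumcircle:
    """Circumcircle of an accepted Delaunay triangle.

    The center is the unit normal of the triangle's plane, signed so that it
    is the pole of the empty cap (away from all remaining points); the
    radius is the angular distance from the center to any vertex.
    """
    n, c = _plane(points, tri)
    rest = [m for m in range(len(points)) if m not in tri]
    if rest:
        side = np.array([n @ points[m] - c for m in rest])
        if np.all(side < -PLANE_TOL):
            center = n
        elif np.all(side > PLANE_TOL):
            center = -n
        else:
            raise DegenerateGeometryError(
                f"triangle {tri} has no empty circumscribed cap"
            )
    else:
        center = n
    return Circumcircle(center, angular_distance(center, points[tri[0]]))


def delaunay_triangulate(populations: list[GeoPopulation]) -> DelaunayComplex:
    """Brute-force spherical Delaunay triangulation by the empty-cap test.

    Examines every one of the C(n,3) candidate triples; a triple is accepted
    iff all remaining points lie strictly on one side of its plane.  Raises
    :class:`DegenerateGeometryError` when a remaining point lies within
    tolerance of an otherwise-empty candidate plane (four nearly cocircular
    points), rather than silently choosing one of the two triangulations.
    """
    n = len(populations)
    if n < 4:
        raise ValueError("need at least 4 populations to triangulate the sphere")
    names = [p.name for p in populations]
    if len(set(names)) != n:
        raise ValueError("population names must be unique")
    points = np.array([p.xyz for p in populations])
    for i, j in itertools.combinations(range(n), 2):
        if angular_distance(points[i], points[j]) < 1e-9:
            raise DegenerateGeometryError(
                f"populations {names[i]} and {names[j]} coincide"
            )

    triangles: dict[tuple[int, int, int], Circumcircle] = {}
    n_candidates = 0
    for tri in itertools.combinations(range(n), 3):
        n_candidates += 1
        nvec, c = _plane(points, tri)
        rest = [m for m in range(n) if m not in tri]
        side = np.array([nvec @ points[m] - c for m in rest])
        near = np.abs(side) <= PLANE_TOL
        if near.any():
            others = side[~near]
            if others.size == 0 or np.all(others < 0) or np.all(others > 0):
                bad = [names[rest[q]] for q in np.nonzero(near)[0]]
                raise DegenerateGeometryError(
                    f"near-cocircular points: triangle "
                    f"{tuple(names[v] for v in tri)} with {bad} on its plane"
                )
            continue
        if np.all(side < 0):
            center = nvec
        elif np.all(side > 0):
            center = -nvec
        else:
            continue
        triangles[tri] = Circumcircle(center, angular_distance(center, points[tri[0]]))

    # edge -> adjacent triangles
    adj: dict[tuple[int, int], list] = {}
    for tri in triangles:
        for e in itertools.combinations(tri, 2):
            adj.setdefault(e, []).append(tri)
    for e, ts in adj.items():
        if len(ts) != 2:
            raise DegenerateGeometryError(
                f"edge {tuple(names[v] for v in e)} adjacent to {len(ts)} "
                "triangles; point set is not in general position"
            )
    if len(triangles) != 2 * n - 4 or len(adj) != 3 * n - 6:
        raise DegenerateGeometryError(
            f"unexpected complex size: {len(triangles)} triangles, "
            f"{len(adj)} edges for n={n}"
        )

    # deterministic integer labels: lexicographic order of sorted name pairs
    by_name = sorted(adj, key=lambda e: tuple(sorted((names[e[0]], names[e[1]]))))
    edges = {e: (lab, tuple(adj[e])) for lab, e in enumerate(by_name, start=1)}

    complex_ = DelaunayComplex(list(populations), points, triangles, edges, {}, n_candidates)
    complex_.angles = {
        lab: edge_inner_angle(e, complex_) for e, (lab, _) in edges.items()
    }
    return complex_


def edge_inner_angle(edge: tuple[int, int], complex_: DelaunayComplex) -> float:
    """Inner intersection angle of the two circumcircles flanking an edge.

    With circumcircles (V1, r1) and (V2, r2) and D the angular distance
    between the centers, the spherical law of cosines in the triangle
    V1-P-V2 (P a shared endpoint) gives

        cos(theta) = (cos D - cos r1 cos r2) / (sin r1 sin r2),

    the same value at either endpoint.  The result lies strictly in (0, pi)
    for distinct intersecting circles.
    """
    edge = tuple(sorted(edge))
    _, (t1, t2) = complex_.edges[edge]
    c1, c2 = complex_.triangles[t1], complex_.triangles[t2]
    for r in (c1.radius, c2.radius):
        if not 0.0 < r < math.pi:
            raise DegenerateGeometryError(f"degenerate circumradius {r}")
    D = angular_distance(c1.center, c2.center)
    arg = (math.cos(D) - math.cos(c1.radius) * math.cos(c2.radius)) / (
        math.sin(c1.radius) * math.sin(c2.radius)
    )
    if arg > 1.0 + CLAMP_TOL or arg < -1.0 - CLAMP_TOL:
        raise DegenerateGeometryError(f"ill-conditioned angle: cos(theta)={arg}")
    return float(math.acos(min(1.0, max(-1.0, arg))))


def delaunay_map(complex_: DelaunayComplex) -> CombinatorialMap:
    """The Delaunay graph as an embedded map (rotation system).

    Every triangle is oriented by its empty-cap pole (the circumcenter
    side); these orientations are globally consistent because the pole
    always faces away from the hull of the point set.  The rotation at each
    population is then the fan of its incident triangles, which is robust
    even for clustered point sets whose cells wrap around the far side of
    the sphere.  Edge labels are carried over from the complex.
    """
    points = complex_.points
    names = complex_.names
    # oriented link: succ[(v, a)] = b for each oriented triangle (v, a, b)
    succ: dict[tuple[int, int], int] = {}
    for tri, circ in complex_.triangles.items():
        i, j, k = tri
        nvec = np.cross(points[j] - points[i], points[k] - points[i])
        order = (i, j, k) if nvec @ circ.center > 0 else (i, k, j)
        for t in range(3):
            v, a, b = order[t], order[(t + 1) % 3], order[(t + 2) % 3]
            succ[(v, a)] = b
    # dart ids: edge with label L -> darts 2(L-1) at the lower-index endpoint,
    # 2(L-1)+1 at the higher
    dart: dict[tuple[int, int], int] = {}
    twin: dict[int, int] = {}
    labels: dict[int, int] = {}
    vnames: dict[int, str] = {}
    for (i, j), (lab, _) in complex_.edges.items():
        d0, d1 = 2 * (lab - 1), 2 * (lab - 1) + 1
        dart[(i, j)], dart[(j, i)] = d0, d1
        twin[d0], twin[d1] = d1, d0
        labels[d0] = labels[d1] = lab
        vnames[d0], vnames[d1] = names[i], names[j]
    rotation: dict[int, int] = {}
    for (v, a), b in succ.items():
        rotation[dart[(v, a)]] = dart[(v, b)]
    cm = CombinatorialMap(rotation, twin, labels, vertex_names=vnames)
    assert cm.n_faces == len(complex_.triangles)
    return cm


def voronoi_dual(complex_: DelaunayComplex) -> CombinatorialMap:
    """The Voronoi diagram of the populations, as an embedded map.

    One vertex per Delaunay triangle (its circumcenter), one edge per
    Delaunay edge (same label), one face per population; all vertex degrees
    are 3 for a simplicial triangulation.  Computed as the dual of the
    Delaunay map, so population names appear as face names.
    """
    return dual(delaunay_map(complex_))
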