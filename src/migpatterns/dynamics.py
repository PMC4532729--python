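"""Temporal dynamics: population splits and mergers, transition
classification, and facet crossings along a migration history.

A population split replaces one point by two daughters an angular distance
``epsilon`` apart, placed symmetrically at +/- epsilon/2 along a chosen
bearing so that the spherical midpoint of the daughters is the ancestor —
which makes the merger of a freshly split pair restore the original
configuration exactly.  For generic small epsilon the Delaunay complex
gains one vertex, three edges and two triangles (forced by Euler's
relation), the local rhomboid of the split; all Delaunay edges not
incident to the parent are preserved.

Between snapshots with the same migration graph, the weight vector moves
inside the graph's load polytope; the graph can only change when the path
reaches a face of that polytope, i.e. when some edge variable hits a bound.
Crossings are detected on the piecewise-linear interpolation between
sampled states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .combmaps import (
    CombinatorialMap,
    MapError,
    all_contractions,
    all_whiteheads,
    canonical_code,
)
from .geo import (
    DelaunayComplex,
    GeoPopulation,
    angular_distance,
    delaunay_triangulate,
)
from .polytopes import HPolytope


class DynamicsError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """A population split: daughter separation ``epsilon`` (radians) along
    the great circle with initial azimuth ``bearing`` (degrees, clockwise
    from north)."""

    population: str
    epsilon: float
    bearing: float = 90.0


def _destination(p: GeoPopulation, bearing_deg: float, dist_rad: float) -> tuple[float, float]:
    """Great-circle destination from ``p``: returns (lon, lat) in degrees."""
    la1 = math.radians(p.latitude)
    lo1 = math.radians(p.longitude)
    br = math.radians(bearing_deg)
    la2 = math.asin(
        math.sin(la1) * math.cos(dist_rad)
        + math.cos(la1) * math.sin(dist_rad) * math.cos(br)
    )
    lo2 = lo1 + math.atan2(
        math.sin(br) * math.sin(dist_rad) * math.cos(la1),
        math.cos(dist_rad) - math.sin(la1) * math.sin(la2),
    )
    return math.degrees(lo2), math.degrees(la2)


def _diff(before: DelaunayComplex, after: DelaunayComplex) -> dict:
    eb = set(map(frozenset, before.pair_labels()))
    ea = set(map(frozenset, after.pair_labels()))
    return {
        "vertices": len(after.populations) - len(before.populations),
        "edges": len(after.edges) - len(before.edges),
        "triangles": len(after.triangles) - len(before.triangles),
        "new_edges": sorted(tuple(sorted(p)) for p in ea - eb),
        "removed_edges": sorted(tuple(sorted(p)) for p in eb - ea),
    }


def split_population(
    populations: list[GeoPopulation],
    spec: SplitSpec,
) -> tuple[list[GeoPopulation], dict]:
    """Split one population into two daughters and re-triangulate.

    The daughters ``<name>_l`` and ``<name>_r`` sit at -/+ epsilon/2 along
    the bearing great circle.  Returns the new population list and a
    structural diff of the Delaunay complex; a warning key is set when the
    perturbation reached beyond the parent's link (epsilon too large for a
    purely local split).
    """
    by_name = {p.name: p for p in populations}
    if spec.population not in by_name:
        raise DynamicsError(f"unknown population {spec.population!r}")
    parent = by_name[spec.population]
    others = [p for p in populations if p.name != spec.population]
    dmin = min(angular_distance(parent.xyz, p.xyz) for p in others)
    if not 0.0 < spec.epsilon < dmin:
        raise DynamicsError(
            f"epsilon must lie in (0, {dmin:.6g}), the distance to the "
            f"nearest other population; got {spec.epsilon}"
        )
    before = delaunay_triangulate(populations)
    half = spec.epsilon / 2.0
    daughters = []
    for suffix, bearing in (("_l", spec.bearing + 180.0), ("_r", spec.bearing)):
        lon, lat = _destination(parent, bearing % 360.0, half)
        daughters.append(GeoPopulation(parent.name + suffix, lon, lat))
    new_pops = others + daughters
    after = delaunay_triangulate(new_pops)
    diff = _diff(before, after)
    touched = {
        pair
        for pair in set(diff["new_edges"]) | set(diff["removed_edges"])
        if not any(
            q in (parent.name, daughters[0].name, daughters[1].name) for q in pair
        )
    }
    diff["nonlocal"] = sorted(touched)
    return new_pops, diff


def merge_populations(
    populations: list[GeoPopulation],
    a: str,
    b: str,
) -> tuple[list[GeoPopulation], dict]:
    """Merge two Delaunay-adjacent populations at their spherical midpoint.

    The reverse of a split: merging a freshly split pair restores the
    parent's position (the normalized chord midpoint of symmetric daughters
    is the ancestor) and hence the original triangulation.
    """
    before = delaunay_triangulate(populations)
    if frozenset((a, b)) not in before.pair_labels():
        raise DynamicsError(f"populations {a!r} and {b!r} are not Delaunay-adjacent")
    by_name = {p.name: p for p in populations}
    pa, pb = by_name[a], by_name[b]
    mid = pa.xyz + pb.xyz
    mid /= np.linalg.norm(mid)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, mid[2]))))
    lon = math.degrees(math.atan2(mid[1], mid[0]))
    if a.endswith("_l") and b.endswith("_r") and a[:-2] == b[:-2]:
        name = a[:-2]
    elif a.endswith("_r") and b.endswith("_l") and a[:-2] == b[:-2]:
        name = a[:-2]
    else:
        name = f"{a}-{b}"
    merged = GeoPopulation(name, lon, lat)
    new_pops = [p for p in populations if p.name not in (a, b)] + [merged]
    after = delaunay_triangulate(new_pops)
    return new_pops, _diff(before, after)


def _as_map(obj) -> CombinatorialMap:
    if isinstance(obj, CombinatorialMap):
        return obj
    if hasattr(obj, "graph"):
        return obj.graph
    raise DynamicsError(f"expected a pattern or map, got {type(obj).__name__}")


def classify_transition(pattern_a, pattern_b) -> tuple[str, object]:
    """Classify the structural event between two consecutive patterns.

    Returns ``(kind, pivot)`` with kind one of ``none`` (equivalent maps),
    ``contraction``/``expansion`` (one edge lost/gained at fixed face
    count, pivot the contracted dart of the larger map), ``whitehead``
    (cubic maps one move apart, pivot the edge label), ``split``/``merge``
    (face count changed by one), or ``unclassified``.
    """
    ma, mb = _as_map(pattern_a), _as_map(pattern_b)
    ca, cb = canonical_code(ma), canonical_code(mb)
    if ca == cb:
        return ("none", None)
    na, nb = ma.n_faces, mb.n_faces
    if nb == na + 1:
        return ("split", None)
    if nb == na - 1:
        return ("merge", None)
    if na == nb:
        if mb.n_edges == ma.n_edges - 1:
            for d, mc in all_contractions(ma):
                if canonical_code(mc) == cb:
                    return ("contraction", d)
        if mb.n_edges == ma.n_edges + 1:
            for d, mc in all_contractions(mb):
                if canonical_code(mc) == ca:
                    return ("expansion", d)
        if ma.is_cubic() and mb.is_cubic() and ma.n_edges == mb.n_edges:
            for d, moved in all_whiteheads(ma):
                if canonical_code(moved) == cb:
                    return ("whitehead", ma.edge_labels.get(d, d))
    return ("unclassified", None)


@dataclass(frozen=True)
class FacetEvent:
    time: float
    variable: object          # edge label reaching a bound
    bound: str                # "lower" | "upper"


def detect_facet_crossing(
    states: list[tuple[float, dict]],
    system: HPolytope,
    tol: float = 1e-9,
    load_tol: float = 1e-6,
) -> list[FacetEvent]:
    """Facet crossings along a piecewise-linear path in one load polytope.

    ``states`` is a time-ordered list of ``(time, weights)`` with weights
    keyed by the system's variables.  Every state must satisfy the load
    equalities within ``load_tol`` (loads are constant while the graph is
    fixed); otherwise the path is inconsistent.  An event is emitted
    whenever the interpolated value of a variable reaches its lower or
    upper bound — the moments at which a contraction becomes admissible.
    """
    if len(states) < 1:
        return []
    times = [t for t, _ in states]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise DynamicsError("state times must be strictly increasing")
    X = []
    for t, w in states:
        x = np.array([float(w[v]) for v in system.variables])
        if len(system.A_eq) and np.max(np.abs(system.A_eq @ x - system.b_eq)) > load_tol:
            raise DynamicsError(
                f"state at t={t} violates the load equalities beyond {load_tol}"
            )
        X.append(x)
    events: list[FacetEvent] = []
    lo = np.array([b[0] for b in system.bounds])
    hi = np.array([b[1] for b in system.bounds])
    for (t1, x1), (t2, x2) in zip(zip(times, X), zip(times[1:], X[1:])):
        for i, var in enumerate(system.variables):
            for bound, bname in ((lo[i], "lower"), (hi[i], "upper")):
                a, b = x1[i] - bound, x2[i] - bound
                if abs(a) <= tol and abs(b) <= tol:
                    continue  # sliding along the facet, not a crossing
                if (a > tol and b < -tol) or (a < -tol and b > tol) or (
                    abs(b) <= tol < abs(a)
                ):
                    frac = a / (a - b) if a != b else 1.0
                    events.append(FacetEvent(t1 + frac * (t2 - t1), var, bname))
                elif abs(a) <= tol < abs(b) and t1 == times[0]:
                    events.append(FacetEvent(t1, var, bname))
    events.sort(key=lambda e: (e.time, str(e.variable)))
    return events
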