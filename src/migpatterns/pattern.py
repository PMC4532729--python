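"""Migration patterns: the 4-tuple M = (G, Theta, W, T) and its validation.

A migration pattern couples the Voronoi diagram ``G`` of a set of
populations on the sphere with three families of numbers indexed by its
edges and faces:

* ``theta``  — the inner intersection angle of the two Delaunay circumcircles
  flanking each edge, in (0, pi);
* ``weights`` — an exogenous gene-flow measure per edge (for instance a
  pairwise F_ST), required to lie strictly in (0, 1);
* ``loads``  — the total load of each population: the sum of the weights on
  the edges bounding its cell.

The geometric angles are constrained by Rivin's circle-pattern theorem: the
angles incident to each population sum to exactly 2*pi (the face condition),
while every closed non-facial cycle of the Delaunay graph must carry an
angle sum strictly above 2*pi.  The weights and angles are kept independent
here: whether a gene-flow measure should be tied to the geometry is an open
modelling question, so only the convenience transform ``theta = 1 - x`` is
offered for callers who want the unit-interval convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .combmaps import CombinatorialMap
from .geo import DelaunayComplex, GeoPopulation, delaunay_triangulate, voronoi_dual

TWO_PI = 2.0 * math.pi


class PatternError(ValueError):
    pass


WeightTable = dict  # frozenset({name_a, name_b}) -> weight


def _normalize_weight_table(weight_table) -> dict[frozenset, float]:
    out = {}
    for key, w in dict(weight_table).items():
        pair = frozenset(key)
        if len(pair) != 2:
            raise PatternError(f"weight key {key!r} is not a pair")
        out[pair] = float(w)
    return out


@dataclass
class MigrationPattern:
    """An assembled migration pattern for a concrete set of populations."""

    complex: DelaunayComplex
    graph: CombinatorialMap          # the Voronoi diagram; faces <-> populations
    theta: dict[int, float]          # edge label -> inner angle (radians)
    weights: dict[int, float]        # edge label -> gene-flow weight in (0,1)
    loads: dict[str, float]          # population -> sum of incident weights
    edge_pops: dict[int, tuple[str, str]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return self.complex.names

    def incident_labels(self, name: str) -> list[int]:
        return self.complex.incident_labels(name)


@dataclass
class ValidationReport:
    """Aggregate of all pattern checks; ``overall`` passes iff every list is
    empty and every deviation is below its tolerance."""

    face_sum_deviations: dict[str, float]
    cycle_violations: list[tuple[tuple[str, ...], float]]
    weight_violations: list[int]
    load_mismatches: dict[str, float]
    overall: bool


def assemble_pattern(
    populations: list[GeoPopulation],
    weight_table,
) -> MigrationPattern:
    """Triangulate the populations and attach weights, angles and loads.

    The weight table must cover exactly the Delaunay edge set; weights must
    lie strictly in (0, 1).  Loads are computed as the per-population sums of
    incident weights — incidence always comes from the computed
    triangulation.
    """
    table = _normalize_weight_table(weight_table)
    complex_ = delaunay_triangulate(populations)
    pair_labels = complex_.pair_labels()
    missing = sorted(tuple(sorted(p)) for p in set(pair_labels) - set(table))
    extra = sorted(tuple(sorted(p)) for p in set(table) - set(pair_labels))
    if missing or extra:
        raise PatternError(
            f"weight table does not match the Delaunay edge set; "
            f"missing pairs: {missing}; non-Delaunay pairs: {extra}"
        )
    bad = {pair_labels[p]: w for p, w in table.items() if not 0.0 < w < 1.0}
    if bad:
        raise PatternError(f"weights outside (0,1) on edges {sorted(bad)}")
    weights = {pair_labels[p]: w for p, w in table.items()}
    loads = {
        p.name: sum(weights[lab] for lab in complex_.incident_labels(p.name))
        for p in populations
    }
    return MigrationPattern(
        complex=complex_,
        graph=voronoi_dual(complex_),
        theta=dict(complex_.angles),
        weights=weights,
        loads=loads,
        edge_pops=complex_.label_pairs(),
    )


def check_rivin_faces(pattern: MigrationPattern, tol: float = 1e-6) -> dict[str, float]:
    """Deviation |sum of incident theta - 2*pi| for each population."""
    return {
        name: abs(sum(pattern.theta[lab] for lab in pattern.incident_labels(name)) - TWO_PI)
        for name in pattern.populations
    }


def check_rivin_cycles(
    pattern: MigrationPattern,
    max_cycle_len: int = 8,
    tol: float = 1e-9,
) -> list[tuple[tuple[int, ...], float]]:
    """Non-facial closed paths of the Voronoi diagram with angle sum <= 2*pi.

    The strict cycle condition of the circle-pattern theorem: every simple
    cycle of the Voronoi graph that does not bound a cell must carry a total
    angle (summed over the Delaunay edges it crosses) strictly above 2*pi.
    A cycle bounding the union of k >= 2 cells sums to ``2*pi*k`` minus
    twice the interior angles, so with all angles below pi the condition
    holds automatically for geometric patterns; it bites when validating a
    proposed angle assignment.  Cycles are enumerated up to
    ``max_cycle_len`` (capped at the edge count) and reported as tuples of
    the crossed edge labels.
    """
    if max_cycle_len < 3:
        raise PatternError("max_cycle_len must be at least 3")
    g = pattern.graph
    n_edges = g.n_edges
    if max_cycle_len > n_edges:
        max_cycle_len = n_edges
    verts = g.vertices()
    vid = {d: i for i, v in enumerate(verts) for d in v}
    gx = nx.Graph()
    gx.add_nodes_from(range(len(verts)))
    parallel: list[tuple[int, int]] = []
    for d, t in g.edges():
        a, b = vid[d], vid[t]
        if gx.has_edge(a, b):
            parallel.append((g.edge_labels[gx.edges[a, b]["dart"]], g.edge_labels[d]))
        else:
            gx.add_edge(a, b, dart=d)
    facial = {frozenset(labs) for labs in g.face_label_sets().values()}
    violations = []
    # a pair of parallel edges is a closed path of length 2
    for pair in parallel:
        if frozenset(pair) in facial:
            continue
        total = pattern.theta[pair[0]] + pattern.theta[pair[1]]
        if total <= TWO_PI + tol:
            violations.append((tuple(pair), total))
    for cycle in nx.simple_cycles(gx, length_bound=max_cycle_len):
        labels = tuple(
            g.edge_labels[gx.edges[a, b]["dart"]]
            for a, b in zip(cycle, cycle[1:] + cycle[:1])
        )
        if frozenset(labels) in facial:
            continue
        total = sum(pattern.theta[lab] for lab in labels)
        if total <= TWO_PI + tol:
            violations.append((labels, total))
    return violations


def validate_pattern(
    pattern: MigrationPattern,
    tol: float = 1e-5,
    max_cycle_len: int = 8,
) -> ValidationReport:
    """Run all pattern checks: weight domain, load consistency, Rivin face
    sums and non-facial cycle sums."""
    face_dev = check_rivin_faces(pattern, tol)
    cycles = check_rivin_cycles(pattern, max_cycle_len)
    weight_bad = sorted(
        lab for lab, w in pattern.weights.items() if not 0.0 < w < 1.0
    )
    load_mis = {}
    for name in pattern.populations:
        expected = sum(pattern.weights[lab] for lab in pattern.incident_labels(name))
        d = abs(pattern.loads.get(name, float("nan")) - expected)
        if not d <= tol:
            load_mis[name] = d
    ok = (
        not cycles
        and not weight_bad
        and not load_mis
        and all(d <= tol for d in face_dev.values())
    )
    return ValidationReport(face_dev, cycles, weight_bad, load_mis, ok)


def angles_from_unit_weights(x: dict[int, float]) -> dict[int, float]:
    """The unit-interval convention ``theta = 1 - x`` for edge variables.

    A convenience transform between the load-system variables in (0,1) and
    angle-like quantities; the geometric angles of an assembled pattern are
    *not* coupled to the gene-flow weights.
    """
    return {lab: 1.0 - v for lab, v in x.items()}
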