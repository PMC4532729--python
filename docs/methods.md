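# Methods

## Scope and model

The package represents migration among `n` point populations on the unit
sphere at three coupled levels: (i) geometric — the spherical Voronoi
tessellation and its Delaunay dual, with circle-intersection angles per
edge; (ii) combinatorial — the finite space of sphere-embedded migration
graphs reachable from one another by contraction, expansion and Whitehead
moves; (iii) linear — the polytopes of admissible edge weightings under
fixed per-population total loads, glued into a complex on which temporal
dynamics are paths. Gene-flow weights are exogenous inputs (any symmetric
measure scaled into (0,1), such as a pairwise F_ST); the package neither
estimates them from genotype data nor assumes any functional relation
between the weights and the geometric angles.

## Spherical geometry

Populations are given in decimal degrees and mapped to unit vectors;
the Earth is treated as the unit sphere since every quantity used
(angles, angular distances) is scale invariant. Latitudes at the poles are
rejected as degenerate, and longitudes in [-180, 360] are normalized to
(-180, 180].

The Delaunay triangulation is computed by brute force: a triple of points
is accepted iff all remaining points lie strictly on one side of its plane
— the empty circumscribed-cap test — examining all C(n,3) candidates. This
O(n^4) procedure was chosen over hull-based shortcuts deliberately: it is
transparent, it is exactly the defining property being tested elsewhere,
and it remains robust in the clustered regime (all points inside a small
cap) where the cells on the far side of the sphere become enormous. It is
entirely adequate for the intended scales (n up to a few tens; the
acceptance run uses n = 8 and the property tests n ≤ 14). A convex-hull
facet computation (scipy) serves as an independent oracle in the tests,
never as the implementation.

Numerical choices: sidedness uses a plane-distance tolerance of 1e-12, and
a remaining point within tolerance of an otherwise-empty candidate plane
raises a degeneracy error naming the offending points rather than silently
picking one of the two triangulations. The circumcenter is the unit normal
of the triangle's plane signed toward the empty cap (so no assumption
`r < π/2` is needed); the inner angle of the two circumcircles flanking an
edge comes from the spherical law of cosines, with the arccos argument
clamped only within 1e-9 (beyond that, a conditioning error is raised).
Inner angles of distinct intersecting circles lie strictly in (0, π) and
this is enforced even though the existence theorem is usually stated with
only a lower bound; all published values and all computed configurations
respect it.

The embedded Delaunay map is built combinatorially, not from arc azimuths:
each triangle is oriented by its empty-cap pole (these orientations are
globally consistent, being outward normals of the hull), and each
population's rotation is read off its oriented triangle fan. This matters
in the clustered regime, where the geodesic realization of "far-side"
edges wraps around the sphere and tangent-plane azimuth sorting produces
the wrong cyclic order. The Voronoi map is the dual of the Delaunay map;
populations appear as its face names and the shared integer edge labels
are assigned deterministically by lexicographic order of the sorted
population-name pairs.

## Circle-pattern validation

Two conditions characterize which angle assignments are realizable as
Delaunay patterns: around each population the incident angles sum to
exactly 2π, and every closed non-facial path of the Voronoi graph carries
a sum strictly above 2π. The first is checked per population with
tolerance 1e-6 on computed geometry (observed deviations are below 1e-9)
and 1e-5 when validating published, rounded values. The second is checked
by enumerating simple cycles of the Voronoi graph up to a configurable
length (default 8; exhaustive for the 18-edge Sumba graph, exponential in
general), summing θ over the crossed edges, and excluding cell boundaries;
pairs of parallel Voronoi edges are handled as closed paths of length two.
Note the quantification is over the *dual* (Voronoi) cycles: a cycle
enclosing k ≥ 2 cells sums to 2πk minus twice the enclosed interior
angles, so geometric patterns always satisfy the condition, and the check
has teeth only for externally proposed angle assignments.

## Combinatorial maps

Embedded multigraphs are combinatorial maps (rotation systems) over darts;
vertices, edges and faces are orbits of the rotation, the twin involution,
and their composite. Sphericity (V − E + F = 2), connectivity, at least
two vertices, and the absence of self-loops (a population cannot be fully
enclosed by one neighbour) are enforced at construction, which means every
move is re-validated automatically. Equivalence of embedded graphs is map
isomorphism allowing orientation reversal, decided by a canonical code:
the minimum over all starting darts and both orientations of a
breadth-first relabeling of the (rotation, twin) images — O(darts²) per
code, acceptable at the target scales (darts ≤ 36).

Contraction fuses the endpoint rotations of an edge preserving cyclic
order; it is refused when it would fuse the last two vertices or turn a
parallel edge into a self-loop. Expansion splits a vertex of degree ≥ 4
along two contiguous arcs of at least two darts each, and is the exact
inverse of contraction (the tests exercise the round trip). The Whitehead
move on an edge of a cubic map is contraction followed by the unique other
2+2 expansion of the resulting degree-4 vertex; it is an involution via
the new edge and inherits the pivot edge's label.

The space of migration graphs with n faces is enumerated layer by layer:
the cubic stratum as the Whitehead closure of the prism generator (the
two-vertex theta graph for n = 3), then each deeper layer as the set of
admissible contractions of the layer above, deduplicating by canonical
code. Depth is (3n − 6) − E, so the deepest layer sits at depth 2n − 6,
holding only the two-vertex map C_n. (A depth of 2n − 5 is sometimes
quoted for this construction; counting edges from 3n − 6 down to n gives
2n − 6, which matches the four-population picture — two contractions from
a cubic graph to C_4 — and is what the implementation uses.) Enumeration
is supported for 3 ≤ n ≤ 8; beyond that the space explodes and no attempt
is made. Abstract maps are not geometrically realized: not every
sphere-embeddable graph arises from an actual point configuration.

## Polytopes and the complex

The load system relaxes the open conditions 0 < x < 1 to the closed box
[0,1]; the open pattern space is recovered as the relative interior, and
`interior_point` answers the strict question by maximizing a uniform slack
on all bounds within the equality subspace (an LP; a max-slack of zero
means the solution set touches the boundary everywhere). Feasibility and
interior points use scipy's HiGHS solver with tolerance 1e-9. Vertex
enumeration is brute force over bound pinnings: for each subset of
variables large enough to make the combined system uniquely solvable, pin
them to bounds, solve, keep feasible solutions, deduplicate within 1e-9;
it is capped at 24 variables and about 10^6 pinnings, and the tests check
it against an independent exact rational re-solve (sympy) on systems of up
to 8 variables. The angle system adds inequality rows for the non-facial
cycles truncated at a configurable length (default 8) — an outer
approximation of the full pattern polytope, since the complete cycle set
is exponential; the truncation depth is exposed in the API.

The complex over the cubic stratum is built by breadth-first closure under
Whitehead moves from a labeled seed, with labels inherited through each
move (the pivot keeps its label on the re-expanded edge). Nodes are
keyed by the label-aware canonical code, so relabelings produced by
different move sequences appear as distinct nodes with permuted
coordinates — the same migration pattern can legitimately have several
coordinate charts, and the quotient by sphere symmetries is out of scope.
Each move records the pivot label and the labeled code of the common
contracted graph; the shared facet is x_pivot = 0 in both neighbouring
polytopes, and the tests verify the witnesses transfer both ways. Complex
construction is capped at 6 faces.

## Dynamics

A split places the daughters symmetrically at ±ε/2 along the bearing
great circle, rather than leaving one daughter at the ancestor: the
spherical midpoint of the daughters is then exactly the ancestor, making
merge a true inverse of split (the round trip restores the original
triangulation bit-for-bit at the tolerances involved). ε must be smaller
than the distance to the nearest other population; a generic small split
adds one vertex, three edges and two triangles (forced by Euler's
relation), and any change to edges not touching the split population is
reported as a non-local warning rather than an error. How the weights and
loads transform across a split is not determined by the model; the package
reports the structural diff and leaves weight inheritance to the caller.

Facet crossings along a history are detected on the piecewise-linear
interpolation between sampled weight vectors — the model treats paths as
continuous but prescribes no parametric form, so linear interpolation is
the minimal assumption. States within one graph segment must satisfy the
segment's load equalities within 1e-6 (total flow through each population
is constant while the graph is fixed); time is an arbitrary strictly
increasing real sequence with no calendar semantics.

## Synthetic data

The generator emulates the two regimes the geometry must handle: isotropic
points on the whole sphere (normalized Gaussian triples) and points
area-uniform inside a spherical cap, defaulting to a 2° cap in eastern
Indonesia to mirror an archipelago-scale study system (the bundled Sumba
populations span about 1.7°). All draws flow through one seeded generator.
What synthetic tests do show: the triangulation invariants, the 2π face
condition, Euler bookkeeping and polytope identities hold across both
regimes. What they do not show: anything about real gene-flow estimation
— synthetic weights are drawn uniformly in (0,1) with no spatial
covariance, no noise model on coordinates, and no missing data, so passing
tests certify the mathematics, not the inference pipeline that would
produce F_ST values in practice.

## Problem sizes

The shipped checks run the worked example at n = 8 (56 candidate triples),
property tests at n ≤ 14 points and n ≤ 6 faces for map spaces (the
6-face space has 209 maps), vertex-enumeration cross-checks at ≤ 8
variables, and the polytope complex at 4 faces. These sizes were chosen as
the smallest at which every claimed structure (layers, shared facets,
expansion-insufficiency at n = 5) is actually exhibited.

## Known limitations

- The Earth is a unit sphere: no ellipsoid, no projections, no landmass
  constraints; geographic barriers enter only through the user's weights.
- Weights are undirected; directed gene flow is not modelled.
- Loads are fixed within a graph segment; time-varying loads (a complex
  with moving walls) are not implemented.
- No inference: reconstructing a history from genetic data is the
  motivating downstream problem, not solved here.
- The published Sumba table carries one internal inconsistency in its
  per-population edge lists; the package always derives incidence from the
  computed triangulation, which is the self-consistent reading (the angle
  table itself satisfies the 2π sums only under that incidence).
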