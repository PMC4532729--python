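# migpatterns

Geometric and combinatorial representation of migration among structured
populations ("metapopulations") on the sphere, for population geneticists
and mathematical biologists who want to treat migration histories as paths
on a concrete mathematical space rather than as free-form parameter sets.

## The model

A set of `n` populations, each reduced to a geographic point on the unit
sphere, induces a Voronoi tessellation under the great-circle metric; its
dual is the spherical Delaunay triangulation, whose edges are the possible
migration channels between neighbouring populations. The **migration
pattern** of the system is the 4-tuple

    M = (G, Θ, W, T)

where `G` is the embedded Voronoi graph, `Θ = {θ_e}` assigns each edge the
inner intersection angle of the two Delaunay circumcircles flanking it,
`W = {w_e}` is an exogenous gene-flow weight per edge with `0 < w_e < 1`
(here a pairwise F_ST), and `T_i = Σ_{e ∋ i} w_e` is each population's
**total load**. The angles are constrained by Rivin's circle-pattern
theorem: around every population `Σ θ_e = 2π`, and every closed non-facial
path of the Voronoi graph carries `Σ θ_e > 2π`.

Dropping the geometry, the possible migration graphs for `n` populations
form a finite space of sphere-embedded combinatorial maps, stratified by
**depth**: the cubic (degree-3) maps at depth 0 are all connected by
Whitehead moves, each contraction move descends one layer, and the deepest
layer holds the single two-vertex map `C_n` of populations strung along a
great circle. Attaching to each labeled cubic graph the **load polytope**

    L°(G, T):   0 ≤ x_e ≤ 1,   Σ_{e ∋ i} x_e = T_i,

and gluing polytopes of Whitehead-adjacent graphs along the shared facet
`x_e = 0` (the contracted edge) yields a finite polytope complex; the
history of a metapopulation with fixed loads is a path on this complex, and
graph transitions happen exactly when the path reaches a facet. Population
splits and mergers move the system between complexes of adjacent dimension.

## Worked example: eight populations on Sumba

The package ships the coordinates of eight populations on the eastern
Indonesian island of Sumba and mitochondrial F_ST weights for the 18 edges
of their Delaunay triangulation:

```python
from migpatterns import (assemble_pattern, check_rivin_faces,
                         load_fixture, validate_pattern)

fx = load_fixture()
pat = assemble_pattern(fx.populations, fx.weights)
for n in pat.populations:
    print(f"{n:10s} degree {len(pat.incident_labels(n))}  T = {pat.loads[n]:.5f}")
print("max |sum(theta) - 2pi| =", f"{max(check_rivin_faces(pat).values()):.2e}")
print("overall:", validate_pattern(pat).overall)
```

prints

```
Kodi       degree 5  T = 0.09325
Lamboya    degree 4  T = 0.11078
Loli       degree 5  T = 0.23837
Wanokaka   degree 4  T = 0.09463
Mamboro    degree 4  T = 0.16669
Anakalang  degree 5  T = 0.14461
Wunga      degree 4  T = 0.16380
Rindi      degree 5  T = 0.05171
max |sum(theta) - 2pi| = 2.92e-10
overall: True
```

The triangulation (56 candidate triples, 12 triangles, 18 edges) is
computed from the coordinates alone by the brute-force empty-cap test; each
`T` is the sum of the F_ST weights on that population's computed Delaunay
edges, and the per-population angle sums confirm the Rivin face condition
to numerical precision. The same pipeline is available from the shell:

```sh
mig build-pattern pops.csv weights.csv -o pattern.json
mig validate pattern.json          # exit 0 iff the pattern is consistent
mig enumerate --n 4                # the 4 migration graphs on 4 populations
mig complex --n 4                  # the polytope complex over the cubic stratum
mig split pops.csv --population Anakalang --epsilon 1e-4
mig random --n 10 --mode cap --seed 1
```

## Layout

- `migpatterns.geo` — spherical geometry: triangulation, circumcircles, angles, Voronoi dual
- `migpatterns.combmaps` — combinatorial maps, moves, canonical codes, enumeration by depth
- `migpatterns.pattern` — pattern assembly and the circle-pattern checks
- `migpatterns.polytopes` — load/angle systems, feasibility, vertices, the polytope complex
- `migpatterns.dynamics` — splits, mergers, transition classification, facet crossings
- `migpatterns.io`, `migpatterns.synth`, `migpatterns.cli` — formats, fixture, generators, CLI

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
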