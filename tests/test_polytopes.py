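"""Load and angle systems, vertex enumeration, and the polytope complex."""

import math

import numpy as np
import pytest

from migpatterns import (
    build_angle_system,
    build_complex,
    build_load_system,
    contraction_facet,
    enumerate_vertices,
    interior_point,
    is_feasible,
    make_CLn,
    make_Cn,
    make_tetrahedron,
)
from migpatterns.polytopes import HPolytope, PolytopeError, ensure_edge_labels


@pytest.fixture()
def c4_system():
    return build_load_system(make_Cn(4), 1.0)


class TestLoadSystem:
    def test_each_variable_in_exactly_two_equalities(self, c4_system, sumba_pattern):
        sys_sumba = build_load_system(sumba_pattern.graph, sumba_pattern.loads)
        for P in (c4_system, sys_sumba):
            assert np.all(P.A_eq.sum(axis=0) == 2.0)
            assert set(np.unique(P.A_eq)) <= {0.0, 1.0}

    def test_c4_solution_family_is_one_dimensional(self, c4_system):
        rank = np.linalg.matrix_rank(c4_system.A_eq)
        assert c4_system.n_vars - rank == 1
        # alternating structure: (t, 1-t, t, 1-t)
        ok, w = is_feasible(c4_system)
        assert ok
        assert w[0] + w[1] == pytest.approx(1.0, abs=1e-9)
        assert w[0] == pytest.approx(w[2], abs=1e-9)

    def test_sumba_weight_vector_is_a_witness(self, sumba_pattern):
        P = build_load_system(sumba_pattern.graph, sumba_pattern.loads)
        x = np.array([sumba_pattern.weights[lab] for lab in P.variables])
        assert np.max(np.abs(P.A_eq @ x - P.b_eq)) < 1e-6
        assert is_feasible(P)[0]

    def test_overloaded_face_flagged_and_infeasible(self):
        c4 = make_Cn(4)
        with pytest.warns(UserWarning, match="trivially infeasible"):
            P = build_load_system(c4, {0: 1.0, 1: 1.0, 2: 1.0, 3: 2.5})
        assert not is_feasible(P)[0]

    def test_nonpositive_load_rejected(self):
        with pytest.raises(PolytopeError, match="positive"):
            build_load_system(make_Cn(4), 0.0)

    def test_load_identity_on_any_feasible_point(self, sumba_pattern):
        """Summing all equalities counts each edge twice, so any feasible
        point satisfies sum(T) = 2 sum(x)."""
        P = build_load_system(sumba_pattern.graph, sumba_pattern.loads)
        _, x = is_feasible(P)
        assert P.b_eq.sum() == pytest.approx(2.0 * x.sum(), abs=1e-8)

    def test_affine_dimension_matches_incidence_rank(self):
        for cm in (make_tetrahedron(), make_CLn(5), make_CLn(6)):
            P = build_load_system(cm, 1.0)
            dim = P.n_vars - np.linalg.matrix_rank(P.A_eq)
            assert dim == (3 * cm.n_faces - 6) - np.linalg.matrix_rank(P.A_eq)


class TestAngleSystem:
    def test_sumba_angles_satisfy_system(self, sumba_pattern):
        P = build_angle_system(sumba_pattern.graph, max_cycle_len=8)
        x = np.array([sumba_pattern.theta[lab] for lab in P.variables])
        assert np.max(np.abs(P.A_eq @ x - P.b_eq)) < 1e-5
        assert np.max(P.A_ub @ x - P.b_ub) < -1e-6  # strictly inside all cycles

    def test_tetrahedron_symmetric_point(self):
        P = build_angle_system(make_tetrahedron())
        x = np.full(P.n_vars, 2.0 * math.pi / 3.0)
        assert np.allclose(P.A_eq @ x, P.b_eq)

    def test_total_angle_identity(self):
        """Summing all face equalities counts each edge twice, so the total
        angle over edges is pi times the face count."""
        for cm in (make_tetrahedron(), make_CLn(5)):
            P = build_angle_system(cm)
            ok, x = is_feasible(P)
            assert ok
            assert x.sum() == pytest.approx(math.pi * cm.n_faces, abs=1e-6)


class TestFeasibilityAndInterior:
    def test_c4_interior_is_the_symmetric_point(self, c4_system):
        assert np.allclose(interior_point(c4_system), 0.5, atol=1e-8)

    def test_unit_square_center(self):
        P = HPolytope(
            variables=[1, 2],
            A_eq=np.zeros((0, 2)),
            b_eq=np.zeros(0),
            bounds=[(0.0, 1.0), (0.0, 1.0)],
        )
        assert np.allclose(interior_point(P), [0.5, 0.5])

    def test_boundary_only_solution_has_no_interior(self):
        # x1 = 0 forced: x1 + x2 = 1 with x2 pinned to [1, 1]
        P = HPolytope(
            variables=[1, 2],
            A_eq=np.array([[1.0, 1.0]]),
            b_eq=np.array([1.0]),
            bounds=[(0.0, 1.0), (1.0, 1.0)],
        )
        assert is_feasible(P)[0]
        assert interior_point(P) is None

    def test_infeasible_system(self):
        P = HPolytope(
            variables=[1],
            A_eq=np.array([[1.0]]),
            b_eq=np.array([2.0]),
            bounds=[(0.0, 1.0)],
        )
        assert not is_feasible(P)[0]


from tests_rational import rational_vertices as _rational_vertices  # noqa: E402


class TestVertexEnumeration:
    def test_c4_vertices_are_the_two_alternating_points(self, c4_system):
        vs = {tuple(np.round(v, 9)) for v in enumerate_vertices(c4_system)}
        assert vs == {(0.0, 1.0, 0.0, 1.0), (1.0, 0.0, 1.0, 0.0)}

    def test_unit_cube_has_eight_vertices(self):
        P = HPolytope(
            variables=[1, 2, 3],
            A_eq=np.zeros((0, 3)),
            b_eq=np.zeros(0),
            bounds=[(0.0, 1.0)] * 3,
        )
        vs = enumerate_vertices(P)
        assert len(vs) == 8

    def test_vertices_satisfy_equalities(self):
        P = build_load_system(make_tetrahedron(), 1.0)
        for v in enumerate_vertices(P):
            assert np.max(np.abs(P.A_eq @ v - P.b_eq)) < 1e-9

    @pytest.mark.parametrize(
        "system",
        [
            build_load_system(make_Cn(4), 1.0),
            build_load_system(make_tetrahedron(), 1.0),
            build_load_system(make_Cn(4), {0: 0.5, 1: 1.0, 2: 1.5, 3: 1.0}),
        ],
        ids=["C4-uniform", "K4-uniform", "C4-mixed"],
    )
    def test_agrees_with_exact_rational_resolve(self, system):
        approx = {tuple(np.round(v, 9)) for v in enumerate_vertices(system)}
        exact = {tuple(np.round(v, 9)) for v in _rational_vertices(system)}
        assert approx == exact


class TestContractionFacet:
    def test_facet_equals_contracted_system(self):
        """Solutions on x_e = 0 of the K4 system coincide with the load
        system of the contracted 3-vertex map, lifted by the zero."""
        from migpatterns import contract_edge
        from migpatterns.polytopes import ensure_edge_labels

        k4 = ensure_edge_labels(make_tetrahedron())
        P = build_load_system(k4, 1.0)
        d, t = k4.edges()[0]
        lab = k4.edge_labels[d]
        F = contraction_facet(P, lab)
        contracted = contract_edge(k4, d)
        Pc = build_load_system(contracted, 1.0)
        # facet witnesses drop to the contracted system and vice versa
        for v in enumerate_vertices(F):
            drop = {l: x for l, x in zip(P.variables, v) if l != lab}
            xc = np.array([drop[l] for l in Pc.variables])
            assert np.max(np.abs(Pc.A_eq @ xc - Pc.b_eq)) < 1e-9
        for v in enumerate_vertices(Pc):
            lift = dict(zip(Pc.variables, v))
            lift[lab] = 0.0
            xv = np.array([lift[l] for l in P.variables])
            assert F.contains(xv, tol=1e-9)

    def test_zeroing_a_full_face_boundary_is_infeasible(self):
        k4 = ensure_edge_labels(make_tetrahedron())
        P = build_load_system(k4, 1.0)
        face_labels = next(iter(k4.face_label_sets().values()))
        for lab in face_labels:
            P = contraction_facet(P, lab)
        assert not is_feasible(P)[0]

    def test_facet_fixing_commutes(self, c4_system):
        a = contraction_facet(contraction_facet(c4_system, 1), 2)
        b = contraction_facet(contraction_facet(c4_system, 2), 1)
        assert a.bounds == b.bounds


class TestComplex:
    def test_four_face_complex_closes_finitely(self):
        kx = build_complex(ensure_edge_labels(make_tetrahedron()), T=1.0, n_cap=4)
        assert kx.n_nodes > 0 and len(kx.moves) > 0
        for node in kx.nodes.values():
            assert node.map.is_cubic()
            assert node.map.n_faces == 4

    def test_every_move_shares_its_pivot_facet(self):
        kx = build_complex(ensure_edge_labels(make_tetrahedron()), T=1.0, n_cap=4)
        for mv in kx.moves:
            Pa = kx.nodes[mv.node_a].polytope
            Pb = kx.nodes[mv.node_b].polytope
            ok, w = is_feasible(contraction_facet(Pa, mv.pivot))
            assert ok
            assert Pa.contains(w) and Pb.contains(w)

    def test_non_cubic_seed_rejected(self):
        from migpatterns import contract_edge

        with pytest.raises(PolytopeError, match="cubic"):
            build_complex(contract_edge(make_tetrahedron(), 0))

    def test_relabeled_seed_gives_permuted_polytopes(self):
        seed = ensure_edge_labels(make_tetrahedron())
        perm = {1: 2, 2: 3, 3: 4, 4: 5, 5: 6, 6: 1}
        relabeled = seed.copy()
        relabeled.edge_labels = {d: perm[l] for d, l in seed.edge_labels.items()}
        ka = build_complex(seed, T=1.0, n_cap=4)
        kb = build_complex(relabeled, T=1.0, n_cap=4)
        assert ka.n_nodes == kb.n_nodes
        assert len(ka.moves) == len(kb.moves)
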