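"""Exact rational vertex enumeration used as an independent oracle."""

import itertools

import sympy


def rational_vertices(P):
    """Enumerate the vertices of an equality+bounds polytope exactly.

    Pins every size-d subset of variables to rational bound values, solves
    the combined system with sympy over the rationals, and keeps the unique
    feasible solutions.  Independent of the floating-point path it checks.
    """
    m = P.n_vars
    A = sympy.Matrix([[sympy.Rational(int(v)) for v in row] for row in P.A_eq])
    b = sympy.Matrix([sympy.nsimplify(v, rational=True) for v in P.b_eq])
    d = m - A.rank() if A.rows else m
    xs = sympy.symbols(f"x0:{m}")
    out = set()
    for subset in itertools.combinations(range(m), d):
        for pick in itertools.product((0, 1), repeat=d):
            rows = [list(A[i, :]) + [b[i]] for i in range(A.rows)]
            for j, s in zip(subset, pick):
                row = [0] * m + [sympy.nsimplify(P.bounds[j][s], rational=True)]
                row[j] = 1
                rows.append(row)
            M = sympy.Matrix(rows)
            sol = sympy.linsolve((M[:, :m], M[:, m]), *xs)
            if len(sol) != 1:
                continue
            (vec,) = sol
            if any(v.free_symbols for v in vec):
                continue
            if all(
                sympy.nsimplify(lo, rational=True)
                <= v
                <= sympy.nsimplify(hi, rational=True)
                for v, (lo, hi) in zip(vec, P.bounds)
            ):
                out.add(tuple(vec))
    return {tuple(float(v) for v in vec) for vec in out}
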