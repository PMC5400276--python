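"""Deficiency subspace, equilibrium manifold, the G matrix and the search."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from crnt import fixtures as fx
from crnt import kinetics
from crnt.deficiency import (
    G_matrix,
    ManifoldEquations,
    check_conditions_def,
    deficiency_basis,
    dimensional_class,
    search_def,
)
from crnt.continuation import reduced_jacobian
from crnt.network import conservation_basis, parse_network, structural_summary
from crnt.optimize import SearchOptions

MOTIF_K = {
    "k51": 7.5, "k15": 1.5, "k16": 2.5, "k82": 8.5, "k28": 4.5,
    "k27": 3.5, "k93": 9.5, "k39": 6.5, "k34": 5.5,
}


def span_equal(A, B):
    r = np.linalg.matrix_rank
    return r(A) == r(B) == r(np.vstack([A, B]))


class TestBasis:
    def test_motif_basis_span(self, motif):
        om = deficiency_basis(motif)
        published = np.array(
            [[0, 0, 0, 0, 1, -1, -1, 1, 0], [0, 0, 0, -1, -1, 1, 0, 0, 1]]
        )
        assert om.shape == (9, 2)
        assert span_equal(om.T, published)

    def test_basis_vectors_annihilated(self, motif):
        from crnt.network import linkage_classes

        om = deficiency_basis(motif)
        _, Lam = linkage_classes(motif)
        assert np.all(motif.Y @ om == 0)
        assert np.all(Lam.T @ om == 0)

    def test_deficiency_zero_network_empty_basis(self):
        net = parse_network("A <-> B")
        assert deficiency_basis(net).shape[1] == 0

    def test_dimension_equals_deficiency_on_fixtures(self):
        for name in ["motif_closed", "ternary_true", "ternary_excess", "stat_early_closed"]:
            net = fx.fixture(name)
            s = structural_summary(net)
            assert deficiency_basis(net).shape[1] == s.delta

    def test_requires_uniterminal(self):
        net = parse_network("B -> A\nB -> C")
        with pytest.raises(ValueError):
            deficiency_basis(net)

    def test_classification(self):
        assert dimensional_class(2, 2) == "proper"
        assert dimensional_class(1, 2) == "over"
        assert dimensional_class(3, 2) == "under"


def printed_manifold_residuals(c, a1, a2, k):
    """The six published equilibrium-manifold equations of the motif,
    hand-coded independently of the package's assembly."""
    c1, c2, c3, c4, c5, c6, c7 = c
    return np.array([
        c1 * c2 - k["k15"] / k["k51"] * c5 + a1 / k["k51"] - a2 / k["k51"],
        c5 + a1 / k["k16"] - a2 / k["k16"],
        c6 + a1 / k["k27"],
        c3 * c4 - k["k28"] / k["k82"] * c6 + a1 / k["k82"],
        c7 + a2 / k["k34"],
        c1 * c4 - k["k39"] / k["k93"] * c7 + a2 / k["k93"],
    ])


class TestManifold:
    def test_six_equations(self, motif):
        man = ManifoldEquations(motif)
        assert man.n_equations == 6

    def test_equivalence_with_printed_equations(self, motif):
        """Points solving the package's manifold equations satisfy the
        published six equations and vice versa."""
        man = ManifoldEquations(motif)
        kv = kinetics.rate_constants_vector(motif, MOTIF_K)
        rng = np.random.default_rng(3)
        checked = 0
        from crnt.deficiency import _InnerSolver, _choose_fixed_concentrations

        solver = _InnerSolver(motif, man, _choose_fixed_concentrations(motif, man, 1), 0)
        while checked < 5:
            a2 = -(10.0 ** rng.uniform(-1, 1))
            a1 = a2 - 10.0 ** rng.uniform(-1, 1)
            cf = [10.0 ** rng.uniform(-1, 1)]
            solver.warm = None
            sol = solver.solve(kv, np.array([a1, a2]), cf)
            if sol is None:
                continue
            c, alpha = sol
            assert np.allclose(
                printed_manifold_residuals(c, alpha[0], alpha[1], MOTIF_K), 0, atol=1e-6
            )
            checked += 1

    def test_printed_solution_satisfies_package_equations(self, motif):
        # explicit solution of the published equations
        rng = np.random.default_rng(4)
        man = ManifoldEquations(motif)
        k = MOTIF_K
        for _ in range(5):
            a2 = -(10.0 ** rng.uniform(-1, 1))
            a1 = a2 - 10.0 ** rng.uniform(-1, 1)
            c1 = 10.0 ** rng.uniform(-1, 1)
            c5 = (a2 - a1) / k["k16"]
            c6 = -a1 / k["k27"]
            c7 = -a2 / k["k34"]
            c2 = (k["k15"] / k["k51"] * c5 - a1 / k["k51"] + a2 / k["k51"]) / c1
            c4 = (k["k39"] / k["k93"] * c7 - a2 / k["k93"]) / c1
            c3 = (k["k28"] / k["k82"] * c6 - a1 / k["k82"]) / c4
            c = np.array([c1, c2, c3, c4, c5, c6, c7])
            if np.any(c <= 0):
                continue
            assert np.linalg.norm(man.residual(c, [a1, a2], MOTIF_K)) < 1e-8 * max(
                1, np.max(np.abs(c)) ** 2
            )

    def test_deficiency_zero_manifold_is_complex_balance(self):
        net = parse_network("A <-> B")
        man = ManifoldEquations(net)
        c = np.array([2.0, 3.0])
        res = man.residual(c, np.zeros(0), {"k1": 1.5, "k2": 1.0})
        A = kinetics.kinetic_matrix(net, {"k1": 1.5, "k2": 1.0})
        assert np.allclose(res, (A @ kinetics.monomials(net, c))[man.kept_rows])

    def test_alpha_from_integrated_equilibrium(self, motif):
        """Integrate the ODEs to steady state; the least-squares deficiency
        parameters then make the manifold equations vanish."""
        man = ManifoldEquations(motif)
        kv = kinetics.rate_constants_vector(motif, MOTIF_K)
        c0 = np.full(motif.N, 0.8)
        sol = solve_ivp(
            lambda t, x: kinetics.rhs(motif, np.maximum(x, 1e-12), kv),
            (0, 5e4), c0, method="LSODA", rtol=1e-12, atol=1e-13,
        )
        c_star = np.maximum(sol.y[:, -1], 1e-12)
        assert np.linalg.norm(kinetics.rhs(motif, c_star, kv)) < 1e-9
        alpha, resid = man.alpha_for_equilibrium(c_star, kv)
        assert resid < 1e-8

    def test_basis_change_invariance(self, motif):
        man = ManifoldEquations(motif)
        T = np.array([[2.0, 1.0], [1.0, 1.0]])  # invertible
        man2 = ManifoldEquations(motif, omega=man.omega @ T)
        rng = np.random.default_rng(0)
        c = 10.0 ** rng.uniform(-1, 1, motif.N)
        alpha = rng.normal(size=2)
        r1 = man.residual(c, alpha, MOTIF_K)
        r2 = man2.residual(c, np.linalg.solve(T, alpha), MOTIF_K)
        assert np.allclose(r1, r2)


class TestGMatrix:
    def test_square_dimensions(self, motif):
        B = conservation_basis(motif).B
        G = G_matrix(motif, np.ones(7), np.array([0.1, -0.2]), MOTIF_K, B)
        assert G.shape == (9, 9)

    def test_first_block_row_pattern(self, motif):
        """Row for the C5 manifold equation matches the published pattern
        (c2, c1, 0, 0, -k15/k51, 0, 0 | 1/k51, -1/k51) up to row scaling."""
        man = ManifoldEquations(motif)
        B = conservation_basis(motif).B
        rng = np.random.default_rng(1)
        c = 10.0 ** rng.uniform(-0.5, 0.5, 7)
        G = G_matrix(motif, c, np.array([0.3, -0.4]), MOTIF_K, B, man)
        i = man.kept_rows.index(4)  # complex C5 (0-based index 4)
        row = G[i]
        published = np.array([
            c[1], c[0], 0, 0, -MOTIF_K["k15"] / MOTIF_K["k51"], 0, 0,
            1 / MOTIF_K["k51"], -1 / MOTIF_K["k51"],
        ])
        scale = row[0] / published[0]
        assert np.allclose(row, scale * published)

    def test_conservation_block(self, motif):
        basis = conservation_basis(motif)
        man = ManifoldEquations(motif)
        G = G_matrix(motif, np.ones(7), np.array([0.1, -0.2]), MOTIF_K, basis.B, man)
        assert np.array_equal(G[6:, :7], basis.B.T)
        assert np.all(G[6:, 7:] == 0)

    def test_det_against_symbolic_oracle(self, motif):
        """Fully symbolic assembly (sympy differentiation of the manifold
        equations) agrees with the analytic numeric G at random points."""
        man = ManifoldEquations(motif)
        basis = conservation_basis(motif)
        c_syms = sp.symbols("c1:8", positive=True)
        a_syms = sp.symbols("a1:3")
        k_syms = {lbl: sp.Symbol(lbl, positive=True) for lbl in motif.labels}
        A = sp.zeros(motif.M, motif.M)
        for j, r in enumerate(motif.reactions):
            A[r.product, r.source] += k_syms[r.label]
            A[r.source, r.source] -= k_syms[r.label]
        psi = sp.Matrix([
            sp.prod([c_syms[i] ** int(motif.Y[i, m]) for i in range(motif.N)])
            for m in range(motif.M)
        ])
        Om = sp.Matrix(man.omega.tolist())
        full = A * psi - Om * sp.Matrix(a_syms)
        H = sp.Matrix([full[i] for i in man.kept_rows])
        G_sym = H.jacobian(sp.Matrix(c_syms)).row_join(H.jacobian(sp.Matrix(a_syms)))
        G_sym = G_sym.col_join(
            sp.Matrix(basis.B.T.tolist()).row_join(sp.zeros(basis.lam, man.delta))
        )
        rng = np.random.default_rng(11)
        for _ in range(50):
            c = 10.0 ** rng.uniform(-1, 1, motif.N)
            alpha = rng.normal(size=2)
            kvals = {lbl: 10.0 ** rng.uniform(-1, 1) for lbl in motif.labels}
            subs = {s: v for s, v in zip(c_syms, c)}
            subs.update({s: v for s, v in zip(a_syms, alpha)})
            subs.update({k_syms[l]: v for l, v in kvals.items()})
            det_sym = float(G_sym.subs(subs).det())
            det_num = float(np.linalg.det(G_matrix(motif, c, alpha, kvals, basis.B, man)))
            assert np.isclose(det_sym, det_num, rtol=1e-8, atol=1e-12)


class TestConditionsAndSearch:
    def test_non_equilibrium_fails_C1(self, motif):
        basis = conservation_basis(motif)
        rep = check_conditions_def(motif, np.ones(7), np.array([1.0, 1.0]), MOTIF_K, basis.B)
        assert not rep.C1 and not rep.satisfied

    def test_motif_certificate_conditions(self, motif, motif_certificate):
        cert = motif_certificate
        assert cert.F_def <= 1e-16
        rep = cert.conditions
        assert rep.C1 and rep.C2 and rep.C3 and rep.satisfied

    def test_certificate_zero_eigenvalue(self, motif, motif_certificate):
        """Independent eigen-oracle: the Jacobian reduced to the compatibility
        class has exactly one near-zero eigenvalue at the saddle-node."""
        cert = motif_certificate
        J = reduced_jacobian(motif, cert.c, cert.k)
        eig = np.sort(np.abs(np.linalg.eigvals(J)))
        assert eig[0] < 1e-8 * np.max(np.abs(J))
        assert eig[1] > 1e4 * max(eig[0], 1e-300)

    def test_summary_text(self, motif_certificate):
        text = motif_certificate.summary()
        assert "Saddle-node certificate" in text and "F_def" in text

    def test_deficiency_zero_weakly_reversible_full_rank(self):
        """Deficiency-Zero consistency: at equilibria of delta=0 weakly
        reversible networks the G matrix keeps full rank (no saddle-node)."""
        net = fx.random_network(1, N=4, R=8, weakly_reversible=True,
                                deficiency_zero=True, moiety_conserved=True)
        basis = conservation_basis(net)
        man = ManifoldEquations(net)
        rng = np.random.default_rng(0)
        kv = 10.0 ** rng.uniform(-1, 1, net.R)
        sol = solve_ivp(
            lambda t, x: kinetics.rhs(net, np.maximum(x, 1e-12), kv),
            (0, 1e5), np.full(net.N, 1.0), method="LSODA", rtol=1e-11, atol=1e-12,
        )
        c_star = np.maximum(sol.y[:, -1], 1e-12)
        alpha, resid = man.alpha_for_equilibrium(c_star, kv)
        assert resid < 1e-7
        G = G_matrix(net, c_star, alpha, kv, basis.B, man)
        assert np.linalg.matrix_rank(G) == G.shape[0]

    def test_search_rejects_non_uniterminal(self):
        net = parse_network("B -> A\nB -> C")
        with pytest.raises(ValueError):
            search_def(net)

    def test_search_rejects_invalid_bounds(self, motif):
        with pytest.raises(ValueError):
            search_def(motif, bounds={"k": (0.0, 10.0)})

    def test_pinned_rate_constant_is_honored(self, motif):
        res = search_def(
            motif,
            options=SearchOptions(seed=1, multistarts=10),
            fixed={"k51": 2.0},
        )
        if res.found:
            assert np.isclose(res.certificate.k["k51"], 2.0)
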