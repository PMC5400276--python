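"""Pseudo-arclength tracing, fold detection, stability and bistability regions."""

import numpy as np
import pytest

from crnt import fixtures as fx
from crnt import kinetics
from crnt.continuation import (
    ContinuationOptions,
    continue_branch,
    detect_bistability,
    find_equilibria,
    quasi_static_sweep,
    reduced_jacobian,
    relax_to_equilibrium,
    trace_curve,
)
from crnt.network import conservation_basis, parse_network


class TestGenericTracer:
    def test_cubic_normal_form_folds(self):
        """x' = p + x - x^3 folds at p = -/+ 2/(3 sqrt 3), x = +/- 1/sqrt 3."""
        F = lambda u, p: np.array([p + u[0] - u[0] ** 3])
        Ju = lambda u, p: np.array([[1 - 3 * u[0] ** 2]])
        Jp = lambda u, p: np.array([1.0])
        u0, p0 = np.array([-2.0]), float(-2.0 + 2.0 ** 3 - 2.0 * 0)  # p = x^3 - x at x=-2
        p0 = (-2.0) ** 3 - (-2.0)
        opts = ContinuationOptions(step=0.05, max_steps=600, p_range=(-10, 10))
        br = trace_curve(F, Ju, Jp, u0, p0, direction=+1, options=opts, positivity=False)
        folds = [br.points[i] for i in br.limit_points]
        assert len(folds) == 2
        fold_ps = sorted(pt.p for pt in folds)
        ref = 2.0 / (3.0 * np.sqrt(3.0))
        assert np.allclose(fold_ps, [-ref, ref], atol=1e-4)
        fold_xs = sorted(abs(pt.u[0]) for pt in folds)
        assert np.allclose(fold_xs, [1 / np.sqrt(3)] * 2, atol=1e-3)

    def test_points_satisfy_equations(self):
        F = lambda u, p: np.array([p + u[0] - u[0] ** 3])
        Ju = lambda u, p: np.array([[1 - 3 * u[0] ** 2]])
        Jp = lambda u, p: np.array([1.0])
        br = trace_curve(F, Ju, Jp, np.array([-2.0]), -6.0, direction=+1,
                         options=ContinuationOptions(max_steps=200, p_range=(-10, 10)),
                         positivity=False)
        for pt in br.points:
            assert abs(F(pt.u, pt.p)[0]) < 1e-8


class TestNetworkContinuation:
    def test_linear_exchange_single_monotone_branch(self):
        # 0 -> A (k_in), A -> 0 (k_out): unique equilibrium c = k_in/k_out
        net = parse_network("kin: 0 -> A\nkout: A -> 0")
        k = {"kin": 2.0, "kout": 1.0}
        br = continue_branch(net, (np.array([2.0]), k), "kin",
                             options=ContinuationOptions(max_steps=200))
        assert br.limit_points == []
        ps = [pt.p for pt in br.points]
        cs = [pt.u[0] for pt in br.points]
        order = np.argsort(ps)
        assert np.all(np.diff(np.array(cs)[order]) > -1e-9)
        for pt in br.points:
            assert np.isclose(pt.u[0], pt.p / k["kout"], rtol=1e-6)

    def test_motif_sigma_branch_two_folds(self, motif, motif_certificate):
        cert = motif_certificate
        br = continue_branch(motif, (cert.c, cert.k), "sigma3")
        assert len(br.limit_points) == 2
        region = detect_bistability(br)
        assert region is not None and region.p_lo < region.p_hi

    def test_branch_points_are_equilibria(self, motif, motif_certificate):
        cert = motif_certificate
        basis = conservation_basis(motif)
        br = continue_branch(motif, (cert.c, cert.k), "sigma3")
        kv = kinetics.rate_constants_vector(motif, cert.k)
        for pt in br.points[:: max(1, len(br.points) // 25)]:
            r = kinetics.rhs(motif, pt.u, kv)
            assert np.linalg.norm(r) < 1e-6 * max(1.0, float(np.max(pt.u)) ** 2)

    def test_fold_has_near_zero_eigenvalue(self, motif, motif_certificate):
        cert = motif_certificate
        br = continue_branch(motif, (cert.c, cert.k), "sigma3")
        for i in br.limit_points:
            eig = br.points[i].eigvals
            assert np.min(np.abs(eig.real)) < 1e-3

    def test_stability_flags_flip_at_folds(self, motif, motif_certificate):
        cert = motif_certificate
        br = continue_branch(motif, (cert.c, cert.k), "sigma3")
        flags = [pt.stability for pt in br.points]
        changes = [
            i for i in range(1, len(flags))
            if {flags[i - 1], flags[i]} == {"stable", "unstable"}
        ]
        # transitions happen only adjacent to detected folds
        for i in changes:
            assert min(abs(i - j) for j in br.limit_points) <= 3

    def test_rejects_non_equilibrium_start(self, motif):
        with pytest.raises(ValueError):
            continue_branch(motif, (np.ones(7), {l: 1.0 for l in motif.labels}), "sigma1",
                            options=ContinuationOptions(max_steps=10))

    def test_unknown_parameter(self, motif, motif_certificate):
        with pytest.raises(ValueError):
            continue_branch(motif, (motif_certificate.c, motif_certificate.k), "nope")

    def test_csv_schema(self, motif, motif_certificate, tmp_path):
        cert = motif_certificate
        br = continue_branch(motif, (cert.c, cert.k), "sigma3",
                             options=ContinuationOptions(max_steps=60))
        path = tmp_path / "branch.csv"
        br.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["parameter", *motif.species, "leading_eig_real",
                                    "stability", "limit_point"]
        assert len(df) == len(br.points)


class TestBistability:
    def test_no_folds_no_region(self):
        net = parse_network("kin: 0 -> A\nkout: A -> 0")
        br = continue_branch(net, (np.array([2.0]), {"kin": 2.0, "kout": 1.0}), "kin",
                             options=ContinuationOptions(max_steps=100))
        assert detect_bistability(br) is None

    def test_motif_region_multiplicity(self, motif, motif_certificate):
        """Inside the reported region independent relaxation finds >= 2 stable
        equilibria in the compatibility class; beyond the folds exactly 1."""
        cert = motif_certificate
        basis = conservation_basis(motif)
        br = continue_branch(motif, (cert.c, cert.k), "sigma3")
        region = detect_bistability(br)
        assert region is not None
        sig_idx = 2  # sigma3
        width = region.p_hi - region.p_lo

        def states_at(p):
            c_ref = cert.c.copy()
            # rescale the reference onto the target compatibility class
            sig = basis.B.T @ c_ref
            target = sig.astype(float).copy()
            target[sig_idx] = p
            # adjust by moving the free species of the swept moiety
            c_adj = c_ref.astype(float).copy()
            mo_species = np.where(basis.B[:, sig_idx] > 0)[0]
            c_adj[mo_species[0]] += (p - sig[sig_idx]) / basis.B[mo_species[0], sig_idx]
            c_adj = np.maximum(c_adj, 1e-9)
            return find_equilibria(motif, cert.k, c_adj, n_starts=16, seed=0, B=basis)

        inside = states_at(region.p_lo + 0.5 * width)
        assert len(inside) >= 2
        outside = states_at(region.p_hi + 5 * width)
        assert len(outside) == 1

    def test_motif_semidiffusive_k17_region(self, motif_sd, motif_sd_certificate):
        cert = motif_sd_certificate
        br = continue_branch(motif_sd, (cert.c, cert.k), "k17")
        assert len(br.limit_points) == 2
        assert detect_bistability(br) is not None

    def test_hysteresis_quasi_static(self, motif_sd, motif_sd_certificate):
        """Forward and backward quasi-static sweeps of the basal-formation
        constant jump at different parameter values bracketing the folds."""
        cert = motif_sd_certificate
        br = continue_branch(motif_sd, (cert.c, cert.k), "k17")
        region = detect_bistability(br)
        assert region is not None
        lo, hi = region.p_lo, region.p_hi
        vals = np.linspace(0.7 * lo, 1.3 * hi, 9)
        i_target = motif_sd.species_index("AA*")
        start_low = relax_to_equilibrium(motif_sd, cert.c, {**cert.k, "k17": vals[0]})
        up = quasi_static_sweep(motif_sd, start_low, {**cert.k, "k17": float(vals[0])},
                                "k17", vals)
        x_end = up[list(motif_sd.species)].iloc[-1].to_numpy(dtype=float)
        down = quasi_static_sweep(motif_sd, x_end, {**cert.k, "k17": float(vals[-1])},
                                  "k17", vals[::-1])
        down = down.iloc[::-1].reset_index(drop=True)
        diff = np.abs(np.log(up["AA*"].to_numpy()) - np.log(down["AA*"].to_numpy()))
        assert np.any(diff > 0.1)  # hysteretic branch separation inside the loop
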