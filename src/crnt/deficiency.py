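"""Deficiency-oriented saddle-node search for mass-conserving networks.

For a uniterminal network the deficiency ``delta = M - l - s`` equals the
dimension of the deficiency subspace ``D = Ker(Y) ∩ Im(A)``.  Writing the
complex-space balance as ``A psi(c) = sum_i alpha_i omega_i`` with a basis
``omega`` of D introduces the *deficiency parameters* ``alpha`` and yields
``M - l`` independent polynomial equations ``H(c, alpha, k) = 0`` describing
the equilibrium locus.  Stacking the Jacobians of ``H`` and of the
conservation residual ``W = B^T c - sigma`` gives the square matrix

    G(c, alpha, k) = [[D_c H, D_alpha H],
                      [B^T,   0        ]]

of size ``N + delta``.  A strictly positive point with

* C.1  H(c, alpha, k) = 0,
* C.2  D_c H of full rank,
* C.3  rank G = N + delta - 1,

is a saddle-node (limit point) of the mass-action dynamics within its
stoichiometric compatibility class.  The search minimizes
``F_def = det(G)^2`` over rate constants, deficiency parameters and (for
under-dimensioned networks) a few fixed concentrations, solving ``H = 0``
for the remaining concentrations at every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
import sympy as sp
from scipy.optimize import linprog

from . import kinetics
from .network import (
    ConservationBasis,
    ReactionNetwork,
    conservation_basis,
    is_uniterminal,
    linkage_classes,
    matrix_rank,
)
from .optimize import SearchOptions, latin_hypercube, sign_bisection

__all__ = [
    "deficiency_basis",
    "ManifoldEquations",
    "dimensional_class",
    "G_matrix",
    "check_conditions_def",
    "SaddleNodeCertificateDef",
    "DeficiencySearchResult",
    "search_def",
]


def deficiency_basis(net: ReactionNetwork) -> np.ndarray:
    """Integer basis (M x delta) of the deficiency subspace Ker(Y) ∩ Ker(Lambda^T).

    Valid for uniterminal networks, where span(omega) = Ker([Y; Lambda^T]).
    Raises for non-uniterminal networks.
    """
    if not is_uniterminal(net):
        raise ValueError("deficiency basis requires a uniterminal network")
    _, Lam = linkage_classes(net)
    stacked = sp.Matrix(np.vstack([net.Y, Lam.T]).tolist())
    kern = stacked.nullspace()
    cols = []
    for v in kern:
        denoms = [sp.fraction(x)[1] for x in v]
        lcm = sp.ilcm(*denoms) if denoms else 1
        w = [int(x * lcm) for x in v]
        g = 0
        for x in w:
            g = gcd(g, abs(x))
        if g > 1:
            w = [x // g for x in w]
        cols.append(w)
    if not cols:
        return np.zeros((net.M, 0), dtype=int)
    return np.array(cols, dtype=int).T


def dimensional_class(lam: int, delta: int) -> str:
    """Network classification: 'proper' (lam = delta), 'over' (lam < delta),
    'under' (lam > delta)."""
    if lam == delta:
        return "proper"
    return "over" if lam < delta else "under"


class ManifoldEquations:
    """Evaluator of the M - l equilibrium-manifold equations H(c, alpha, k).

    Built from ``A psi(c) - Omega alpha``: within each linkage class the rows
    sum to zero (the kinetic matrix and the basis vectors both annihilate the
    class-indicator vectors), so one dependent row per class - the class's
    first complex - is dropped, leaving M - l independent equations.
    """

    def __init__(self, net: ReactionNetwork, omega: np.ndarray | None = None):
        self.net = net
        self.omega = deficiency_basis(net) if omega is None else np.asarray(omega)
        if self.omega.shape[0] != net.M:
            raise ValueError("basis rows must match the number of complexes")
        comps, self.Lambda = linkage_classes(net)
        drop = {comp[0] for comp in comps}
        self.kept_rows = [i for i in range(net.M) if i not in drop]
        self.delta = self.omega.shape[1]

    @property
    def n_equations(self) -> int:
        return len(self.kept_rows)

    def residual(self, c, alpha, k) -> np.ndarray:
        A = kinetics.kinetic_matrix(self.net, k)
        psi = kinetics.monomials(self.net, c, guard=False)
        full = A @ psi - self.omega @ np.atleast_1d(np.asarray(alpha, dtype=float)) if self.delta else A @ psi
        return full[self.kept_rows]

    def d_c(self, c, k) -> np.ndarray:
        """Jacobian of H with respect to c (rows kept_rows, N columns)."""
        c = np.maximum(np.asarray(c, dtype=float), 1e-300)
        A = kinetics.kinetic_matrix(self.net, k)
        psi = kinetics.monomials(self.net, c, guard=False)
        dpsi = (psi[:, None] * self.net.Y.T) / c  # M x N
        return (A @ dpsi)[self.kept_rows]

    def d_alpha(self) -> np.ndarray:
        return -self.omega[self.kept_rows]

    def relative_residual(self, c, alpha, k) -> float:
        """Residual of H scaled row-wise by the magnitude of its terms, so the
        equilibrium test is meaningful across concentration scales."""
        A = kinetics.kinetic_matrix(self.net, k)
        psi = kinetics.monomials(self.net, c, guard=False)
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        scale = np.abs(A) @ psi
        if self.delta:
            scale = scale + np.abs(self.omega) @ np.abs(alpha)
        scale = np.maximum(scale[self.kept_rows], 1.0)
        return float(np.linalg.norm(self.residual(c, alpha, k) / scale, np.inf))

    def alpha_for_equilibrium(self, c, k) -> tuple[np.ndarray, float]:
        """Least-squares deficiency parameters for a given state, and the
        residual norm of H at that (c, alpha, k)."""
        A = kinetics.kinetic_matrix(self.net, k)
        psi = kinetics.monomials(self.net, c)
        if self.delta == 0:
            alpha = np.zeros(0)
        else:
            alpha, *_ = np.linalg.lstsq(self.omega, A @ psi, rcond=None)
        return alpha, float(np.linalg.norm(self.residual(c, alpha, k)))


def G_matrix(
    net: ReactionNetwork,
    c,
    alpha,
    k,
    B: np.ndarray,
    manifold: ManifoldEquations | None = None,
) -> np.ndarray:
    """The square (N + delta) saddle-node test matrix [[DcH, DaH], [B^T, 0]]."""
    man = manifold or ManifoldEquations(net)
    DcH = man.d_c(c, k)
    DaH = man.d_alpha()
    lam = B.shape[1]
    top = np.hstack([DcH, DaH])
    bottom = np.hstack([B.T, np.zeros((lam, man.delta))])
    G = np.vstack([top, bottom])
    n = net.N + man.delta
    if G.shape != (n, n):
        raise ValueError(f"G has shape {G.shape}, expected ({n}, {n}); inconsistent B or omega")
    return G


def _equilibrated_det(G: np.ndarray) -> tuple[float, float]:
    """(det of the row-equilibrated matrix, raw det).  Each row is scaled to
    unit infinity norm before the determinant to tame the dynamic range."""
    raw = float(np.linalg.det(G))
    scale = np.max(np.abs(G), axis=1)
    scale[scale == 0] = 1.0
    return float(np.linalg.det(G / scale[:, None])), raw


@dataclass
class ConditionReport:
    satisfied: bool
    H_norm: float  # raw residual norm
    H_rel: float  # residual scaled by the magnitude of the equation terms
    rank_DcH: int
    rank_DcH_required: int
    rank_G: int
    rank_G_required: int
    c_positive: bool
    k_positive: bool

    @property
    def C1(self) -> bool:
        return self.H_rel <= 1e-8

    @property
    def C2(self) -> bool:
        return self.rank_DcH == self.rank_DcH_required

    @property
    def C3(self) -> bool:
        return self.rank_G == self.rank_G_required


def check_conditions_def(
    net: ReactionNetwork,
    c,
    alpha,
    k,
    B: np.ndarray | None = None,
    manifold: ManifoldEquations | None = None,
    h_tol: float = 1e-8,
) -> ConditionReport:
    """Diagnostics for the saddle-node conditions C.1-C.3 at a point."""
    man = manifold or ManifoldEquations(net)
    if B is None:
        B = conservation_basis(net).B
    c = np.asarray(c, dtype=float)
    kv = kinetics.rate_constants_vector(net, k)
    H = man.residual(c, alpha, kv)
    DcH = man.d_c(c, kv)
    G = G_matrix(net, c, alpha, kv, B, man)
    ml = man.n_equations
    rep = ConditionReport(
        satisfied=False,
        H_norm=float(np.linalg.norm(H)),
        H_rel=man.relative_residual(c, alpha, kv),
        rank_DcH=matrix_rank(DcH),
        rank_DcH_required=min(net.N, ml),
        rank_G=matrix_rank(G),
        rank_G_required=net.N + man.delta - 1,
        c_positive=bool(np.all(c > 0)),
        k_positive=bool(np.all(kv > 0)),
    )
    rep.satisfied = (
        rep.H_rel <= h_tol and rep.C2 and rep.C3 and rep.c_positive and rep.k_positive
    )
    return rep


@dataclass
class SaddleNodeCertificateDef:
    """A certified saddle-node point of the deficiency-oriented search."""

    c: np.ndarray
    k: dict[str, float]
    alpha: np.ndarray
    sigma: np.ndarray
    F_def: float
    det_G: float
    conditions: ConditionReport
    species: tuple[str, ...]

    def summary(self) -> str:
        lines = ["Saddle-node certificate (deficiency route)", "-" * 44]
        lines.append(f"F_def = det(G)^2 = {self.F_def:.3e}   (raw det G = {self.det_G:.3e})")
        r = self.conditions
        lines.append(f"C.1 |H| = {r.H_norm:.2e}  C.2 rank DcH = {r.rank_DcH}/{r.rank_DcH_required}  "
                     f"C.3 rank G = {r.rank_G}/{r.rank_G_required}")
        lines.append("steady state:")
        for sp_, ci in zip(self.species, self.c):
            lines.append(f"  [{sp_}] = {ci:.6g}")
        lines.append("rate constants:")
        for lbl, kj in self.k.items():
            lines.append(f"  {lbl} = {kj:.6g}")
        lines.append("deficiency parameters alpha = " + np.array2string(self.alpha, precision=6))
        lines.append("conservation constants sigma = " + np.array2string(self.sigma, precision=6))
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "method": "deficiency",
            "c": {s: float(v) for s, v in zip(self.species, self.c)},
            "k": {l: float(v) for l, v in self.k.items()},
            "alpha": [float(a) for a in self.alpha],
            "sigma": [float(s) for s in self.sigma],
            "F_def": self.F_def,
            "det_G": self.det_G,
            "conditions": {
                "C1_H_norm": self.conditions.H_norm,
                "C2_rank_DcH": self.conditions.rank_DcH,
                "C3_rank_G": self.conditions.rank_G,
            },
        }


@dataclass
class DeficiencySearchResult:
    found: bool
    certificate: SaddleNodeCertificateDef | None
    best_objective: float
    n_evals: int
    message: str = ""

    def summary(self) -> str:
        if self.found:
            return self.certificate.summary()
        return (
            "No saddle-node certificate found within the search budget "
            f"(best F_def = {self.best_objective:.3e}, {self.n_evals} evaluations).\n"
            "Note: failure to find a certificate does not preclude multistationarity."
        )


class _InnerSolver:
    """Solves H(c, alpha, k) = 0 for the non-decision unknowns at a candidate x.

    The manifold equations are linear in the monomial vector psi and
    log-linear in c, so the solve is split accordingly:

    1. the kept rows of ``A psi = Omega alpha`` are a full-row-rank linear
       system in psi; its solution set is ``psi = psi_base + W u`` with ``u``
       collecting the kernel coordinates plus (for over-dimensioned networks)
       the free trailing alpha components;
    2. strict positivity of psi over that affine set is decided exactly by a
       Chebyshev-center linear program (fast rejection of infeasible
       candidates);
    3. the remaining *toric consistency* system
       ``Y^T log c = log(psi_base + W u)`` — with the decision-fixed
       concentration components substituted — is square and mildly nonlinear;
       a damped Newton iteration (steps shortened to keep psi positive)
       solves it from the LP center or a warm start.
    """

    def __init__(self, net, man: ManifoldEquations, fixed_c_idx, free_alpha: int):
        self.net = net
        self.man = man
        self.fixed_c_idx = list(fixed_c_idx)
        self.unknown_c_idx = [i for i in range(net.N) if i not in self.fixed_c_idx]
        self.free_alpha = free_alpha  # count of alpha components solved for
        self.warm: tuple[np.ndarray, np.ndarray] | None = None
        self.YT = net.Y.T.astype(float)  # M x N

    def _affine_psi(self, kv, alpha_fixed):
        """psi_base and W such that the kept rows of A psi - Omega alpha = 0
        become psi = psi_base + W u, u = (kernel coords, free alpha)."""
        man = self.man
        A_kept = kinetics.kinetic_matrix(self.net, kv)[man.kept_rows]  # (M-l) x M
        delta = man.delta
        Om_kept = man.omega[man.kept_rows] if delta else np.zeros((len(man.kept_rows), 0))
        rhs = Om_kept[:, : delta - self.free_alpha] @ np.asarray(alpha_fixed, dtype=float) \
            if delta - self.free_alpha else np.zeros(len(man.kept_rows))
        psi_base, *_ = np.linalg.lstsq(A_kept, rhs, rcond=None)
        # kernel of the kept rows (dimension l for uniterminal networks)
        u_, s_, vt = np.linalg.svd(A_kept)
        tol = max(A_kept.shape) * np.finfo(float).eps * (s_[0] if len(s_) else 1.0)
        kernel = vt[np.sum(s_ > tol):].T  # M x l
        cols = [kernel]
        if self.free_alpha:
            Q, *_ = np.linalg.lstsq(A_kept, Om_kept[:, delta - self.free_alpha:], rcond=None)
            cols.append(Q)
        W = np.hstack(cols)
        return psi_base, W

    @staticmethod
    def _positive_center(psi_base, W):
        """Chebyshev-style LP: u maximizing the minimum entry of psi_base + W u
        (capped at 1); None when no strictly positive psi exists."""
        m, n_u = W.shape
        # variables (u, eps): maximize eps  s.t.  -W u + eps <= psi_base
        A_ub = np.hstack([-W, np.ones((m, 1))])
        res = linprog(
            c=np.concatenate([np.zeros(n_u), [-1.0]]),
            A_ub=A_ub,
            b_ub=psi_base,
            bounds=[(-1e12, 1e12)] * n_u + [(None, 1.0)],
            method="highs",
        )
        if not res.success or res.x[-1] <= 1e-12:
            return None
        return res.x[:n_u]

    def solve(self, kv, alpha_fixed, c_fixed, warm=None):
        man = self.man
        delta = man.delta
        N, M = self.net.N, self.net.M
        free_idx = self.unknown_c_idx
        n_x = len(free_idx)
        psi_base, W = self._affine_psi(kv, alpha_fixed)
        n_u = W.shape[1]
        if n_u + n_x != M:
            return None  # inconsistent dimensions (non-uniterminal kernel)

        x_fix_contrib = np.zeros(M)
        for i, idx in enumerate(self.fixed_c_idx):
            if c_fixed[i] <= 0:
                return None
            x_fix_contrib += self.YT[:, idx] * np.log(c_fixed[i])

        starts = []
        if warm is not None:
            starts.append(warm)
        elif self.warm is not None:
            starts.append(self.warm)
        u0 = self._positive_center(psi_base, W)
        if u0 is None:
            return None
        psi0 = np.maximum(psi_base + W @ u0, 1e-300)  # LP feasibility slack can leave tiny negatives
        x0, *_ = np.linalg.lstsq(self.YT[:, free_idx], np.log(psi0) - x_fix_contrib, rcond=None)
        starts.append((u0, x0))

        for u, x in starts:
            got = self._newton(u.copy(), x.copy(), psi_base, W, x_fix_contrib, free_idx)
            if got is None:
                continue
            u, x = got
            c = np.empty(N)
            for i, idx in enumerate(self.fixed_c_idx):
                c[idx] = c_fixed[i]
            c[free_idx] = np.exp(np.clip(x, -230, 230))
            alpha = np.empty(delta)
            alpha[: delta - self.free_alpha] = alpha_fixed
            if self.free_alpha:
                alpha[delta - self.free_alpha:] = u[-self.free_alpha:]
            scale = max(1.0, float(np.max(np.abs(psi_base + W @ u))))
            if np.linalg.norm(man.residual(c, alpha, kv)) > 1e-7 * scale:
                continue
            self.warm = (u, x)
            return c, alpha
        return None

    def _newton(self, u, x, psi_base, W, x_fix_contrib, free_idx, max_iter=60):
        Yf = self.YT[:, free_idx]  # M x n_x
        n_u = W.shape[1]
        for _ in range(max_iter):
            psi = psi_base + W @ u
            if np.any(psi <= 0):
                return None
            r = Yf @ x + x_fix_contrib - np.log(psi)
            if np.linalg.norm(r, np.inf) < 1e-11:
                return u, x
            J = np.hstack([-W / psi[:, None], Yf])
            try:
                dz = np.linalg.lstsq(J, -r, rcond=None)[0]
            except np.linalg.LinAlgError:
                return None
            du, dx = dz[:n_u], dz[n_u:]
            # fraction-to-boundary damping: keep psi strictly positive
            denom = W @ du
            neg = denom < 0
            step = 1.0
            if np.any(neg):
                step = min(1.0, 0.95 * float(np.min(-psi[neg] / denom[neg])))
            if step <= 1e-14:
                return None
            u = u + step * du
            x = x + step * dx
            if not (np.all(np.isfinite(u)) and np.all(np.isfinite(x))):
                return None
        return None


def _choose_fixed_concentrations(net, man: ManifoldEquations, n_fix: int) -> list[int]:
    """Pick species to fix in under-dimensioned networks so that the remaining
    D_c H block keeps full rank at a generic point (greedy, deterministic)."""
    if n_fix == 0:
        return []
    rng = np.random.default_rng(12345)
    c = rng.uniform(0.5, 2.0, net.N)
    kv = rng.uniform(0.5, 2.0, net.R)
    J = man.d_c(c, kv)
    full = matrix_rank(J)
    fixed: list[int] = []
    for i in range(net.N):
        if len(fixed) == n_fix:
            break
        trial = fixed + [i]
        keep = [j for j in range(net.N) if j not in trial]
        if matrix_rank(J[:, keep]) == full:
            fixed.append(i)
    if len(fixed) < n_fix:  # fall back to the first species
        fixed = list(range(n_fix))
    return fixed


def search_def(
    net: ReactionNetwork,
    bounds: dict | None = None,
    options: SearchOptions | None = None,
    *,
    B: ConservationBasis | None = None,
    fixed: dict[str, float] | None = None,
) -> DeficiencySearchResult:
    """Search for a saddle-node certificate by the deficiency-oriented route.

    The decision vector is ``x = (k, alpha[, fixed c components])`` depending
    on the dimensional class; at each candidate the manifold equations are
    solved for the remaining concentrations and the objective is the squared
    determinant of the row-equilibrated ``G``.  Candidates whose signed
    determinants differ bracket a zero; Brent refinement drives ``F_def``
    below the acceptance tolerance, and the rank conditions are then verified.

    ``bounds`` may override the default boxes with keys ``"k"``, ``"alpha"``
    and ``"c"`` mapping to (low, high) pairs.  ``fixed`` pins individual rate
    constants (by label) or concentrations (key ``"c:<species>"``).
    """
    options = options or SearchOptions()
    if not is_uniterminal(net):
        raise ValueError("deficiency-oriented search requires a uniterminal network")
    basis = B or conservation_basis(net)
    lam = basis.lam
    if lam < 1:
        raise ValueError("deficiency-oriented search requires at least one conservation law")
    man = ManifoldEquations(net)
    delta = man.delta
    klass = dimensional_class(lam, delta)

    bounds = bounds or {}
    k_lo, k_hi = bounds.get("k", (1e-3, 1e3))
    a_lo, a_hi = bounds.get("alpha", (-1e3, 1e3))
    c_lo, c_hi = bounds.get("c", (1e-3, 1e3))
    if k_lo <= 0 or c_lo <= 0:
        raise ValueError("lower bounds for k and c must be positive")
    fixed = fixed or {}

    n_fix_c = max(lam - delta, 0)
    n_alpha_dec = delta if klass != "over" else lam
    free_alpha = delta - n_alpha_dec
    fixed_c_idx = _choose_fixed_concentrations(net, man, n_fix_c)
    solver = _InnerSolver(net, man, fixed_c_idx, free_alpha)

    # decision vector layout: [log10 k (R)] + [alpha, signed-log coded (n_alpha_dec)]
    # + [log10 c_fixed (n_fix_c)].  The alpha coordinate t maps to
    # sign(t) * (10^|t| - 1): deficiency parameters can take either sign and
    # span decades, so their magnitudes are explored logarithmically.
    t_hi = np.log10(1.0 + max(abs(a_lo), abs(a_hi)))
    box = [(np.log10(k_lo), np.log10(k_hi))] * net.R
    box += [(-t_hi, t_hi)] * n_alpha_dec
    box += [(np.log10(c_lo), np.log10(c_hi))] * n_fix_c

    pinned_k = {}
    pinned_c = {}
    for key, val in fixed.items():
        if key.startswith("c:"):
            pinned_c[net.species_index(key[2:])] = float(val)
        else:
            pinned_k[key] = float(val)

    labels = net.labels
    n_evals = 0
    best = np.inf

    def unpack(x):
        kv = 10.0 ** x[: net.R]
        for lbl, val in pinned_k.items():
            kv[labels.index(lbl)] = val
        t = x[net.R: net.R + n_alpha_dec]
        alpha_dec = np.sign(t) * (10.0 ** np.abs(t) - 1.0)
        c_fixed = 10.0 ** x[net.R + n_alpha_dec:]
        for i, idx in enumerate(fixed_c_idx):
            if idx in pinned_c:
                c_fixed[i] = pinned_c[idx]
        return kv, alpha_dec, c_fixed

    def signed_det(x, warm=None):
        nonlocal n_evals, best
        n_evals += 1
        kv, alpha_dec, c_fixed = unpack(x)
        sol = solver.solve(kv, alpha_dec, c_fixed, warm=warm)
        if sol is None:
            return np.nan
        c, alpha = sol
        G = G_matrix(net, c, alpha, kv, basis.B, man)
        det_eq, _ = _equilibrated_det(G)
        best = min(best, det_eq ** 2)
        return det_eq

    def certify(x) -> SaddleNodeCertificateDef | None:
        kv, alpha_dec, c_fixed = unpack(x)
        sol = solver.solve(kv, alpha_dec, c_fixed)
        if sol is None:
            return None
        c, alpha = sol
        if np.any(c <= 0) or np.any(c < c_lo / 1e3) or np.any(c > c_hi * 1e3):
            return None
        G = G_matrix(net, c, alpha, kv, basis.B, man)
        det_eq, det_raw = _equilibrated_det(G)
        if det_eq ** 2 > options.tol:
            return None
        rep = check_conditions_def(net, c, alpha, kv, basis.B, man)
        if not rep.satisfied:
            return None
        return SaddleNodeCertificateDef(
            c=c,
            k={lbl: float(v) for lbl, v in zip(labels, kv)},
            alpha=alpha,
            sigma=basis.B.T @ c,
            F_def=det_eq ** 2,
            det_G=det_raw,
            conditions=rep,
            species=net.species,
        )

    rng = np.random.default_rng(options.seed)
    # adaptive exploration: det(G) sign changes can be rare in decision space,
    # so sample in batches until both signs are represented (or the budget for
    # the exploration phase runs out)
    evals = []
    n_pos = n_neg = 0
    want = max(2, options.multistarts // 3)
    batch = max(30 * options.multistarts, 300)
    explore_cap = min(40 * batch, options.budget // 2)
    while n_evals < explore_cap:
        X = latin_hypercube(rng, batch, box)
        for x in X:
            solver.warm = None
            d = signed_det(x)
            if np.isfinite(d):
                evals.append((d, x))
                if d > 0:
                    n_pos += 1
                else:
                    n_neg += 1
            if n_evals >= explore_cap:
                break
        if n_pos >= want and n_neg >= want:
            break

    pos = sorted([e for e in evals if e[0] > 0], key=lambda t: t[0])
    neg = sorted([e for e in evals if e[0] < 0], key=lambda t: -t[0])
    attempts = 0
    for dp, xp in pos:
        for dn, xn in neg:
            if attempts >= options.multistarts or n_evals >= options.budget:
                break
            attempts += 1
            solver.warm = None
            root = sign_bisection(lambda x: signed_det(x), xp, xn)
            if root is None:
                continue
            cert = certify(root)
            if cert is not None:
                return DeficiencySearchResult(True, cert, cert.F_def, n_evals)
        if attempts >= options.multistarts or n_evals >= options.budget:
            break

    return DeficiencySearchResult(
        False,
        None,
        best,
        n_evals,
        message="no sign change of det(G) located" if not (pos and neg) else "bisection did not certify",
    )
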