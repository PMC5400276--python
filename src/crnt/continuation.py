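"""Equilibrium continuation from a certified saddle-node.

A pseudo-arclength predictor-corrector traces the equilibrium curve of the
mass-action dynamics as one parameter varies: either a rate constant or one
conservation constant ``sigma_i`` (the total amount of a conserved moiety).
For mass-conserving networks the traced system is the reduced one,

    F(c, p) = [ P S v(c, k) ;  B^T c - sigma ] = 0,

with ``P`` selecting ``s`` independent rows of ``S``.  Limit points (folds)
are located by a sign change of the parameter component of the unit tangent
and refined by bisection on the arclength step; at every accepted point the
eigenvalues of the Jacobian reduced to the stoichiometric compatibility class
decide stability.  A bistable region is a parameter interval between two
folds carrying two stable branch segments with an unstable one in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sopt

from . import kinetics
from .network import ConservationBasis, ReactionNetwork, conservation_basis, matrix_rank

__all__ = [
    "BranchPoint",
    "EquilibriumBranch",
    "BistabilityRegion",
    "ContinuationOptions",
    "trace_curve",
    "continue_branch",
    "detect_bistability",
    "reduced_jacobian",
    "relax_to_equilibrium",
    "quasi_static_sweep",
    "find_equilibria",
]

STABILITY_THRESHOLD = 1e-8


@dataclass
class ContinuationOptions:
    step: float = 0.05
    min_step: float = 1e-8
    max_step: float = 1.0
    max_steps: int = 800
    corrector_tol: float = 1e-10
    max_corrector_iter: int = 8
    p_range: tuple[float, float] = (0.0, np.inf)


@dataclass
class BranchPoint:
    p: float
    u: np.ndarray
    eigvals: np.ndarray | None = None
    stability: str = "unknown"  # 'stable' | 'unstable' | 'near-critical'
    tangent_p: float = 0.0


@dataclass
class EquilibriumBranch:
    parameter: str
    points: list[BranchPoint]
    limit_points: list[int]
    species: tuple[str, ...] = ()
    truncated: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"parameter": [pt.p for pt in self.points]}
        names = self.species or tuple(f"u{i+1}" for i in range(len(self.points[0].u)))
        for i, name in enumerate(names):
            cols[name] = [pt.u[i] for pt in self.points]
        cols["leading_eig_real"] = [
            float(np.max(pt.eigvals.real)) if pt.eigvals is not None and len(pt.eigvals) else np.nan
            for pt in self.points
        ]
        cols["stability"] = [pt.stability for pt in self.points]
        cols["limit_point"] = [i in self.limit_points for i in range(len(self.points))]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class BistabilityRegion:
    p_lo: float
    p_hi: float
    stable_low: BranchPoint
    stable_high: BranchPoint
    unstable: BranchPoint

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<BistabilityRegion [{self.p_lo:.6g}, {self.p_hi:.6g}]>"


# ---------------------------------------------------------------------------
# generic pseudo-arclength tracer
# ---------------------------------------------------------------------------

def _tangent(Ju: np.ndarray, Jp: np.ndarray, prev: np.ndarray | None) -> np.ndarray | None:
    """Unit kernel vector of the extended Jacobian [Ju | Jp], oriented to keep
    a positive inner product with the previous tangent."""
    n = Ju.shape[0]
    A = np.hstack([Ju, Jp.reshape(n, 1)])
    _, _, vt = np.linalg.svd(A)
    tau = vt[-1]
    nrm = np.linalg.norm(tau)
    if nrm == 0 or not np.all(np.isfinite(tau)):
        return None
    tau = tau / nrm
    if prev is not None and tau @ prev < 0:
        tau = -tau
    return tau


def _correct(F, Ju, Jp, u_pred, p_pred, tau, u_ref, p_ref, opts: ContinuationOptions):
    """Newton corrector orthogonal to the tangent; returns (u, p, n_iter) or None."""
    u, p = np.array(u_pred, dtype=float), float(p_pred)
    n = len(u)
    for it in range(1, opts.max_corrector_iter + 1):
        r = F(u, p)
        ortho = tau[:n] @ (u - u_ref) + tau[n] * (p - p_ref) - 0.0
        res = np.concatenate([r, [ortho]])
        if np.linalg.norm(r) < opts.corrector_tol and abs(ortho) < 1e-12:
            return u, p, it
        J = np.zeros((n + 1, n + 1))
        J[:n, :n] = Ju(u, p)
        J[:n, n] = Jp(u, p)
        J[n, :n] = tau[:n]
        J[n, n] = tau[n]
        try:
            dz = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            return None
        u = u + dz[:n]
        p = p + dz[n]
        if not np.all(np.isfinite(u)) or not np.isfinite(p):
            return None
    r = F(u, p)
    if np.linalg.norm(r) < opts.corrector_tol:
        return u, p, opts.max_corrector_iter
    return None


def trace_curve(
    F: Callable[[np.ndarray, float], np.ndarray],
    Ju: Callable[[np.ndarray, float], np.ndarray],
    Jp: Callable[[np.ndarray, float], np.ndarray],
    u0: np.ndarray,
    p0: float,
    *,
    direction: int = 1,
    options: ContinuationOptions | None = None,
    eig_fn: Callable[[np.ndarray, float], np.ndarray] | None = None,
    positivity: bool = True,
) -> EquilibriumBranch:
    """Trace the solution curve of F(u, p) = 0 through (u0, p0).

    ``direction`` selects the initial orientation along the curve (sign of the
    parameter component of the first tangent, or of the dominant state
    component at a fold).  Fold points are refined by bisection on the
    arclength step and flagged in ``limit_points``.
    """
    opts = options or ContinuationOptions()
    u = np.array(u0, dtype=float)
    p = float(p0)
    res0 = np.linalg.norm(F(u, p))
    if res0 > 1e2 * opts.corrector_tol:
        # polish the start onto the curve at fixed p
        sol = sopt.root(lambda x: F(x, p), u, method="hybr")
        if not sol.success or np.linalg.norm(sol.fun) > 1e2 * opts.corrector_tol:
            raise ValueError(f"start point is not an equilibrium (|F| = {res0:.2e})")
        u = sol.x

    tau = _tangent(Ju(u, p), Jp(u, p), None)
    if tau is None:
        raise ValueError("singular extended Jacobian at the start point")
    # orient: by parameter component if it is significant, else by state part
    comp = tau[-1] if abs(tau[-1]) > 1e-6 else tau[np.argmax(np.abs(tau[:-1]))]
    if comp * direction < 0:
        tau = -tau

    def make_point(u, p, tau) -> BranchPoint:
        eig = eig_fn(u, p) if eig_fn is not None else None
        stability = "unknown"
        if eig is not None and len(eig):
            mre = float(np.max(eig.real))
            if mre < -STABILITY_THRESHOLD:
                stability = "stable"
            elif mre > STABILITY_THRESHOLD:
                stability = "unstable"
            else:
                stability = "near-critical"
        return BranchPoint(p=float(p), u=np.array(u), eigvals=eig, stability=stability, tangent_p=float(tau[-1]))

    points = [make_point(u, p, tau)]
    limit_points: list[int] = []
    truncated = False
    h = opts.step
    n = len(u)
    visited = [np.concatenate([u, [p]])]

    def step_from(u, p, tau, h):
        u_pred = u + h * tau[:n]
        p_pred = p + h * tau[n]
        return _correct(F, Ju, Jp, u_pred, p_pred, tau, u_pred, p_pred, opts)

    for _ in range(opts.max_steps):
        ok = None
        while h >= opts.min_step:
            ok = step_from(u, p, tau, h)
            if ok is not None:
                u_new, p_new, iters = ok
                if positivity and np.any(u_new <= 0):
                    ok = None
                else:
                    break
            h = h / 2
        if ok is None:
            truncated = True
            break
        tau_new = _tangent(Ju(u_new, p_new), Jp(u_new, p_new), tau)
        if tau_new is None:
            truncated = True
            break
        if tau[-1] * tau_new[-1] < 0:
            # fold between the previous and the new point: bisect the step
            fold = _refine_fold(F, Ju, Jp, u, p, tau, h, opts, n)
            if fold is not None:
                uf, pf, tauf = fold
                points.append(make_point(uf, pf, tauf))
                limit_points.append(len(points) - 1)
        points.append(make_point(u_new, p_new, tau_new))
        # loop detection: tracers can fall back onto an already-traversed
        # sheet after a sharp fold; stop instead of cycling
        z_new = np.concatenate([u_new, [p_new]])
        if len(visited) > 20:
            past = np.array(visited[:-15])
            d = np.min(np.linalg.norm(past - z_new, axis=1))
            if d < 1e-6 * max(1.0, float(np.linalg.norm(z_new))):
                u, p, tau = u_new, p_new, tau_new
                break
        visited.append(z_new)
        u, p, tau = u_new, p_new, tau_new
        if iters <= 3:
            h = min(h * 1.5, opts.max_step)
        elif iters >= opts.max_corrector_iter - 1:
            h = max(h / 2, opts.min_step)
        if not (opts.p_range[0] <= p <= opts.p_range[1]):
            break

    limit_points = _confirm_folds(points, limit_points)
    return EquilibriumBranch("p", points, limit_points, truncated=truncated)


def _confirm_folds(points, candidates, window: int = 5, rel_amp: float = 1e-7):
    """Keep only fold candidates that are genuine local extrema of the
    parameter: tangent-sign jitter on near-flat branch segments produces
    spurious sign changes whose local parameter amplitude is negligible."""
    confirmed = []
    ps = np.array([pt.p for pt in points])
    for i in candidates:
        lo, hi = max(0, i - window), min(len(ps), i + window + 1)
        seg = ps[lo:hi]
        amp = seg.max() - seg.min()
        if amp < rel_amp * (1.0 + abs(ps[i])):
            continue
        slack = 0.05 * amp
        if ps[i] >= seg.max() - slack or ps[i] <= seg.min() + slack:
            confirmed.append(i)
    # merge duplicates referring to the same extremum
    merged = []
    for i in confirmed:
        if merged and i - merged[-1] <= 2 and abs(ps[i] - ps[merged[-1]]) < rel_amp * (1 + abs(ps[i])):
            continue
        merged.append(i)
    return merged


def _refine_fold(F, Ju, Jp, u, p, tau, h, opts, n):
    """Bisection on the arclength step to pin the fold (tangent_p = 0)."""

    def tangent_p_at(s):
        ok = _correct(F, Ju, Jp, u + s * tau[:n], p + s * tau[n], tau, u + s * tau[:n], p + s * tau[n], opts)
        if ok is None:
            return None
        uu, pp, _ = ok
        tt = _tangent(Ju(uu, pp), Jp(uu, pp), tau)
        if tt is None:
            return None
        return uu, pp, tt

    lo, hi = 0.0, h
    glo = tau[-1]
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        got = tangent_p_at(mid)
        if got is None:
            hi = mid
            continue
        uu, pp, tt = got
        best = (uu, pp, tt)
        if glo * tt[-1] > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, h):
            break
    return best


# ---------------------------------------------------------------------------
# network-level continuation
# ---------------------------------------------------------------------------

def _independent_rows(S: np.ndarray) -> list[int]:
    rows: list[int] = []
    for i in range(S.shape[0]):
        cand = rows + [i]
        if matrix_rank(S[cand]) == len(cand):
            rows.append(i)
    return rows


def _dependent_species(B: np.ndarray) -> list[int]:
    """One dependent species per moiety: the largest coefficient (ties: lowest
    index), chosen so the dependent block of B is invertible."""
    lam = B.shape[1]
    dep: list[int] = []
    for m in range(lam):
        order = sorted(range(B.shape[0]), key=lambda i: (-B[i, m], i))
        for i in order:
            if B[i, m] <= 0 or i in dep:
                continue
            cand = dep + [i]
            if matrix_rank(B[cand, :]) == len(cand):
                dep.append(i)
                break
    if len(dep) < lam:
        raise ValueError("could not select independent dependent species from B")
    return dep


def reduced_jacobian(
    net: ReactionNetwork, c, k, B: np.ndarray | None = None
) -> np.ndarray:
    """Jacobian of the dynamics restricted to the stoichiometric compatibility
    class (s x s); equals the full Jacobian when there is no conservation."""
    J = kinetics.jacobian(net, c, k)
    if B is None:
        B = conservation_basis(net).B
    lam = B.shape[1]
    if lam == 0:
        return J
    dep = _dependent_species(B)
    ind = [i for i in range(net.N) if i not in dep]
    Bd = B[dep, :].T.astype(float)  # lam x lam
    Bi = B[ind, :].T.astype(float)  # lam x (N - lam)
    T = -np.linalg.solve(Bd, Bi)  # d c_dep / d c_ind
    return J[np.ix_(ind, ind)] + J[np.ix_(ind, dep)] @ T


def _parse_parameter(net: ReactionNetwork, basis: ConservationBasis, param: str):
    if param in net.labels:
        return ("k", net.labels.index(param))
    for prefix in ("sigma", "M"):
        if param.startswith(prefix):
            tail = param[len(prefix):]
            if tail.isdigit():
                i = int(tail) - 1
                if 0 <= i < basis.lam:
                    return ("sigma", i)
    raise ValueError(f"unknown continuation parameter {param!r}")


def continue_branch(
    net: ReactionNetwork,
    start: tuple[Sequence[float], dict | Sequence[float]],
    param: str,
    direction: str = "both",
    options: ContinuationOptions | None = None,
    *,
    B: ConservationBasis | None = None,
) -> EquilibriumBranch:
    """Trace the equilibrium branch through ``start = (c, k)`` as ``param``
    (a rate-constant label, or ``sigma<i>`` for a conservation constant) varies.

    With ``direction='both'`` the forward and backward traces are merged into
    one ordered branch; fold points are flagged and each point carries the
    leading eigenvalues of the reduced Jacobian with its stability call.
    """
    opts = options or ContinuationOptions()
    c0, k0 = start
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 <= 0):
        raise ValueError("start concentrations must be strictly positive")
    kv = kinetics.rate_constants_vector(net, k0)
    basis = B or conservation_basis(net)
    kind, idx = _parse_parameter(net, basis, param)
    S = net.S
    sel = _independent_rows(S)
    lam = basis.lam
    sigma0 = basis.B.T @ c0

    # the curve is traced in log coordinates (y = log c, q = log p): tangent
    # components become dimensionless, so the arclength step is meaningful
    # across branches spanning several decades
    def kvec(p):
        kk = kv.copy()
        if kind == "k":
            kk[idx] = p
        return kk

    def sigma(p):
        sg = sigma0.astype(float).copy()
        if kind == "sigma":
            sg[idx] = p
        return sg

    # fixed row scaling so rate and conservation residuals are comparable
    v0 = kinetics.rates(net, c0, kv)
    row_scale = 1.0 / np.maximum(np.abs(S[sel]).astype(float) @ v0, 1e-12)
    if lam:
        row_scale = np.concatenate([row_scale, 1.0 / np.maximum(np.abs(sigma0), 1.0)])

    def F(y, q):
        c, p = np.exp(np.clip(y, -230, 230)), float(np.exp(np.clip(q, -230, 230)))
        r = kinetics.rhs(net, c, kvec(p))[sel]
        if lam:
            r = np.concatenate([r, basis.B.T @ c - sigma(p)])
        return r * row_scale

    def Ju(y, q):
        c = np.exp(np.clip(y, -230, 230))
        p = float(np.exp(np.clip(q, -230, 230)))
        J = kinetics.jacobian(net, c, kvec(p))[sel]
        if lam:
            J = np.vstack([J, basis.B.T.astype(float)])
        return (J * c) * row_scale[:, None]  # chain rule d/dy = diag(c)

    def Jp(y, q):
        c = np.exp(np.clip(y, -230, 230))
        p = float(np.exp(np.clip(q, -230, 230)))
        if kind == "k":
            v_j = kinetics.rates(net, c, kvec(p))[idx] / kvec(p)[idx]
            col = S[:, idx].astype(float)[sel] * v_j
            if lam:
                col = np.concatenate([col, np.zeros(lam)])
        else:
            col = np.zeros(len(sel) + lam)
            col[len(sel) + idx] = -1.0
        return (col * p) * row_scale  # chain rule d/dq

    def eig_fn(y, q):
        c = np.exp(np.clip(y, -230, 230))
        p = float(np.exp(np.clip(q, -230, 230)))
        eig = np.linalg.eigvals(reduced_jacobian(net, c, kvec(p), basis.B))
        return eig[np.argsort(-eig.real)][: min(len(eig), 5)]

    p0 = float(kv[idx]) if kind == "k" else float(sigma0[idx])
    if p0 <= 0:
        raise ValueError("continuation parameter must start positive")
    start_res = np.linalg.norm(F(np.log(c0), np.log(p0)))
    if start_res > 1e-4:
        raise ValueError(
            f"start point is not an equilibrium (scaled residual {start_res:.2e})"
        )
    lo, hi = opts.p_range
    if lo == 0.0 and np.isinf(hi):
        # default window: six decades either side of the start; near the
        # boundary of the positive orthant the reduced system degenerates and
        # the trace would wander numerically
        lo, hi = p0 * 1e-6, p0 * 1e6
    log_opts = ContinuationOptions(
        step=opts.step,
        min_step=opts.min_step,
        max_step=opts.max_step,
        max_steps=opts.max_steps,
        corrector_tol=opts.corrector_tol,
        max_corrector_iter=opts.max_corrector_iter,
        p_range=(np.log(lo) if lo > 0 else -np.inf, np.log(hi) if np.isfinite(hi) else np.inf),
    )

    def run(sign):
        return trace_curve(
            F, Ju, Jp, np.log(c0), np.log(p0), direction=sign, options=log_opts,
            eig_fn=eig_fn, positivity=False,
        )

    if direction == "forward":
        branch = run(+1)
    elif direction == "backward":
        branch = run(-1)
    elif direction == "both":
        fwd = run(+1)
        bwd = run(-1)
        pts = list(reversed(bwd.points[1:])) + fwd.points
        off = len(bwd.points) - 1
        lps = sorted([off - i for i in bwd.limit_points if i > 0] + [off + i for i in fwd.limit_points])
        branch = EquilibriumBranch("p", pts, lps, truncated=fwd.truncated or bwd.truncated)
    else:
        raise ValueError("direction must be 'forward', 'backward' or 'both'")
    # map back from log coordinates
    for pt in branch.points:
        pt.p = float(np.exp(pt.p))
        pt.u = np.exp(pt.u)
    branch.parameter = param
    branch.species = net.species
    return branch


def relax_to_equilibrium(
    net: ReactionNetwork,
    c0,
    k,
    *,
    B: ConservationBasis | None = None,
    t_max: float = 5e5,
    tol: float = 1e-8,
) -> np.ndarray | None:
    """Integrate the mass-action ODEs to (near) steady state, then polish with
    Newton on the reduced equations.  Returns the equilibrium or None.

    Conserved totals are those of the initial condition (the dynamics keep
    them invariant).  This is the workhorse for basin-respecting equilibrium
    location: unlike a bare root solve it converges to a *stable* state
    reachable from ``c0``.
    """
    from scipy.integrate import solve_ivp

    c0 = np.asarray(c0, dtype=float)
    kv = kinetics.rate_constants_vector(net, k)
    basis = B or conservation_basis(net)
    Bf = basis.B.astype(float)
    sigma = Bf.T @ c0
    sel = _independent_rows(net.S)
    lam = basis.lam

    # moderate integration accuracy suffices: the Newton polish below drives
    # the equilibrium residual to full precision
    sol = solve_ivp(
        lambda t, x: kinetics.rhs(net, np.maximum(x, 1e-12), kv),
        (0.0, t_max),
        np.maximum(c0, 1e-12),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        return None
    xe = np.maximum(sol.y[:, -1], 1e-12)

    def G(y):
        cc = np.exp(np.clip(y, -60, 60))
        r = kinetics.rhs(net, cc, kv)[sel]
        if lam:
            r = np.concatenate([r, (Bf.T @ cc - sigma) / np.maximum(np.abs(sigma), 1.0)])
        return r

    pol = sopt.root(G, np.log(xe), method="hybr")
    if pol.success and np.linalg.norm(pol.fun) < tol:
        return np.exp(pol.x)
    # fall back to the integrated endpoint if it is already converged
    if np.linalg.norm(G(np.log(xe))) < tol:
        return xe
    return None


def quasi_static_sweep(
    net: ReactionNetwork,
    c0,
    k,
    param: str,
    values,
    *,
    B: ConservationBasis | None = None,
) -> pd.DataFrame:
    """Warm-started steady-state sweep of one rate constant.

    At each parameter value the system relaxes from the previous steady state
    (quasi-static protocol), so ascending and descending sweeps traverse the
    hysteresis loop and jump at different parameter values when the system is
    bistable.  Returns a DataFrame with the parameter and all concentrations.
    """
    basis = B or conservation_basis(net)
    kk = dict(k) if isinstance(k, dict) else {l: v for l, v in zip(net.labels, k)}
    if param not in kk:
        raise ValueError(f"unknown rate constant {param!r}")
    x = np.asarray(c0, dtype=float)
    rows = []
    for p in values:
        kk[param] = float(p)
        nxt = relax_to_equilibrium(net, x, kk, B=basis)
        ok = nxt is not None
        if ok:
            x = nxt
        rows.append([float(p), *x, ok])
    return pd.DataFrame(rows, columns=["parameter", *net.species, "converged"])


def find_equilibria(
    net: ReactionNetwork,
    k,
    c_ref,
    *,
    n_starts: int = 12,
    seed: int = 0,
    B: ConservationBasis | None = None,
    atol: float = 1e-4,
) -> list[np.ndarray]:
    """Distinct stable equilibria in the compatibility class of ``c_ref``,
    found by ODE relaxation from randomized initial conditions projected onto
    the class."""
    basis = B or conservation_basis(net)
    Bf = basis.B.astype(float)
    c_ref = np.asarray(c_ref, dtype=float)
    sigma = Bf.T @ c_ref
    rng = np.random.default_rng(seed)

    sig_norm = max(1.0, float(np.max(np.abs(sigma)))) if basis.lam else 1.0

    def project(c):
        """Map a positive draw onto the compatibility class by iterative
        proportional fitting (multiplicative updates preserve positivity),
        finished with a few additive Newton corrections."""
        if basis.lam == 0:
            return np.maximum(c, 1e-10)
        c = np.maximum(np.asarray(c, dtype=float), 1e-10)
        for _ in range(300):
            done = True
            for m in range(basis.lam):
                s = float(Bf[:, m] @ c)
                if s <= 0:
                    continue
                f = sigma[m] / s
                if abs(f - 1.0) > 1e-12:
                    done = False
                mask = Bf[:, m] > 0
                c[mask] *= f
            if done:
                break
        BtB = Bf.T @ Bf
        for _ in range(5):
            r = Bf.T @ c - sigma
            if np.max(np.abs(r)) < 1e-10 * sig_norm:
                break
            c = np.maximum(c - Bf @ np.linalg.solve(BtB, r), 1e-12)
        return c

    sig_scale = max(1.0, float(np.max(np.abs(sigma)))) if basis.lam else 1.0
    c_scale = max(float(np.max(c_ref)), 1e-6)
    found: list[np.ndarray] = []
    for i in range(n_starts):
        # alternate two start distributions: multiplicative perturbations of
        # the reference, and reference-independent log-uniform draws — small
        # basins (e.g. the near-inactive state of a switch) are easy to miss
        # with perturbative starts alone
        if i % 2 == 0:
            x0 = project(c_ref * np.exp(rng.normal(0, 2.0, net.N)))
        else:
            x0 = project(10.0 ** rng.uniform(-4, 0, net.N) * c_scale)
        if basis.lam and np.max(np.abs(Bf.T @ x0 - sigma)) > 1e-8 * sig_scale:
            continue  # projection onto the class failed for this draw
        eq = relax_to_equilibrium(net, x0, k, B=basis)
        if eq is None:
            continue
        if basis.lam and np.max(np.abs(Bf.T @ eq - sigma)) > 1e-6 * sig_scale:
            continue  # polished onto a different compatibility class
        eigs = np.linalg.eigvals(reduced_jacobian(net, eq, k, basis.B))
        if np.max(eigs.real) > -STABILITY_THRESHOLD:
            continue  # keep stable equilibria only
        if not any(np.allclose(np.log(eq), np.log(f), atol=atol) for f in found):
            found.append(eq)
    return found


def detect_bistability(branch: EquilibriumBranch) -> BistabilityRegion | None:
    """Pair consecutive folds and verify the classic S-shape: two stable
    segments overlapping in parameter with an unstable segment in between."""
    if len(branch.limit_points) < 2:
        return None
    for a, b in zip(branch.limit_points, branch.limit_points[1:]):
        p_a, p_b = branch.points[a].p, branch.points[b].p
        p_lo, p_hi = min(p_a, p_b), max(p_a, p_b)
        if p_hi - p_lo <= 0:
            continue
        pm = 0.5 * (p_lo + p_hi)
        # segments: before fold a, between folds, after fold b
        segs = [branch.points[: a + 1], branch.points[a: b + 1], branch.points[b:]]
        picks = []
        for seg in segs:
            inside = [pt for pt in seg if p_lo < pt.p < p_hi]
            if not inside:
                picks.append(None)
                continue
            picks.append(min(inside, key=lambda pt: abs(pt.p - pm)))
        if any(pk is None for pk in picks):
            continue
        outer = [picks[0], picks[2]]
        stable = [pt for pt in outer if pt.stability == "stable"]
        if len(stable) == 2 and picks[1].stability == "unstable":
            lo_pt, hi_pt = stable
            return BistabilityRegion(p_lo, p_hi, lo_pt, hi_pt, picks[1])
    return None
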