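"""Injectivity-oriented saddle-node search for semi-diffusive networks.

A semi-diffusive network (every species degraded, one inflow per conserved
moiety of the true subsystem) has dynamics ``cdot = K + S_to v_to(c, k)``
with constant inflow ``K``.  With mass action the Jacobian factorizes as
``D_c f = S_to diag(v_to) Y_r^T diag(1/c)``.  Taking the steady-state fluxes
``mu`` of the true + outflow reactions as decision variables,

    Jbar(mu) = S_to diag(mu) Y_r^T,      pbar(mu) = -S_to mu,

and a positive flux vector with

* C.6  rank Jbar(mu) = N - 1   (via F_inj = det(Jbar)^2 = 0),
* C.7  pbar_i > 0 for key species, pbar_i = 0 otherwise,

certifies a saddle-node at the recovered steady state.  Setting ``c = 1``
recovers ``k_j = mu_j`` for the true + outflow reactions and the inflow
constants from ``pbar``.

The linear constraints ``pbar_i = 0`` (non-key species) intersected with
``mu >= 0`` form a polyhedral cone; its extreme rays are enumerated exactly
and the search runs over positive ray weights, which satisfies the equality
constraints identically and keeps every coordinate positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .cone import extreme_rays
from .network import SemiDiffusiveNetwork, matrix_rank
from .optimize import SearchOptions, latin_hypercube, sign_bisection

__all__ = [
    "p_of_fluxes",
    "flux_jacobian",
    "check_injectivity",
    "flux_cone_rays",
    "SaddleNodeCertificateInj",
    "InjectivitySearchResult",
    "search_inj",
    "recover_point",
]


def _require_semidiffusive(net) -> SemiDiffusiveNetwork:
    if not isinstance(net, SemiDiffusiveNetwork):
        raise TypeError("this operation requires a SemiDiffusiveNetwork (see make_semidiffusive)")
    return net


def p_of_fluxes(net: SemiDiffusiveNetwork, mu) -> np.ndarray:
    """Net consumption vector pbar(mu) = -S_to mu; equals the inflow K at steady state."""
    net = _require_semidiffusive(net)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (net.R_to,):
        raise ValueError(f"expected {net.R_to} fluxes, got {mu.shape}")
    return -net.S_to @ mu


def flux_jacobian(net: SemiDiffusiveNetwork, mu) -> np.ndarray:
    """Jbar(mu) = S_to diag(mu) Y_r^T; equals D_c f at c = 1 with v_to = mu."""
    net = _require_semidiffusive(net)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (net.R_to,):
        raise ValueError(f"expected {net.R_to} fluxes, got {mu.shape}")
    return (net.S_to * mu) @ net.Y_r.T


@dataclass
class InjectivityReport:
    n_trials: int
    n_positive: int
    n_negative: int
    n_zero: int
    sign_change: bool

    @property
    def injective_candidate(self) -> bool:
        """True when no sign change was found (heuristic; not a proof of injectivity)."""
        return not self.sign_change


def check_injectivity(net: SemiDiffusiveNetwork, trials: int = 200, seed: int = 0) -> InjectivityReport:
    """Sign survey of det Jbar(mu) over log-uniform positive flux samples.

    A sign change (or an exact zero) proves the network is not injective; a
    constant sign across all samples is only evidence of injectivity.
    """
    net = _require_semidiffusive(net)
    rng = np.random.default_rng(seed)
    n_pos = n_neg = n_zero = 0
    for _ in range(trials):
        mu = 10.0 ** rng.uniform(-3, 3, net.R_to)
        d = float(np.linalg.det(flux_jacobian(net, mu)))
        if d > 0:
            n_pos += 1
        elif d < 0:
            n_neg += 1
        else:
            n_zero += 1
    return InjectivityReport(trials, n_pos, n_neg, n_zero, sign_change=(n_pos > 0 and n_neg > 0) or n_zero > 0)


def flux_cone_rays(net: SemiDiffusiveNetwork) -> np.ndarray:
    """Extreme rays (rows) of the steady-state flux cone
    {mu >= 0 : (S_to mu)_i = 0 for every non-key species i}."""
    net = _require_semidiffusive(net)
    key = set(net.key_indices)
    E = net.S_to[[i for i in range(net.N) if i not in key], :]
    return extreme_rays(E.astype(object))


@dataclass
class SaddleNodeCertificateInj:
    """A certified saddle-node point of the injectivity-oriented search."""

    mu: np.ndarray
    c: np.ndarray
    k: dict[str, float]
    F_inj: float
    det_Jbar: float
    rank_Jbar: int
    pbar: np.ndarray
    species: tuple[str, ...]

    def summary(self) -> str:
        lines = ["Saddle-node certificate (injectivity route)", "-" * 44]
        lines.append(f"F_inj = det(Jbar)^2 = {self.F_inj:.3e}   (raw det = {self.det_Jbar:.3e})")
        lines.append(f"C.6 rank Jbar = {self.rank_Jbar} (target N-1 = {len(self.species) - 1})")
        lines.append("fluxes mu (true + outflow reactions):")
        lines.append("  " + np.array2string(self.mu, precision=6))
        lines.append("pbar components (inflow rates for key species, 0 otherwise):")
        for sp, p in zip(self.species, self.pbar):
            lines.append(f"  {sp}: {p:.6g}")
        lines.append("recovered steady state:")
        for sp, ci in zip(self.species, self.c):
            lines.append(f"  [{sp}] = {ci:.6g}")
        lines.append("recovered rate constants:")
        for lbl, kj in self.k.items():
            lines.append(f"  {lbl} = {kj:.6g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "method": "injectivity",
            "mu": [float(m) for m in self.mu],
            "c": {s: float(v) for s, v in zip(self.species, self.c)},
            "k": {l: float(v) for l, v in self.k.items()},
            "F_inj": self.F_inj,
            "det_Jbar": self.det_Jbar,
            "rank_Jbar": self.rank_Jbar,
            "pbar": [float(p) for p in self.pbar],
        }


@dataclass
class InjectivitySearchResult:
    found: bool
    certificate: SaddleNodeCertificateInj | None
    best_objective: float
    n_evals: int
    message: str = ""

    def summary(self) -> str:
        if self.found:
            return self.certificate.summary()
        return (
            "No saddle-node certificate found within the search budget "
            f"(best F_inj = {self.best_objective:.3e}, {self.n_evals} evaluations).\n"
            "Note: failure to find a certificate does not preclude multistationarity."
        )


def recover_point(
    net: SemiDiffusiveNetwork, mu, c_target=None
) -> tuple[np.ndarray, dict[str, float]]:
    """Recover (c, k) from certified fluxes.

    By default the steady state is placed at ``c = 1`` so that
    ``k_j = mu_j`` for true + outflow reactions; for an arbitrary positive
    target ``c*`` the scaling ``k_j = mu_j / psi_source(j)(c*)`` places the
    same fluxes at ``c*``.  Inflow constants are the key-species components of
    ``pbar``.  The steady-state residual is verified before returning.
    """
    net = _require_semidiffusive(net)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("fluxes must be strictly positive")
    c = np.ones(net.N) if c_target is None else np.asarray(c_target, dtype=float)
    if np.any(c <= 0):
        raise ValueError("target steady state must be strictly positive")
    psi = kinetics.monomials(net, c)
    pbar = p_of_fluxes(net, mu)
    k: dict[str, float] = {}
    for pos, j in enumerate(net.to_indices):
        r = net.reactions[j]
        k[r.label] = float(mu[pos] / psi[r.source])
    for j in net.inflow_indices:
        r = net.reactions[j]
        target_species = net.complexes[r.product][0][0]
        k[r.label] = float(pbar[net.species_index(target_species)])
        if k[r.label] <= 0:
            raise ValueError(f"nonpositive inflow constant recovered for {target_species}")
    resid = kinetics.rhs(net, c, k)
    if np.linalg.norm(resid) > 1e-8 * max(1.0, float(np.max(mu))):
        raise ValueError(f"recovered point violates the steady state (|f| = {np.linalg.norm(resid):.2e})")
    return c, k


def search_inj(
    net: SemiDiffusiveNetwork,
    bounds: tuple[float, float] | None = None,
    options: SearchOptions | None = None,
    *,
    fixed_mu: dict[int, float] | None = None,
) -> InjectivitySearchResult:
    """Search for a saddle-node certificate by the injectivity-oriented route.

    Decision variables are log weights of the flux-cone extreme rays, which
    satisfy the non-key equality constraints of ``pbar`` exactly and keep
    ``mu > 0``.  det Jbar is evaluated on Latin-hypercube samples; a pair of
    opposite signs brackets a zero which Brent refinement pins down, after
    which C.6 and C.7 are verified.
    """
    net = _require_semidiffusive(net)
    options = options or SearchOptions()
    mu_lo, mu_hi = bounds or (1e-3, 1e3)
    if mu_lo <= 0:
        raise ValueError("flux lower bound must be positive")

    rays = flux_cone_rays(net)
    if rays.shape[0] == 0 or np.any(rays.sum(axis=0) == 0):
        raise ValueError(
            "no strictly positive flux vector satisfies the pbar constraints; "
            "the key-species set is incompatible with a positive steady state (A.2)"
        )
    rays_f = rays.astype(float)
    # normalize each ray to unit max so weights map to flux magnitudes
    rays_f /= rays_f.max(axis=1, keepdims=True)
    n_w = rays_f.shape[0]

    key = np.array(net.inflow_pattern(), dtype=bool)
    n_evals = 0
    best = np.inf

    def mu_of(w_log):
        return rays_f.T @ (10.0 ** w_log)

    def signed_det(w_log):
        nonlocal n_evals, best
        n_evals += 1
        Jbar = flux_jacobian(net, mu_of(w_log))
        scale = np.max(np.abs(Jbar), axis=1)
        scale[scale == 0] = 1.0
        d_eq = float(np.linalg.det(Jbar / scale[:, None]))
        best = min(best, d_eq ** 2)
        return d_eq

    def certify(w_log) -> SaddleNodeCertificateInj | None:
        mu = mu_of(w_log)
        if fixed_mu:
            # the saddle-node conditions are homogeneous in mu (det Jbar scales
            # as t^N, pbar as t), so one pinned flux is honored by rescaling
            items = sorted(fixed_mu.items())
            idx0, val0 = items[0]
            t = val0 / mu[idx0]
            if t <= 0:
                return None
            mu = t * mu
            for idx, val in items[1:]:
                if abs(mu[idx] - val) > 1e-8 * max(1.0, abs(val)):
                    return None
        if np.any(mu <= 0) or np.any(mu < mu_lo / 1e6) or np.any(mu > mu_hi * 1e6):
            return None
        Jbar = flux_jacobian(net, mu)
        scale = np.max(np.abs(Jbar), axis=1)
        scale[scale == 0] = 1.0
        det_eq = float(np.linalg.det(Jbar / scale[:, None]))
        if det_eq ** 2 > options.tol:
            return None
        if matrix_rank(Jbar) != net.N - 1:
            return None
        pbar = p_of_fluxes(net, mu)
        if np.any(pbar[key] <= 0):
            return None
        if np.any(np.abs(pbar[~key]) > 1e-9 * max(1.0, float(np.max(mu)))):
            return None
        c, k = recover_point(net, mu)
        return SaddleNodeCertificateInj(
            mu=mu,
            c=c,
            k=k,
            F_inj=det_eq ** 2,
            det_Jbar=float(np.linalg.det(Jbar)),
            rank_Jbar=matrix_rank(Jbar),
            pbar=pbar,
            species=net.species,
        )

    rng = np.random.default_rng(options.seed)
    lo, hi = np.log10(mu_lo), np.log10(mu_hi)
    box = [(lo, hi)] * n_w
    # det sign changes can be rare events in flux space; determinant samples
    # are cheap, so explore densely before bracketing
    X = latin_hypercube(rng, max(150 * options.multistarts, 300), box)
    evals = []
    for x in X:
        if n_evals >= options.budget:
            break
        mu = mu_of(x)
        if np.any(p_of_fluxes(net, mu)[key] <= 0):
            continue
        d = signed_det(x)
        if np.isfinite(d):
            evals.append((d, x))

    pos = sorted([e for e in evals if e[0] > 0], key=lambda t: t[0])
    neg = sorted([e for e in evals if e[0] < 0], key=lambda t: -t[0])
    attempts = 0
    for dp, xp in pos:
        for dn, xn in neg:
            if attempts >= options.multistarts or n_evals >= options.budget:
                break
            attempts += 1
            root = sign_bisection(signed_det, xp, xn)
            if root is None:
                continue
            cert = certify(root)
            if cert is not None:
                return InjectivitySearchResult(True, cert, cert.F_inj, n_evals)
        if attempts >= options.multistarts or n_evals >= options.budget:
            break

    return InjectivitySearchResult(
        False,
        None,
        best,
        n_evals,
        message="no sign change of det(Jbar) located" if not (pos and neg) else "bisection did not certify",
    )
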