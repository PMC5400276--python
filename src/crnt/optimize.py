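"""Seeded derivative-free global search used by both saddle-node routes.

The saddle-node objectives are squared determinants: smooth, highly
multi-modal, and with zero as the known global optimum whenever a saddle-node
exists.  The strategy is a Latin-hypercube multistart with Nelder-Mead
polishing, plus a root-bracketing accelerator (`sign_bisection`) that the
search routes use when the objective exposes a *signed* quantity whose zero
is sought: two samples of opposite sign bracket a zero along the connecting
segment, and Brent's method drives it to machine precision.

Everything is deterministic given the seed: same seed, same evaluation
sequence, same result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize as sopt
from scipy.stats import qmc

__all__ = ["SearchOptions", "MinimizeResult", "minimize", "latin_hypercube", "sign_bisection"]


@dataclass
class SearchOptions:
    seed: int = 0
    multistarts: int = 10
    local_polish: str = "Nelder-Mead"
    tol: float = 1e-16
    budget: int = 20000  # max objective evaluations
    polish_maxiter: int = 400

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.multistarts < 1:
            raise ValueError("multistarts must be >= 1")


@dataclass
class MinimizeResult:
    x: np.ndarray
    fun: float
    n_evals: int
    accepted: bool
    trace: list = field(default_factory=list)  # monotone best-so-far (n_evals, best)


def _validate_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    if np.any(lo >= hi):
        raise ValueError("bounds must satisfy low < high")
    return lo, hi


def latin_hypercube(rng: np.random.Generator, n: int, bounds) -> np.ndarray:
    """n seeded Latin-hypercube samples in the given box (rows are points)."""
    lo, hi = _validate_bounds(bounds)
    sampler = qmc.LatinHypercube(d=len(lo), seed=rng)
    u = sampler.random(n)
    return lo + u * (hi - lo)


def minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    options: SearchOptions | None = None,
) -> MinimizeResult:
    """Multistart box-constrained minimization, deterministic given the seed.

    Latin-hypercube exploration followed by Nelder-Mead polishing of the most
    promising starts, all within the evaluation budget.  Returns the best
    point, its value, the evaluation count and the monotone best-so-far trace;
    ``accepted`` is True when the best value reached ``options.tol``.
    """
    options = options or SearchOptions()
    lo, hi = _validate_bounds(bounds)
    rng = np.random.default_rng(options.seed)

    n_evals = 0
    best_x, best_f = None, np.inf
    trace: list[tuple[int, float]] = []

    def f(x) -> float:
        nonlocal n_evals, best_x, best_f
        n_evals += 1
        val = float(objective(np.clip(x, lo, hi)))
        if val < best_f:
            best_f = val
            best_x = np.array(x, dtype=float)
            trace.append((n_evals, val))
        return val

    n_explore = max(options.multistarts * 4, 8)
    X = latin_hypercube(rng, n_explore, bounds)
    vals = []
    for x in X:
        if n_evals >= options.budget:
            break
        vals.append((f(x), tuple(x)))
    vals.sort(key=lambda t: t[0])

    for _, x0 in vals[: options.multistarts]:
        if best_f <= options.tol or n_evals >= options.budget:
            break
        remaining = options.budget - n_evals
        if options.local_polish == "Nelder-Mead":
            polish_opts = {"maxfev": min(options.polish_maxiter, remaining),
                           "xatol": 1e-12, "fatol": 1e-18}
        else:
            polish_opts = {"maxiter": min(options.polish_maxiter, remaining)}
        sopt.minimize(f, np.array(x0), method=options.local_polish, options=polish_opts)

    if best_f > options.tol and n_evals < options.budget and best_x is not None:
        # final derivative-free polish around the incumbent
        sopt.minimize(
            f, best_x, method="Powell",
            options={"maxfev": min(2 * options.polish_maxiter, options.budget - n_evals),
                     "xtol": 1e-14, "ftol": 1e-16},
        )

    return MinimizeResult(
        x=best_x if best_x is not None else (lo + hi) / 2,
        fun=best_f,
        n_evals=n_evals,
        accepted=best_f <= options.tol,
        trace=trace,
    )


def sign_bisection(
    signed: Callable[[np.ndarray], float],
    x_pos: np.ndarray,
    x_neg: np.ndarray,
    *,
    xtol: float = 1e-15,
) -> np.ndarray | None:
    """Locate a zero of a signed scalar field along the segment [x_neg, x_pos].

    ``signed`` must be continuous along the segment (NaN returns abort the
    bracket).  Returns the zero-crossing point or None.
    """
    x_pos = np.asarray(x_pos, dtype=float)
    x_neg = np.asarray(x_neg, dtype=float)

    def g(t: float) -> float:
        return signed((1 - t) * x_neg + t * x_pos)

    g0, g1 = g(0.0), g(1.0)
    if not (np.isfinite(g0) and np.isfinite(g1)) or g0 * g1 > 0:
        return None
    try:
        t = sopt.brentq(g, 0.0, 1.0, xtol=xtol, maxiter=200)
    except (ValueError, RuntimeError):
        return None
    return (1 - t) * x_neg + t * x_pos
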