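"""Mass-action kinetics: rates, monomials, the kinetic matrix and Jacobians.

Two equivalent ODE formulations are provided for a network with molecularity
matrix ``Y``, stoichiometric matrix ``S`` and rate constants ``k``:

* the species form ``cdot = S v(c, k)`` with ``v_j = k_j prod_i c_i^{alpha_ij}``,
* the complex form ``cdot = Y A psi(c)`` with monomials
  ``psi_j(c) = prod_i c_i^{Y_ij}`` and the kinetic matrix ``A`` whose
  off-diagonal entry (i, j) collects the constants of reactions C_j -> C_i
  and whose diagonal holds the negated outgoing sums.

For semi-diffusive networks the mass-action Jacobian factorizes as
``D_c f = S_to diag(v_to) Y_r^T diag(1/c)``; the same factorization holds for
any mass-action network with ``S`` and the source-complex matrix of all
reactions, which is what :func:`jacobian` uses.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .network import ReactionNetwork, SemiDiffusiveNetwork

__all__ = [
    "rate_constants_vector",
    "monomials",
    "source_selector",
    "kinetic_matrix",
    "rates",
    "rhs",
    "rhs_complex_form",
    "jacobian",
    "pair_label",
]


def rate_constants_vector(net: ReactionNetwork, k: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Per-reaction constants as an array in reaction order.

    ``k`` may be a mapping from rate labels (or complex-pair labels, see
    :func:`pair_label`) to positive values, or a sequence in reaction order.
    """
    if isinstance(k, Mapping):
        out = np.empty(net.R)
        for j, r in enumerate(net.reactions):
            if r.label in k:
                out[j] = k[r.label]
            else:
                pl = pair_label(net, j)
                if pl in k:
                    out[j] = k[pl]
                else:
                    raise KeyError(f"missing rate constant for reaction {r.label!r} ({pl})")
    else:
        out = np.asarray(k, dtype=float)
        if out.shape != (net.R,):
            raise ValueError(f"expected {net.R} rate constants, got {out.shape}")
    if np.any(out <= 0):
        raise ValueError("rate constants must be strictly positive")
    return out.astype(float)


def pair_label(net: ReactionNetwork, j: int) -> str:
    """Complex-pair label ``k{source}{product}`` (1-based) of reaction j."""
    r = net.reactions[j]
    return f"k{r.source + 1}_{r.product + 1}"


def _check_positive(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    return c


def monomials(net: ReactionNetwork, c: Sequence[float], *, guard: bool = True) -> np.ndarray:
    """Mass-action monomial vector psi(c), psi_j = prod_i c_i^{Y_ij}.

    The zero complex has the empty product psi = 1.  With ``guard=False`` the
    continuous extension 0**0 = 1 is used and zero entries are allowed.
    """
    c = _check_positive(c) if guard else np.asarray(c, dtype=float)
    Y = net.Y
    with np.errstate(divide="ignore"):
        psi = np.prod(np.power(c[:, None], Y), axis=0)
    return psi


def source_selector(net: ReactionNetwork) -> np.ndarray:
    """R x M 0/1 matrix U selecting each reaction's source complex."""
    U = np.zeros((net.R, net.M), dtype=int)
    for j, r in enumerate(net.reactions):
        U[j, r.source] = 1
    return U


def kinetic_matrix(net: ReactionNetwork, k) -> np.ndarray:
    """M x M kinetic matrix A: A[i, j] = sum of constants of reactions C_j -> C_i,
    A[j, j] = -(sum of constants of reactions leaving C_j)."""
    kv = rate_constants_vector(net, k)
    A = np.zeros((net.M, net.M))
    for j, r in enumerate(net.reactions):
        A[r.product, r.source] += kv[j]
        A[r.source, r.source] -= kv[j]
    return A


def rates(net: ReactionNetwork, c, k) -> np.ndarray:
    """Reaction-rate vector v(c, k) = diag(k) U psi(c)."""
    kv = rate_constants_vector(net, k)
    psi = monomials(net, c)
    return kv * psi[net.source_indices]


def rhs(net: ReactionNetwork, c, k) -> np.ndarray:
    """Right-hand side cdot = S v(c, k) (species formulation)."""
    return net.S @ rates(net, c, k)


def rhs_complex_form(net: ReactionNetwork, c, k) -> np.ndarray:
    """Right-hand side cdot = Y A psi(c) (complex formulation); identical to
    :func:`rhs` for every mass-action network."""
    return net.Y @ (kinetic_matrix(net, k) @ monomials(net, c))


def jacobian(net: ReactionNetwork, c, k) -> np.ndarray:
    """Analytic mass-action Jacobian D_c f = S diag(v) Y_src^T diag(1/c).

    ``Y_src`` holds the source-complex molecularities of all reactions.  For a
    semi-diffusive network the inflow reactions contribute zero columns (their
    source is the zero complex), so this reduces to the factorized form
    ``S_to diag(v_to) Y_r^T diag(1/c)``.
    """
    c = _check_positive(c)
    v = rates(net, c, k)
    Ysrc = net.Y[:, net.source_indices]  # N x R
    return (net.S * v) @ (Ysrc.T / c)


def semidiffusive_inflow(net: SemiDiffusiveNetwork, k) -> np.ndarray:
    """Constant inflow vector K of a semi-diffusive network (rates of the
    inflow pseudo-reactions, one per key species)."""
    kv = rate_constants_vector(net, k)
    K = np.zeros(net.N)
    Y = net.Y
    for j in net.inflow_indices:
        K += Y[:, net.reactions[j].product] * kv[j]
    return K
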