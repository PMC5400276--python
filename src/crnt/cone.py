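"""Exact extreme-ray enumeration for pointed polyhedral cones in the nonnegative orthant.

Used for two geometric problems that arise in reaction-network analysis:

* conserved-moiety bases: extreme rays of ``{b >= 0 : S^T b = 0}`` (the
  semi-positive left nullspace of the stoichiometric matrix), and
* steady-state flux cones of semi-diffusive networks: extreme rays of
  ``{mu >= 0 : E mu = 0}`` for the sub-stoichiometry ``E`` of species whose
  net production must vanish.

Both cones are intersections of the nonnegative orthant with a linear
subspace, hence pointed, so the double-description method starting from the
orthant's generators applies directly.  All arithmetic is integer (inputs are
integer matrices); rays are returned as primitive integer vectors.
"""

from __future__ import annotations

from math import gcd

import numpy as np

__all__ = ["extreme_rays", "nonnegative_nullspace_rays"]


def _primitive(v: np.ndarray) -> np.ndarray:
    g = 0
    for x in v:
        g = gcd(g, int(abs(x)))
    return v // g if g > 1 else v


def extreme_rays(eq: np.ndarray) -> np.ndarray:
    """Extreme rays of the cone ``{x >= 0 : eq @ x = 0}``.

    Parameters
    ----------
    eq : integer array, shape (m, n)
        Equality constraints.

    Returns
    -------
    integer array, shape (n_rays, n)
        One primitive integer generator per extreme ray (possibly zero rows
        returned as an empty array when the cone is trivial).
    """
    eq = np.asarray(eq, dtype=object)
    if eq.ndim != 2:
        raise ValueError("equality matrix must be 2-D")
    m, n = eq.shape
    # start from the nonnegative orthant: rays = standard basis
    rays = [np.array([1 if j == i else 0 for j in range(n)], dtype=object) for i in range(n)]
    # zero sets over the n sign constraints x_i >= 0
    zsets = [frozenset(j for j in range(n) if j != i) for i in range(n)]

    for row in range(m):
        a = eq[row]
        vals = [int(sum(a[j] * r[j] for j in range(n))) for r in rays]
        keep = [i for i, v in enumerate(vals) if v == 0]
        pos = [i for i, v in enumerate(vals) if v > 0]
        neg = [i for i, v in enumerate(vals) if v < 0]
        new_rays = [rays[i] for i in keep]
        new_zsets = [zsets[i] for i in keep]
        for ip in pos:
            for im in neg:
                z = zsets[ip] & zsets[im]
                # combinatorial adjacency test: no third ray's zero set contains z
                adjacent = True
                for iq in range(len(rays)):
                    if iq in (ip, im):
                        continue
                    if z <= zsets[iq]:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                r = vals[ip] * rays[im] - vals[im] * rays[ip]
                r = _primitive(r)
                new_rays.append(r)
                new_zsets.append(frozenset(j for j in range(n) if r[j] == 0))
        rays, zsets = new_rays, new_zsets

    if not rays:
        return np.zeros((0, n), dtype=int)
    out = np.array([[int(x) for x in r] for r in rays], dtype=int)
    # deterministic order: lexicographic by coordinates
    order = np.lexsort(out.T[::-1])
    return out[order]


def nonnegative_nullspace_rays(S: np.ndarray) -> np.ndarray:
    """Extreme rays of ``{b >= 0 : S^T b = 0}`` for integer ``S`` (N x R)."""
    S = np.asarray(S)
    return extreme_rays(S.T.astype(object))
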