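"""Independent numerical oracles, deliberately implemented along different
routes than the package code they validate.

* :func:`fd_release` solves the radial diffusion PDE directly with a
  Crank-Nicolson finite-difference scheme (the package uses the
  eigenfunction series).
* :func:`bisect_j0_roots` brackets and bisects J0 sign changes (the
  package delegates to scipy's Bessel-zero routine).
* :func:`permuted_cells` enumerates axis relabelings of a unit cell
  (the package relies on Niggli canonicalization).
* :func:`brute_force_candidates` re-derives the Raman candidate set by
  plain enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg, special


def fd_release(
    tau_checkpoints: list[float], eta: float = math.inf, n_r: int = 800
) -> dict[float, float]:
    """Released fraction from a Crank-Nicolson solve of the cylinder PDE.

    Dimensionless form on r in [0, 1]: u_t = u_rr + u_r / r, u(r,0)=1,
    with u(1)=0 (eta infinite) or -u_r(1) = eta u(1).  Time steps grow
    geometrically from 1e-8 to resolve the initial boundary layer.
    Returns {tau: w} via the mass balance w = 1 - 2 * int u r dr.
    """
    dr = 1.0 / n_r
    r = np.linspace(0.0, 1.0, n_r + 1)
    u = np.ones(n_r + 1)

    lo = np.zeros(n_r + 1)
    di = np.zeros(n_r + 1)
    up = np.zeros(n_r + 1)
    # axis r=0 by symmetry: u_t = 4 (u_1 - u_0) / dr^2
    di[0], up[0] = -4.0 / dr**2, 4.0 / dr**2
    i = np.arange(1, n_r)
    lo[i] = (1.0 - 0.5 / i) / dr**2
    di[i] = -2.0 / dr**2
    up[i] = (1.0 + 0.5 / i) / dr**2
    dirichlet = math.isinf(eta)
    if dirichlet:
        u[-1] = 0.0
    else:
        # ghost node from -u_r(1) = eta u(1):
        # u_{N+1} = u_{N-1} - 2 dr eta u_N, then the radial Laplacian at r=1
        lo[n_r] = 2.0 / dr**2
        di[n_r] = -2.0 / dr**2 - 2.0 * eta / dr - eta

    res: dict[float, float] = {}
    tau = 0.0
    checkpoints = sorted(tau_checkpoints)
    ab = np.zeros((3, n_r + 1))
    for target in checkpoints:
        while tau < target - 1e-15:
            dt = min(max(1e-8, tau * 1e-3), target - tau)
            ab[0, 1:] = -dt / 2 * up[:-1]
            ab[1, :] = 1.0 - dt / 2 * di
            ab[2, :-1] = -dt / 2 * lo[1:]
            rhs = u + dt / 2 * (
                np.r_[0.0, lo[1:] * u[:-1]] + di * u + np.r_[up[:-1] * u[1:], 0.0]
            )
            if dirichlet:
                ab[1, -1], ab[2, -2], rhs[-1] = 1.0, 0.0, 0.0
            u = linalg.solve_banded((1, 1), ab, rhs)
            tau += dt
        res[target] = float(1.0 - 2.0 * np.trapezoid(u * r, r))
    return res


def bisect_j0_roots(n: int, tol: float = 1e-12) -> np.ndarray:
    """First n zeros of J0 by plain bracketing + bisection."""
    roots = []
    lo = 0.5
    while len(roots) < n:
        hi = lo + 0.5
        while special.j0(lo) * special.j0(hi) > 0:
            lo, hi = hi, hi + 0.5
        a, b = lo, hi
        while b - a > tol:
            mid = 0.5 * (a + b)
            if special.j0(a) * special.j0(mid) <= 0:
                b = mid
            else:
                a = mid
        roots.append(0.5 * (a + b))
        lo = b
    return np.array(roots)


# the 48 signed axis permutations that relabel a right-handed cell;
# only parameter-level relabelings (a,b,c cyclic/swap with matching angles)
# are enumerable without a full basis transform, which is all that is
# needed to probe labeling invariance.
_PERMS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def permuted_cells(params: tuple[float, ...]) -> list[tuple[float, ...]]:
    """All axis relabelings (a,b,c with matching angle moves) of one cell."""
    lengths = params[:3]
    angles = params[3:]
    out = []
    for p in _PERMS:
        out.append(tuple(lengths[i] for i in p) + tuple(angles[i] for i in p))
    return out


def brute_force_candidates(
    nu: float, refs: list[tuple[str, tuple[float, ...]]], tol: float
) -> set[str]:
    """Candidate polymorphs by plain enumeration over every reference peak."""
    out = set()
    for pid, positions in refs:
        for p in positions:
            if abs(nu - p) <= tol:
                out.add(pid)
    return out
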