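"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the conjugate update
is checked against brute-force numerical integration of the unnormalized
Normal/Inverse-Gamma posterior on a (beta, sigma^2) grid, and neighbor
search is checked against an all-pairs O(n^2) distance scan.
"""

from __future__ import annotations

import numpy as np


def grid_nig_moments(
    x: np.ndarray,
    y: np.ndarray,
    a0: float,
    b0: float,
    mu0: float,
    lambda0: float,
    beta_grid: np.ndarray | None = None,
    s2_grid: np.ndarray | None = None,
) -> dict:
    """Posterior moments for p=1 by quadrature of the unnormalized density.

    The joint unnormalized posterior is

        prior NIG(beta, s2 | mu0, lambda0, a0, b0) * prod_i N(y_i | x_i b, s2)

    integrated on a dense (beta, log s2) grid. Returns moments from which
    the closed-form hyperparameters can be recovered:

        mun     = E[beta]
        an, bn  from E[1/s2] = an/bn and E[1/s2^2] = an(an+1)/bn^2
        lambdan from E[(beta - mun)^2 / s2] = 1/lambdan
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    if beta_grid is None:
        beta_grid = np.linspace(-40.0, 40.0, 4001)
    if s2_grid is None:
        s2_grid = np.exp(np.linspace(np.log(1e-4), np.log(1e5), 4001))

    B, S = np.meshgrid(beta_grid, s2_grid, indexing="ij")
    # log NIG prior: s2^{-(a0+1)} e^{-b0/s2} * N(beta | mu0, s2/lambda0)
    logp = (
        -(a0 + 1.0) * np.log(S)
        - b0 / S
        - 0.5 * np.log(S / lambda0)
        - 0.5 * lambda0 * (B - mu0) ** 2 / S
    )
    for xi, yi in zip(x, y):
        logp += -0.5 * np.log(S) - 0.5 * (yi - xi * B) ** 2 / S
    logp -= logp.max()
    w = np.exp(logp)
    # trapezoid weights on both axes (log-spaced in s2)
    wb = np.gradient(beta_grid)
    ws = np.gradient(s2_grid)
    w = w * wb[:, None] * ws[None, :]
    Z = w.sum()

    e_beta = (w * B).sum() / Z
    e_inv_s2 = (w / S).sum() / Z
    e_inv_s2_sq = (w / S**2).sum() / Z
    e_quad = (w * (B - e_beta) ** 2 / S).sum() / Z
    var_inv = e_inv_s2_sq - e_inv_s2**2
    an = e_inv_s2**2 / var_inv
    bn = an / e_inv_s2
    return {
        "mun": e_beta,
        "an": an,
        "bn": bn,
        "lambdan": 1.0 / e_quad,
        "var_beta": (w * (B - e_beta) ** 2).sum() / Z,
    }


def brute_force_neighbors(coords: np.ndarray, comp_dist: float) -> set[tuple[int, int]]:
    """All-pairs scan: index pairs (i < j) with squared distance <= comp_dist^2."""
    n = len(coords)
    r2 = comp_dist * comp_dist
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (coords[i, 0] - coords[j, 0]) ** 2 + (coords[i, 1] - coords[j, 1]) ** 2
            if d2 <= r2:
                out.add((i, j))
    return out


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via the normal equations (the flat-prior limit)."""
    return np.linalg.solve(X.T @ X, X.T @ y)
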