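"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations — flood fill instead of labelled
morphology, textbook IRLS instead of the quadrature GLMM, direct
quadrature of the marginal probability — so the package code is checked
against a second route, not against itself.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def flood_fill_components(mask: np.ndarray) -> list[np.ndarray]:
    """Connected components (8-neighbour) of a boolean image by BFS.

    Returns a list of (n_i, 2) coordinate arrays, one per component.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            coords = []
            while stack:
                y, x = stack.pop()
                coords.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(np.array(coords))
    return comps


def second_moment_anisotropy(coords: np.ndarray) -> float:
    """1 - lambda_min/lambda_max of the coordinate covariance matrix."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    ev = np.linalg.eigvalsh(cov)
    if ev[-1] <= 0:
        return 0.0
    return 1.0 - ev[0] / ev[-1]


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Plain logistic regression by iteratively reweighted least squares."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / W
        beta_new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
        if np.abs(beta_new - beta).max() < tol:
            return beta_new
        beta = beta_new
    return beta


def marginal_bernoulli_prob(eta: float, sigma: float, n_nodes: int = 201) -> float:
    """E_b[logistic(eta + b)], b ~ N(0, sigma^2), by dense trapezoid
    quadrature over +-8 sigma."""
    if sigma == 0:
        return float(expit(eta))
    b = np.linspace(-8 * sigma, 8 * sigma, n_nodes)
    phi = np.exp(-0.5 * (b / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return float(np.trapezoid(expit(eta + b) * phi, b))
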