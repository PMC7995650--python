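"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package: connected components by breadth-first
flood fill, OLS by explicit normal equations, per-term F by the general
linear hypothesis formula.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def bfs_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, list[int]]:
    """Flood-fill connected-component labeling, IDs in scan order."""
    mask = np.asarray(mask, dtype=bool)
    offs = neighbour_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    sizes: list[int] = []
    nid = 0
    for idx in np.argwhere(mask):
        start = tuple(idx)
        if labels[start]:
            continue
        nid += 1
        labels[start] = nid
        queue = deque([start])
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for off in offs:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if not all(0 <= nb[k] < mask.shape[k] for k in range(3)):
                    continue
                if mask[nb] and not labels[nb]:
                    labels[nb] = nid
                    queue.append(nb)
        sizes.append(size)
    return labels, sizes


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """beta and SE from the explicit (X'X)^-1 X'y solve (LU, pivoting)."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    mse = float(resid @ resid) / dof
    cov = mse * np.linalg.inv(xtx)
    return beta, np.sqrt(np.diag(cov))


def glh_term_f(X: np.ndarray, y: np.ndarray, col: int) -> float:
    """Type III F for one column via the general-linear-hypothesis formula.

    F = (L beta)' [L (X'X)^-1 L']^-1 (L beta) / (q * mse) with L selecting
    ``col``; algebraically the full-vs-reduced sum-of-squares comparison.
    """
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    mse = float(resid @ resid) / dof
    return float(beta[col] ** 2 / (xtx_inv[col, col] * mse))
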