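"""Independent brute-force oracles for single-division slack-based scores.

Used only to cross-check the LP implementation on tiny instances (n <= 3,
one division, no links, no undesirable outputs).  Two routes, neither of
which touches the package's solver:

* ``grid_score``: exhaustive grid search over the intensity simplex (VRS)
  or an axis-aligned box (CRS), slacks computed in closed form from the
  constraints at every grid point.
* ``vertex_score``: exact enumeration of every basic feasible point of the
  small polytope in intensity space (all active-constraint subsets), which
  contains an optimum because the objective is linear.
"""

from __future__ import annotations

import itertools

import numpy as np


def simplex_grid(n: int, steps: int) -> np.ndarray:
    """All points of the regular grid on the (n-1)-simplex, shape (G, n)."""
    if n == 1:
        return np.ones((1, 1))
    if n == 2:
        a = np.arange(steps + 1) / steps
        return np.stack([a, 1.0 - a], axis=1)
    if n == 3:
        i, j = np.meshgrid(
            np.arange(steps + 1), np.arange(steps + 1), indexing="ij"
        )
        keep = (i + j) <= steps
        i, j = i[keep], j[keep]
        return np.stack([i, j, steps - i - j], axis=1) / steps
    raise NotImplementedError("oracle supports n <= 3")


def _objective(lam: np.ndarray, X, V, x_o, v_o, orientation):
    """Feasible mask and objective values for a batch of intensity vectors."""
    in_proj = lam @ X  # (G, m)
    out_proj = lam @ V  # (G, r)
    tol = 1e-9
    feas = (
        np.all(lam >= -tol, axis=1)
        & np.all(in_proj <= x_o * (1 + tol) + tol, axis=1)
        & np.all(out_proj >= v_o * (1 - tol) - tol, axis=1)
    )
    if orientation == "input_oriented":
        obj = np.mean(np.maximum(x_o - in_proj, 0.0) / x_o, axis=1)
    else:
        obj = np.mean(np.maximum(out_proj - v_o, 0.0) / v_o, axis=1)
    return feas, obj


def _score(orientation: str, opt: float) -> float:
    return 1.0 - opt if orientation == "input_oriented" else 1.0 / (1.0 + opt)


def grid_score(
    X: np.ndarray,
    V: np.ndarray,
    o: int,
    orientation: str = "input_oriented",
    rts: str = "vrs",
    resolution: float = 1e-3,
) -> float:
    """Grid-search slack-based score; X is (n, m), V is (n, r), rows = DMUs."""
    n = X.shape[0]
    x_o, v_o = X[o], V[o]
    if rts == "vrs":
        lam = simplex_grid(n, int(round(1.0 / resolution)))
    else:
        # box grid: lambda_j <= min_i x_o[i] / X[j, i] keeps inputs feasible
        ub = np.min(x_o / X, axis=1)
        steps = {1: 100_000, 2: 1_000, 3: 100}[n]
        axes = [np.linspace(0.0, u, steps + 1) for u in ub]
        lam = np.stack(
            np.meshgrid(*axes, indexing="ij"), axis=-1
        ).reshape(-1, n)
    feas, obj = _objective(lam, X, V, x_o, v_o, orientation)
    assert feas.any(), "self-benchmark must be feasible"
    return _score(orientation, float(obj[feas].max()))


def vertex_score(
    X: np.ndarray,
    V: np.ndarray,
    o: int,
    orientation: str = "input_oriented",
    rts: str = "vrs",
) -> float:
    """Exact score by enumerating all basic feasible intensity vectors."""
    n = X.shape[0]
    x_o, v_o = X[o], V[o]
    # inequality rows A lam <= b:  X^T lam <= x_o, -V^T lam <= -v_o, -lam <= 0
    A = np.vstack([X.T, -V.T, -np.eye(n)])
    b = np.concatenate([x_o, -v_o, np.zeros(n)])
    candidates = []
    if rts == "vrs":
        eq = np.ones((1, n))
        for rows in itertools.combinations(range(len(A)), n - 1):
            M = np.vstack([eq, A[list(rows)]])
            rhs = np.concatenate([[1.0], b[list(rows)]])
            try:
                lam = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                continue
            candidates.append(lam)
    else:
        for rows in itertools.combinations(range(len(A)), n):
            M = A[list(rows)]
            rhs = b[list(rows)]
            try:
                lam = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                continue
            candidates.append(lam)
    lam = np.array(candidates) if candidates else np.zeros((0, n))
    feas, obj = _objective(lam, X, V, x_o, v_o, orientation)
    assert feas.any(), "no feasible vertex found"
    return _score(orientation, float(obj[feas].max()))
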