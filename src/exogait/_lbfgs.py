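"""Limited-memory BFGS Hessian approximation for the trust-region solver.

SciPy's dense BFGS update costs O(n^2) per iteration and per matrix-vector
product, which dominates solve time for collocation NLPs with thousands of
variables.  This drop-in :class:`HessianUpdateStrategy` keeps the last ``m``
curvature pairs and applies the compact representation

    B = gamma*I - W M^-1 W^T,   W = [gamma*S, Y],
    M = [[gamma*S^T S, L], [L^T, -D]]

(L strictly lower triangular of S^T Y, D its diagonal), so products cost
O(m n) instead of O(n^2).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import HessianUpdateStrategy


class LBFGSHessian(HessianUpdateStrategy):
    """Compact limited-memory BFGS approximation of the objective Hessian."""

    def __init__(self, memory: int = 30):
        self.memory = memory
        self._s: list[np.ndarray] = []
        self._y: list[np.ndarray] = []
        self.gamma = 1.0
        self.n = None
        self._factors = None

    def initialize(self, n, approx_type):
        if approx_type != "hess":
            raise ValueError("LBFGSHessian approximates the Hessian only")
        self.n = n
        self.approx_type = approx_type
        self._s.clear()
        self._y.clear()
        self.gamma = 1.0
        self._factors = None

    def update(self, delta_x, delta_grad):
        sy = float(delta_x @ delta_grad)
        # curvature safeguard (skip update), as in damped quasi-Newton practice
        if sy <= 1e-10 * np.linalg.norm(delta_x) * np.linalg.norm(delta_grad):
            return
        self._s.append(np.array(delta_x, dtype=float))
        self._y.append(np.array(delta_grad, dtype=float))
        if len(self._s) > self.memory:
            self._s.pop(0)
            self._y.pop(0)
        self.gamma = float(self._y[-1] @ self._y[-1]) / sy
        self._refactor()

    def _refactor(self):
        s_mat = np.array(self._s).T           # (n, m)
        y_mat = np.array(self._y).T           # (n, m)
        m = s_mat.shape[1]
        sts = s_mat.T @ s_mat
        sty = s_mat.T @ y_mat
        low = np.tril(sty, k=-1)
        diag = np.diag(np.diag(sty))
        mid = np.block([[self.gamma * sts, low], [low.T, -diag]])
        w = np.hstack([self.gamma * s_mat, y_mat])
        try:
            from scipy.linalg import lu_factor

            self._factors = (w, lu_factor(mid))
        except Exception:
            self._factors = None

    def dot(self, p):
        p = np.asarray(p, dtype=float)
        out = self.gamma * p
        if self._factors is not None:
            from scipy.linalg import lu_solve

            w, lu = self._factors
            out = out - w @ lu_solve(lu, w.T @ p)
        return out

    def __matmul__(self, p):
        return self.dot(p)

    def get_matrix(self):
        eye = np.eye(self.n)
        return np.column_stack([self.dot(eye[:, i]) for i in range(self.n)])
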