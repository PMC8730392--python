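"""Colored complex-step Jacobians for node-separable NLP functions.

Direct-collocation residuals are node-local: each output depends on a handful
of decision variables at one or two adjacent mesh nodes.  Exploiting that
sparsity, columns of the Jacobian whose row supports are disjoint can be
perturbed simultaneously.  A single complex-step evaluation per color then
yields every column of that color to machine precision (no subtractive
cancellation), provided the function is written complex-analytically (no
branching or absolute values on perturbed quantities).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import sparse

_STEP = 1e-100


class ColoredJacobian:
    """Sparse Jacobian of ``fun: R^n -> R^m`` via colored complex steps.

    ``rows_per_col[j]`` lists the output indices that may depend on input
    ``j`` (a conservative superset is fine).  Columns are greedily grouped
    into colors with disjoint row supports.
    """

    def __init__(self, fun: Callable[[np.ndarray], np.ndarray],
                 n_in: int, n_out: int,
                 rows_per_col: Sequence[np.ndarray]):
        self.fun = fun
        self.n_in = n_in
        self.n_out = n_out
        rows_per_col = [np.asarray(r, dtype=np.intp) for r in rows_per_col]

        # greedy coloring: a color is a set of columns with disjoint rows
        color_masks: list[np.ndarray] = []
        color_cols: list[list[int]] = []
        order = np.argsort([-len(r) for r in rows_per_col])
        col_color = np.empty(n_in, dtype=np.intp)
        for j in order:
            rows = rows_per_col[j]
            for c, mask in enumerate(color_masks):
                if not mask[rows].any():
                    mask[rows] = True
                    color_cols[c].append(j)
                    col_color[j] = c
                    break
            else:
                mask = np.zeros(n_out, dtype=bool)
                mask[rows] = True
                color_masks.append(mask)
                color_cols.append([j])
                col_color[j] = len(color_masks) - 1

        self.n_colors = len(color_cols)
        self._color_cols = [np.asarray(c, dtype=np.intp) for c in color_cols]
        # per color: concatenated (row, col) entry positions
        self._color_rows = []
        self._entry_row = []
        self._entry_col = []
        for cols in self._color_cols:
            rows_cat = np.concatenate([rows_per_col[j] for j in cols]) \
                if len(cols) else np.empty(0, dtype=np.intp)
            cols_cat = np.concatenate([np.full(len(rows_per_col[j]), j, dtype=np.intp)
                                       for j in cols]) \
                if len(cols) else np.empty(0, dtype=np.intp)
            self._color_rows.append(rows_cat)
            self._entry_row.append(rows_cat)
            self._entry_col.append(cols_cat)
        self._pattern_row = np.concatenate(self._entry_row)
        self._pattern_col = np.concatenate(self._entry_col)
        self.nnz = len(self._pattern_row)

    def __call__(self, x: np.ndarray) -> sparse.csr_matrix:
        x = np.asarray(x, dtype=float)
        data = np.empty(self.nnz)
        pos = 0
        for cols, rows_cat in zip(self._color_cols, self._color_rows):
            xp = x.astype(complex)
            xp[cols] += 1j * _STEP
            vals = np.imag(self.fun(xp)) / _STEP
            data[pos:pos + len(rows_cat)] = vals[rows_cat]
            pos += len(rows_cat)
        return sparse.csr_matrix(
            (data, (self._pattern_row, self._pattern_col)),
            shape=(self.n_out, self.n_in))

    def dense_row_weighted(self, x: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Gradient of ``weights @ fun(x)`` as a dense vector (for objectives)."""
        jac = self(x)
        return np.asarray(jac.T @ weights).ravel()
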