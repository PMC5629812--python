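"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the mathematics, not the
package implementation: dense linear algebra, exhaustive enumeration, and
closed forms, so the fast sparse/production paths are checked against a
slow second route.
"""

from __future__ import annotations

import numpy as np


def dense_effective_resistance(L: np.ndarray, s: int, g: int) -> float:
    """Two-terminal resistance from the exact rank-corrected inverse:
    L+ = (L + J/n)^-1 - J/n, R = L+_ss + L+_gg - 2 L+_sg."""
    n = L.shape[0]
    J = np.ones((n, n)) / n
    Lp = np.linalg.inv(L + J) - J
    return float(Lp[s, s] + Lp[g, g] - 2 * Lp[s, g])


def dense_voltages(L: np.ndarray, s: int, g: int, current: float = 1.0) -> np.ndarray:
    """Grounded dense solve: delete the ground row/column, solve, re-insert."""
    n = L.shape[0]
    keep = [i for i in range(n) if i != g]
    b = np.zeros(n - 1)
    b[keep.index(s)] = current
    v = np.zeros(n)
    v[keep] = np.linalg.solve(L[np.ix_(keep, keep)], b)
    return v


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Slopes and standard errors from (X'X)^-1 X'y, from first principles."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se


def residual_partial_correlation(series: np.ndarray, a: int, b: int) -> float:
    """Partial correlation of rows a, b of ``series`` given all other rows,
    via regression residuals over the columns (observations)."""
    k, n = series.shape
    others = [i for i in range(k) if i not in (a, b)]
    X = np.column_stack([np.ones(n)] + [series[i] for i in others])
    ra = series[a] - X @ np.linalg.lstsq(X, series[a], rcond=None)[0]
    rb = series[b] - X @ np.linalg.lstsq(X, series[b], rcond=None)[0]
    return float(np.corrcoef(ra, rb)[0, 1])


def circle_cells_bruteforce(raster, cx: float, cy: float, radius: float):
    """All (row, col, value) whose cell center lies within the radius,
    found by an explicit double loop."""
    out = []
    for r in range(raster.n_rows):
        for c in range(raster.n_cols):
            x, y = raster.cell_center(r, c)
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2 and np.isfinite(
                raster.data[r, c]
            ):
                out.append((r, c, raster.data[r, c]))
    return out
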