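"""Zero-fill incomplete factorization for the five-point SPD operator.

For the symmetric M-matrix A = D + Ls + Ls^T assembled on the (nx, ny) grid
(lexicographic order, j fastest), the zero-fill incomplete factorization
keeps the off-diagonals of A and replaces the diagonal by the recursion

    d(i,j) = diag(i,j) - sx(i-1,j)^2 / d(i-1,j) - sy(i,j-1)^2 / d(i,j-1),

giving the symmetric positive definite preconditioner
M = (D' + Ls) D'^-1 (D' + Ls^T) — the structured-grid equivalent of ILU(0)
(a.k.a. DIC/IC(0)) and safe for conjugate gradients.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ic0_factor(diag, sx, sy):  # pragma: no cover - compiled
    nx, ny = diag.shape
    d = np.empty_like(diag)
    for i in range(nx):
        for j in range(ny):
            v = diag[i, j]
            if i > 0:
                v -= sx[i - 1, j] * sx[i - 1, j] / d[i - 1, j]
            if j > 0:
                v -= sy[i, j - 1] * sy[i, j - 1] / d[i, j - 1]
            d[i, j] = v
    return d


@njit(cache=True)
def ic0_apply(r, d, sx, sy, out):  # pragma: no cover - compiled
    nx, ny = d.shape
    # forward solve (D' + Ls) z = r ; off-diagonals of A are -sigma
    for i in range(nx):
        for j in range(ny):
            v = r[i, j]
            if i > 0:
                v += sx[i - 1, j] * out[i - 1, j]
            if j > 0:
                v += sy[i, j - 1] * out[i, j - 1]
            out[i, j] = v / d[i, j]
    # scale by D' then backward solve (D' + Ls^T) x = w
    for i in range(nx - 1, -1, -1):
        for j in range(ny - 1, -1, -1):
            v = out[i, j] * d[i, j]
            if i < nx - 1:
                v += sx[i, j] * out[i + 1, j]
            if j < ny - 1:
                v += sy[i, j] * out[i, j + 1]
            out[i, j] = v / d[i, j]
    return out
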