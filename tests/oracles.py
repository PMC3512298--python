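"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (dense matrices, per-volume loops,
no shared code with the package's solver) so it can serve as an oracle.
"""

from __future__ import annotations

import numpy as np


def dense_diffusion_matrix(sigma_x, sigma_y, alpha):
    """Volume-by-volume flux-balance assembly of the implicit operator.

    Loops every interior face and accumulates +sigma on the two incident
    diagonals and -sigma on the two off-diagonals; adds alpha to every
    diagonal.  Volumes are flattened in C order over (nx, ny).
    """
    nxm1, ny = sigma_x.shape
    nx = nxm1 + 1
    n = nx * ny
    A = np.zeros((n, n))

    def p(i, j):
        return i * ny + j

    for i in range(nx):
        for j in range(ny):
            A[p(i, j), p(i, j)] += alpha
    for i in range(nx - 1):
        for j in range(ny):
            s = sigma_x[i, j]
            a, b = p(i, j), p(i + 1, j)
            A[a, a] += s
            A[b, b] += s
            A[a, b] -= s
            A[b, a] -= s
    for i in range(nx):
        for j in range(ny - 1):
            s = sigma_y[i, j]
            a, b = p(i, j), p(i, j + 1)
            A[a, a] += s
            A[b, b] += s
            A[a, b] -= s
            A[b, a] -= s
    return A


def dense_split_step(V, eta_states, sigma_x, sigma_y, alpha, model, dt_o, N_o,
                     istim_fn, t0):
    """One Godunov macro step via dense solve + non-fused Euler substeps.

    ``eta_states`` is the full (n_vars, M) state array (row 0 = V, updated
    in place on a copy which is returned).
    """
    S = eta_states.copy()
    A = dense_diffusion_matrix(sigma_x, sigma_y, alpha)
    S[0, :] = np.linalg.solve(A, alpha * V.ravel())
    dt_p = dt_o * N_o
    for k in range(N_o):
        istim = istim_fn(t0 + k * dt_o)
        dS = model.rhs(S, istim)
        S += dt_o * dS
    return S
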