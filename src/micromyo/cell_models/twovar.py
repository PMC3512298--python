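"""Two-variable phenomenological excitable membrane model for solver tests.

A Mitchell-Schaeffer-type model rescaled to physiological voltage units:
``u = (V - V_rest) / V_amp`` is the normalized potential and ``w`` a slow
recovery gate.

    dV/dt = V_amp * ( w * u^2 (1 - u) / tau_in  -  u / tau_out ) + I_stim
    dw/dt = (1 - w) / tau_open   if u <  u_gate
            -w / tau_close       if u >= u_gate

Rest state (V_rest, w = 1) is an exact fixed point.  The fast inward time
scale tau_in sets the upstroke, tau_out the repolarization, tau_open /
tau_close the recovery (hence the action-potential duration).  The
right-hand side is ~two orders of magnitude cheaper than the 41-variable
model, which is what makes it useful in tests; the time scales can be
overridden (e.g. to shrink the wavelength for reduced-domain reentry
demonstrations).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import IonicModelSpec

V_REST = -80.0    # mV
V_AMP = 100.0     # mV
TAU_IN = 0.3      # ms
TAU_OUT = 6.0     # ms
TAU_OPEN = 120.0  # ms
TAU_CLOSE = 80.0  # ms
U_GATE = 0.13

_kernel_cache: dict[tuple, object] = {}


def _make_kernel(tau_in, tau_out, tau_open, tau_close, u_gate):
    key = (tau_in, tau_out, tau_open, tau_close, u_gate)
    if key in _kernel_cache:
        return _kernel_cache[key]

    @njit(fastmath=True)
    def kernel(S, dS, istim, dt, fused):  # pragma: no cover - compiled
        M = S.shape[1]
        for m in range(M):
            V = S[0, m]
            w = S[1, m]
            u = (V - V_REST) / V_AMP
            dV = V_AMP * (w * u * u * (1.0 - u) / tau_in - u / tau_out) \
                + istim[m]
            if u < u_gate:
                dw = (1.0 - w) / tau_open
            else:
                dw = -w / tau_close
            if fused:
                S[0, m] = V + dt * dV
                S[1, m] = w + dt * dw
            else:
                dS[0, m] = dV
                dS[1, m] = dw

    _kernel_cache[key] = kernel
    return kernel


def test_model(
    tau_in: float = TAU_IN,
    tau_out: float = TAU_OUT,
    tau_open: float = TAU_OPEN,
    tau_close: float = TAU_CLOSE,
    u_gate: float = U_GATE,
) -> IonicModelSpec:
    """Cheap two-variable excitable model (registry name ``"test"``)."""
    return IonicModelSpec(
        name="test",
        n_vars=2,
        initial_state=np.array([V_REST, 1.0]),
        kernel=_make_kernel(float(tau_in), float(tau_out), float(tau_open),
                            float(tau_close), float(u_gate)),
        markov_groups={},
        rel_cost=1.0,
    )
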