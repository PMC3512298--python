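"""Common interface for ionic membrane models.

A model is described by an :class:`IonicModelSpec` wrapping a compiled kernel
with signature ``kernel(S, dS, istim, dt, fused)`` where ``S`` is the
structure-of-arrays state ``(n_vars, M)`` (variable-major; row 0 is the
transmembrane potential V in mV), ``istim`` a per-volume applied current
density in pA/pF, and ``dt`` the explicit-Euler step in ms.  With
``fused=True`` the kernel advances ``S`` in place; with ``fused=False`` it
writes time derivatives into ``dS`` and leaves ``S`` untouched.  Volumes are
independent: the result does not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["IonicModelSpec", "CellStateArray", "ode_substep_euler"]


@dataclass
class IonicModelSpec:
    name: str
    n_vars: int
    initial_state: np.ndarray                  # (n_vars,)
    kernel: Callable                            # see module docstring
    markov_groups: dict[str, list[int]] = field(default_factory=dict)
    # Explicit state indices per probability-conserving Markov chain; the
    # remaining occupancy of each chain is carried implicitly as one minus
    # the explicit sum (the chains' reference state is not a differential
    # variable).
    rel_cost: float = 1.0                       # rough cost per rhs vs "test"

    def make_states(self, n_volumes: int) -> np.ndarray:
        """Uniform state array (n_vars, M) at the model's resting state."""
        return np.ascontiguousarray(
            np.repeat(self.initial_state[:, None], n_volumes, axis=1)
        )

    def rhs(self, states: np.ndarray, istim: np.ndarray) -> np.ndarray:
        """Time derivatives (dV/dt = -I_ion + I_stim in mV/ms, and d(eta)/dt)."""
        dS = np.empty_like(states)
        self.kernel(states, dS, istim, 0.0, False)
        return dS

    def step(self, states: np.ndarray, dt: float, istim: np.ndarray) -> None:
        """One explicit-Euler substep, in place."""
        self.kernel(states, states, istim, dt, True)

    def markov_occupancy(self, states: np.ndarray) -> dict[str, np.ndarray]:
        """Total occupancy per Markov chain (explicit states + implicit rest)."""
        out = {}
        for name, idx in self.markov_groups.items():
            explicit = states[idx, ...].sum(axis=0)
            out[name] = explicit + (1.0 - explicit)  # implicit complement
        return out

    def markov_explicit_sums(self, states: np.ndarray) -> dict[str, np.ndarray]:
        """Sum of the explicit chain states (must stay within [0, 1])."""
        return {name: states[idx, ...].sum(axis=0)
                for name, idx in self.markov_groups.items()}


class CellStateArray:
    """Thin wrapper over the structure-of-arrays ionic state.

    ``arr`` has shape (n_vars, M) with contiguous per-variable blocks; the
    first block is always the transmembrane potential V (mV).
    """

    def __init__(self, model: IonicModelSpec, n_volumes: int,
                 arr: np.ndarray | None = None):
        self.model = model
        self.arr = model.make_states(n_volumes) if arr is None else arr
        if self.arr.shape != (model.n_vars, n_volumes):
            raise ValueError("state array shape mismatch")

    @property
    def V(self) -> np.ndarray:
        return self.arr[0]

    @property
    def eta(self) -> np.ndarray:
        return self.arr[1:]

    @property
    def n_volumes(self) -> int:
        return self.arr.shape[1]

    def copy(self) -> "CellStateArray":
        return CellStateArray(self.model, self.n_volumes, self.arr.copy())


def ode_substep_euler(
    states: np.ndarray,
    model: IonicModelSpec,
    dt_o: float,
    istim: np.ndarray,
    inplace: bool = False,
) -> np.ndarray:
    """Advance every volume's ionic state by one explicit-Euler substep.

    V <- V + dt_o * (-I_ion(V, eta) + I_stim)  (both in pA/pF = mV/ms),
    eta <- eta + dt_o * f(V, eta).  Volumes are advanced independently.

    Raises ``FloatingPointError`` naming the first offending volume and
    variable if a non-finite value appears.
    """
    if dt_o < 0:
        raise ValueError("dt_o must be >= 0")
    istim = np.asarray(istim, dtype=float)
    if istim.shape != (states.shape[1],):
        raise ValueError("istim length must match the number of volumes")
    out = states if inplace else states.copy()
    if dt_o > 0:
        model.step(out, dt_o, istim)
        if not np.isfinite(out).all():
            var, vol = np.argwhere(~np.isfinite(out))[0]
            raise FloatingPointError(
                f"non-finite state: volume {vol}, variable {var} "
                f"(model {model.name})"
            )
    return out
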