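"""Post-processing: activation maps, conduction velocity, L2 splitting error."""

from __future__ import annotations

import numpy as np

__all__ = [
    "activation_times",
    "activation_map",
    "conduction_velocity",
    "anisotropy_ratio",
    "l2_relative_error",
    "DEFAULT_THRESHOLD_MV",
]

# Upward-crossing threshold used for wavefront timing (the action-potential
# upstroke spans roughly -80 to +30 mV, so -30 mV sits well inside it).
DEFAULT_THRESHOLD_MV = -30.0


def activation_times(
    traces: np.ndarray,
    times: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MV,
) -> np.ndarray:
    """First upward threshold crossing per trace, linearly interpolated.

    ``traces`` has shape (nt, nv), sampled at the (uniform) ``times``.  A
    crossing landing exactly on a sample gets that sample's time.  Traces
    that never cross return NaN (undefined).
    """
    traces = np.asarray(traces, float)
    times = np.asarray(times, float)
    nt, nv = traces.shape
    if times.shape != (nt,):
        raise ValueError("times length must match traces")
    out = np.full(nv, np.nan)
    at_sample = traces >= threshold
    for v in range(nv):
        idx = np.argmax(at_sample[:, v])
        if not at_sample[idx, v]:
            continue                       # never crosses
        if idx == 0:
            out[v] = times[0]              # already above at the first sample
            continue
        v0, v1 = traces[idx - 1, v], traces[idx, v]
        if v1 == threshold or v1 == v0:
            out[v] = times[idx]
        else:
            frac = (threshold - v0) / (v1 - v0)
            out[v] = times[idx - 1] + frac * (times[idx] - times[idx - 1])
    return out


def activation_map(
    frames: np.ndarray, times: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MV,
) -> np.ndarray:
    """Activation times of a recorded field sequence (nt, nx, ny) -> (nx, ny)."""
    nt = frames.shape[0]
    flat = frames.reshape(nt, -1)
    return activation_times(flat, times, threshold).reshape(frames.shape[1:])


def conduction_velocity(
    act: np.ndarray,
    p1: tuple[int, int],
    p2: tuple[int, int],
    h: float = 8.0,
) -> float:
    """Conduction velocity (um/ms) between two activated grid points.

    ``act`` is an activation map over the (nx, ny) grid (NaN = undefined);
    ``p1`` and ``p2`` are volume indices.  Velocity = Euclidean distance /
    activation-time difference, requiring t(p2) > t(p1).
    """
    t1, t2 = act[p1], act[p2]
    if np.isnan(t1) or np.isnan(t2):
        raise ValueError("activation undefined at a measurement point")
    if t2 <= t1:
        raise ValueError("t(p2) must exceed t(p1) for a CV measurement")
    dist = h * float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    if dist == 0.0:
        raise ValueError("measurement points coincide")
    return dist / (t2 - t1)


def anisotropy_ratio(cv_a: float, cv_b: float) -> float:
    """min/max of two conduction velocities (dimensionless, <= 1)."""
    return min(cv_a, cv_b) / max(cv_a, cv_b)


def l2_relative_error(
    V: np.ndarray, V_ref: np.ndarray, sqrt: bool = False
) -> float:
    """Relative L2 error between two potential records.

    Literal ratio sum((V - V_ref)^2) / sum(V_ref^2) over all time samples
    and volumes; with ``sqrt=True`` the square root of that ratio is
    returned instead.  Multiply by 100 for a percentage.
    """
    V = np.asarray(V, float)
    V_ref = np.asarray(V_ref, float)
    if V.shape != V_ref.shape:
        raise ValueError("V and V_ref must have the same shape")
    denom = float((V_ref ** 2).sum())
    if denom == 0.0:
        raise ValueError("V_ref is identically zero")
    ratio = float(((V - V_ref) ** 2).sum()) / denom
    return float(np.sqrt(ratio)) if sqrt else ratio
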