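"""Stimulation protocols: rectangular current pulses, central and S1-S2.

A schedule is pure data: a list of pulses, each a rectangle of volumes, an
amplitude (pA/pF, i.e. current density already normalized by the membrane
capacitance, positive = depolarizing), a start time and a duration.  The
solver injects the summed amplitude of all active pulses covering a volume
during the reaction substeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microstructure import TissueGeometry

__all__ = [
    "StimulusPulse",
    "StimulusSchedule",
    "make_central_stimulus",
    "make_edge_stimulus",
    "make_s1s2",
    "stimulus_current",
    "DEFAULT_PULSE_MS",
    "DEFAULT_AMPLITUDE",
]

# Default pulse length, ms.
DEFAULT_PULSE_MS = 2.0
# Default amplitude, pA/pF: comfortably suprathreshold (roughly twice the
# diastolic threshold) for the 41-variable model on the shipped
# microstructure with a 2 ms pulse over a small region; the large value
# reflects the ~1 mm liminal length of well-coupled tissue draining a small
# stimulated patch.  Measure thresholds with ``find_threshold``.
DEFAULT_AMPLITUDE = 500.0


@dataclass(frozen=True)
class StimulusPulse:
    """One rectangular pulse: volumes [i0, i1) x [j0, j1), times [start, start+duration)."""

    i0: int
    i1: int
    j0: int
    j1: int
    amplitude: float   # pA/pF
    start: float       # ms
    duration: float    # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.start < 0:
            raise ValueError("pulse start must be >= 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("pulse amplitude must be finite")
        if self.i0 >= self.i1 or self.j0 >= self.j1:
            raise ValueError("pulse region is empty")

    def active(self, t: float) -> bool:
        return self.start - 1e-12 <= t < self.start + self.duration - 1e-12

    def covers(self, i: int, j: int) -> bool:
        return self.i0 <= i < self.i1 and self.j0 <= j < self.j1

    @property
    def n_volumes(self) -> int:
        return (self.i1 - self.i0) * (self.j1 - self.j0)


class StimulusSchedule:
    """A list of pulses on a given mesh, with fast per-substep evaluation."""

    def __init__(self, pulses: list[StimulusPulse], shape: tuple[int, int]):
        nx, ny = shape
        for p in pulses:
            if not (0 <= p.i0 < p.i1 <= nx and 0 <= p.j0 < p.j1 <= ny):
                raise ValueError(f"pulse region {p} outside mesh {shape}")
        if len(set(pulses)) != len(pulses):
            raise ValueError("duplicate identical pulses in schedule")
        self.pulses = list(pulses)
        self.shape = (nx, ny)
        self._cache_key: tuple[int, ...] | None = None
        self._cache_arr: np.ndarray | None = None
        self._zero = np.zeros(nx * ny)

    def stimulus_current(self, volume_index: tuple[int, int], t: float) -> float:
        """Summed amplitude of active pulses covering one volume at time t."""
        i, j = volume_index
        return float(sum(p.amplitude for p in self.pulses
                         if p.active(t) and p.covers(i, j)))

    def current_array(self, t: float, n_volumes: int) -> np.ndarray:
        """Per-volume current at time t, flattened in C order over (nx, ny).

        The array is cached while the set of active pulses is unchanged;
        callers must not mutate it.
        """
        key = tuple(k for k, p in enumerate(self.pulses) if p.active(t))
        if not key:
            return self._zero
        if key != self._cache_key:
            nx, ny = self.shape
            arr = np.zeros((nx, ny))
            for k in key:
                p = self.pulses[k]
                arr[p.i0:p.i1, p.j0:p.j1] += p.amplitude
            self._cache_key = key
            self._cache_arr = arr.ravel()
        return self._cache_arr

    def total_charge(self) -> float:
        """Sum over pulses of amplitude * duration * covered volumes."""
        return sum(p.amplitude * p.duration * p.n_volumes for p in self.pulses)


def stimulus_current(schedule: StimulusSchedule,
                     volume_index: tuple[int, int], t: float) -> float:
    """Functional form of :meth:`StimulusSchedule.stimulus_current`."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return schedule.stimulus_current(volume_index, t)


def make_central_stimulus(
    geom: TissueGeometry,
    amplitude: float = DEFAULT_AMPLITUDE,
    start: float = 0.0,
    duration: float = DEFAULT_PULSE_MS,
    half_width_um: float = 40.0,
) -> StimulusSchedule:
    """A single pulse over the centered square of side 2*half_width_um."""
    span_x, span_y = geom.nx * geom.h, geom.ny * geom.h
    if not half_width_um < min(span_x, span_y) / 2:
        raise ValueError("half_width must be less than half the domain")
    w = max(1, int(round(2 * half_width_um / geom.h)))
    i0 = (geom.nx - w) // 2
    j0 = (geom.ny - w) // 2
    pulse = StimulusPulse(i0, i0 + w, j0, j0 + w, amplitude, start, duration)
    return StimulusSchedule([pulse], (geom.nx, geom.ny))


def make_edge_stimulus(
    geom: TissueGeometry,
    edge: str = "left",
    depth: int = 2,
    amplitude: float = DEFAULT_AMPLITUDE,
    start: float = 0.0,
    duration: float = DEFAULT_PULSE_MS,
) -> StimulusSchedule:
    """A pulse along one domain edge, ``depth`` volumes deep, full extent."""
    nx, ny = geom.nx, geom.ny
    regions = {
        "left": (0, depth, 0, ny),
        "right": (nx - depth, nx, 0, ny),
        "bottom": (0, nx, 0, depth),
        "top": (0, nx, ny - depth, ny),
    }
    if edge not in regions:
        raise ValueError(f"edge must be one of {sorted(regions)}")
    pulse = StimulusPulse(*regions[edge], amplitude, start, duration)
    return StimulusSchedule([pulse], (nx, ny))


def make_s1s2(
    geom: TissueGeometry,
    coupling_interval: float,
    s1_amplitude: float = DEFAULT_AMPLITUDE,
    s2_amplitude: float = DEFAULT_AMPLITUDE,
    pulse_ms: float = DEFAULT_PULSE_MS,
    s1_depth: int = 2,
) -> StimulusSchedule:
    """Cross-field S1-S2: S1 strip on the left edge at t = 0, then a
    premature S2 over the lower-left quadrant at t = coupling_interval."""
    if coupling_interval <= 0:
        raise ValueError("coupling_interval must be > 0")
    nx, ny = geom.nx, geom.ny
    s1 = StimulusPulse(0, s1_depth, 0, ny, s1_amplitude, 0.0, pulse_ms)
    s2 = StimulusPulse(0, nx // 2, 0, ny // 2, s2_amplitude,
                       coupling_interval, pulse_ms)
    return StimulusSchedule([s1, s2], (nx, ny))
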