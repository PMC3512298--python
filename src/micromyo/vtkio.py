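"""Legacy ASCII VTK (STRUCTURED_POINTS) and CSV trace I/O.

Snapshots are written as VTK structured points so any standard viewer
(ParaView, VisIt) opens them; the format is plain text and round-trips the
double-precision field exactly via repr.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

__all__ = ["write_snapshot", "read_snapshot", "write_traces", "read_traces"]


def write_snapshot(path, fields: dict[str, np.ndarray], h: float = 8.0,
                   title: str = "micromyo snapshot") -> None:
    """Write 2-D cell fields (nx, ny) as VTK structured points.

    All fields must share one shape; values are written x-fastest as VTK
    expects, full double precision.
    """
    fields = {k: np.asarray(v, float) for k, v in fields.items()}
    shapes = {v.shape for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must have the same shape")
    (nx, ny), = shapes
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {h!r} {h!r} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(repr(float(v)) for v in arr.T.ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> dict[str, np.ndarray]:
    """Read back a snapshot written by :func:`write_snapshot`."""
    lines = Path(path).read_text().splitlines()
    dims = None
    fields: dict[str, np.ndarray] = {}
    k = 0
    while k < len(lines):
        line = lines[k]
        if line.startswith("DIMENSIONS"):
            nx, ny, _ = (int(v) for v in line.split()[1:])
            dims = (nx, ny)
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = np.array([float(v) for v in lines[k + 2:k + 2 + dims[0] * dims[1]]])
            fields[name] = vals.reshape(dims[1], dims[0]).T
            k += 1 + dims[0] * dims[1]
        k += 1
    return fields


def write_traces(path, times: np.ndarray, traces: np.ndarray,
                 probes: list[tuple[int, int]]) -> None:
    """CSV probe traces: header ``time_ms, V_i_j, ...`` one row per sample."""
    times = np.asarray(times, float)
    traces = np.asarray(traces, float)
    if traces.shape != (len(times), len(probes)):
        raise ValueError("traces shape must be (n_times, n_probes)")
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_ms"] + [f"V_{i}_{j}" for i, j in probes])
        for t, row in zip(times, traces):
            w.writerow([repr(float(t))] + [repr(float(v)) for v in row])


def read_traces(path) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Read back traces written by :func:`write_traces`."""
    with open(path, newline="") as f:
        rows = list(csv.reader(f))
    header = rows[0]
    probes = []
    for col in header[1:]:
        _, i, j = col.split("_")
        probes.append((int(i), int(j)))
    data = np.array([[float(v) for v in row] for row in rows[1:]])
    if data.size == 0:
        return np.empty(0), np.empty((0, len(probes))), probes
    return data[:, 0], data[:, 1:], probes
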