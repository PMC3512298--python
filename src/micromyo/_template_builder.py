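"""Programmatic construction of the shipped basic-unit template.

The template is checked in as ``micromyo/data/basic_unit.json``; this module
is the generator that produced it (kept so the data file can be audited and
regenerated bit-identically).  Layout: a running-bond ("brick wall") pattern
of 32 myocytes on the 81 x 18 torus — eight longitudinal strands whose cell
boundaries are staggered by half a cell between neighbouring strands, so that
under periodic closure every cell touches exactly two cells at its ends
(plicate junctions) and two on each lateral side (interplicate / combined
plicate), i.e. six gap-junction neighbours each.

Junction placement fractions (how many rows of a cell-end interface carry
plicate junctions; how many interplicate / combined-plicate junctions sit on
each lateral border arc) are design parameters of the template, chosen so the
assembled tissue reproduces the reference longitudinal and transverse
conduction velocities (410 and 130 um/ms).
"""

from __future__ import annotations

import json

import numpy as np

from .microstructure import BasicUnit, ConnectionKind

NX, NY = 81, 18
N_CELLS = 32

# Longitudinal strands (bottom to top): number of 8 um rows each.
STRAND_HEIGHTS = (2, 2, 3, 2, 2, 3, 2, 2)
# Cell boundaries along x (volume columns) on the 81-column circle.
# Even strands start at 0; odd strands are staggered by half a cell, so their
# fourth cell wraps the east seam (cols 70..80 plus 0..9).
EVEN_BOUNDS = (0, 20, 40, 60)
ODD_BOUNDS = (10, 30, 50, 70)

# Gap-junction placement (design parameters, see module docstring).
PLICATE_ROWS = 1          # rows of each cell-end interface carrying plicate
INTER_PER_ARC = 4         # interplicate junctions per lateral border arc
COMBINED_PER_ARC = 2      # combined-plicate junctions per lateral border arc

# Designed continuous cell dimensions: target mean / sample SD in um.
LENGTH_MEAN, LENGTH_SD = 120.9, 27.8
WIDTH_MEAN, WIDTH_SD = 18.3, 3.5
_DIMS_SEED = 20120824


def _strand_of_row() -> np.ndarray:
    out = np.empty(NY, dtype=int)
    j = 0
    for s, hgt in enumerate(STRAND_HEIGHTS):
        out[j : j + hgt] = s
        j += hgt
    assert j == NY
    return out


def _cell_of_column(strand: int) -> np.ndarray:
    bounds = EVEN_BOUNDS if strand % 2 == 0 else ODD_BOUNDS
    out = np.empty(NX, dtype=int)
    for i in range(NX):
        k = 0
        for kk, b in enumerate(bounds):
            if i >= b:
                k = kk
        if i < bounds[0]:        # wrapped cell (east seam)
            k = len(bounds) - 1
        out[i] = 4 * strand + k
    return out


def _cell_grid() -> np.ndarray:
    srow = _strand_of_row()
    per_strand = [_cell_of_column(s) for s in range(len(STRAND_HEIGHTS))]
    grid = np.empty((NX, NY), dtype=np.int32)
    for j in range(NY):
        grid[:, j] = per_strand[srow[j]]
    return grid


def _x_faces(grid: np.ndarray) -> np.ndarray:
    """x-face labels incl. the east seam column (face nx-1 couples to col 0)."""
    srow = _strand_of_row()
    xf = np.full((NX, NY), int(ConnectionKind.MEMBRANE), dtype=np.int8)
    for i in range(NX):
        inext = (i + 1) % NX
        for j in range(NY):
            a, b = grid[i, j], grid[inext, j]
            if a == b:
                xf[i, j] = ConnectionKind.CYTOPLASM
            else:
                xf[i, j] = ConnectionKind.MEMBRANE  # filled below per interface
    # Cell-end interfaces: plicate on the first PLICATE_ROWS rows of the strand.
    row_in_strand = np.zeros(NY, dtype=int)
    for j in range(1, NY):
        row_in_strand[j] = row_in_strand[j - 1] + 1 if srow[j] == srow[j - 1] else 0
    for i in range(NX):
        inext = (i + 1) % NX
        for j in range(NY):
            if grid[i, j] != grid[inext, j] and row_in_strand[j] < PLICATE_ROWS:
                xf[i, j] = ConnectionKind.PLICATE
    return xf


def _arcs_on_circle(pairs: list[tuple[int, int]]) -> list[list[int]]:
    """Split circle columns into maximal arcs of constant (below, above) pair."""
    n = len(pairs)
    start = 0
    while start < n and pairs[start] == pairs[start - 1]:
        start += 1
    if start == n:   # single arc covering the whole circle
        return [list(range(n))]
    arcs, cur = [], [start]
    for k in range(1, n):
        i = (start + k) % n
        if pairs[i] == pairs[(i - 1) % n]:
            cur.append(i)
        else:
            arcs.append(cur)
            cur = [i]
    arcs.append(cur)
    return arcs


def _y_faces(grid: np.ndarray) -> np.ndarray:
    """y-face labels incl. the north seam row (face ny-1 couples to row 0)."""
    srow = _strand_of_row()
    yf = np.full((NX, NY), int(ConnectionKind.MEMBRANE), dtype=np.int8)
    for j in range(NY):
        jnext = (j + 1) % NY
        below, above = grid[:, j], grid[:, jnext]
        if srow[j] == srow[jnext]:
            yf[:, j] = ConnectionKind.CYTOPLASM   # interior of a strand
            continue
        # Strand interface: distribute junctions along each border arc.
        pairs = [(int(below[i]), int(above[i])) for i in range(NX)]
        for arc in _arcs_on_circle(pairs):
            kinds = [ConnectionKind.INTERPLICATE] * INTER_PER_ARC
            for q in range(COMBINED_PER_ARC):
                kinds.insert(2 * q + 1, ConnectionKind.COMBINED_PLICATE)
            kinds = kinds[: len(arc)]
            # Evenly spaced positions within the arc.
            pos = [arc[int(round(q * (len(arc) - 1) / max(len(kinds) - 1, 1)))]
                   for q in range(len(kinds))]
            for kind, i in zip(kinds, pos):
                yf[i, j] = kind
    return yf


def _cell_dims() -> np.ndarray:
    """32 designed (length, width) pairs with exact mean and sample SD."""
    rng = np.random.default_rng(_DIMS_SEED)
    z_len = rng.normal(size=N_CELLS)
    z_wid = rng.normal(size=N_CELLS)

    def standardize(z, mean, sd):
        z = (z - z.mean()) / z.std(ddof=1)
        z = np.clip(z, -2.2, 2.2)               # keep dims physiological
        z = (z - z.mean()) / z.std(ddof=1)      # re-standardize after clip
        return mean + sd * z

    dims = np.column_stack(
        [standardize(z_len, LENGTH_MEAN, LENGTH_SD),
         standardize(z_wid, WIDTH_MEAN, WIDTH_SD)]
    )
    assert dims.min() > 0
    return dims


def build_template() -> BasicUnit:
    grid = _cell_grid()
    return BasicUnit(
        cell_label_grid=grid,
        x_face_labels=_x_faces(grid),
        y_face_labels=_y_faces(grid),
        cell_dims=_cell_dims(),
        h=8.0,
        d=10.0,
        meta={
            "strand_heights": list(STRAND_HEIGHTS),
            "plicate_rows_per_end": PLICATE_ROWS,
            "interplicate_per_arc": INTER_PER_ARC,
            "combined_per_arc": COMBINED_PER_ARC,
        },
    )


def template_to_json(unit: BasicUnit) -> str:
    doc = {
        "h": unit.h,
        "d": unit.d,
        "cell_label_grid": unit.cell_label_grid.tolist(),
        "x_face_labels": unit.x_face_labels.tolist(),
        "y_face_labels": unit.y_face_labels.tolist(),
        "cell_dims": unit.cell_dims.tolist(),
        "meta": unit.meta,
    }
    return json.dumps(doc)
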