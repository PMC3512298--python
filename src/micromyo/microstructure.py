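"""Cardiac tissue microstructure: template unit, tiling, face conductances.

The tissue is a uniform 2-D grid of 8 um x 8 um finite volumes.  Every
interior face between two volumes carries a *connection label* describing the
microanatomy at that face: cytoplasm (both volumes inside one myocyte), plain
membrane (no electrical contact), or one of three gap-junction classes
(plicate at longitudinal cell ends, interplicate and combined plicate on
lateral borders).  Face labels are turned into effective face conductivities
(uS/um) which the finite-volume solver consumes directly.

The shipped basic unit holds 32 myocytes on an 81 x 18 grid (648 um x 144 um)
in a running-bond layout defined on the periodic closure of the unit (four
cells wrap the east seam), so that under periodic tiling every cell couples
to exactly six neighbours through gap junctions.  Larger sheets are produced
by tiling copies of the unit; the unit's seam faces define how adjacent
copies connect.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ConnectionKind",
    "ConductanceParams",
    "BasicUnit",
    "TissueGeometry",
    "FaceField",
    "CellStats",
    "build_basic_unit",
    "tile_units",
    "crop",
    "assign_face_conductances",
    "cell_statistics",
    "neighbor_graph",
    "periodic_neighbor_degrees",
]


class ConnectionKind(enum.IntEnum):
    """The five possible connection types between neighbouring volumes."""

    MEMBRANE = 0
    CYTOPLASM = 1
    PLICATE = 2
    INTERPLICATE = 3
    COMBINED_PLICATE = 4


GAP_JUNCTION_KINDS = (
    ConnectionKind.PLICATE,
    ConnectionKind.INTERPLICATE,
    ConnectionKind.COMBINED_PLICATE,
)


@dataclass(frozen=True)
class ConductanceParams:
    """Electrical parameters of the microstructure.

    Conductivities (sigma_*) are in uS/um and apply per face directly;
    gap-junction conductances (G_*) are in uS and are divided by the tissue
    depth ``d`` to obtain an effective face conductivity.
    """

    sigma_c: float = 0.4     # cytoplasm conductivity, uS/um
    G_p: float = 0.5         # plicate gap junction, uS
    G_i: float = 0.33        # interplicate gap junction, uS
    G_c: float = 0.062       # combined plicate gap junction, uS
    sigma_m: float = 0.0     # membrane (no flux), uS/um
    d: float = 10.0          # tissue depth, um
    h: float = 8.0           # volume edge length, um

    def __post_init__(self) -> None:
        for name in ("sigma_c", "G_p", "G_i", "G_c", "sigma_m", "d", "h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be nonnegative and finite, got {v}")
        if self.d <= 0 or self.h <= 0:
            raise ValueError("d and h must be positive")

    def face_value(self, kind: ConnectionKind) -> float:
        """Effective face conductivity (uS/um) for a connection label."""
        return self.face_lookup()[int(kind)]

    def face_lookup(self) -> np.ndarray:
        """Label -> face conductivity table, indexed by ConnectionKind."""
        return np.array(
            [
                self.sigma_m,
                self.sigma_c,
                self.G_p / self.d,
                self.G_i / self.d,
                self.G_c / self.d,
            ]
        )


@dataclass(frozen=True)
class BasicUnit:
    """The 32-cell template unit on its periodic (torus) closure.

    Arrays are indexed ``[i, j]`` with ``i`` the x (longitudinal) volume
    index and ``j`` the y (transverse) index.  ``x_face_labels[i, j]`` is the
    face between volumes (i, j) and (i+1, j); column ``i = nx-1`` is the east
    seam face to the next tiled copy.  ``y_face_labels[i, j]`` is the face
    between (i, j) and (i, j+1); row ``j = ny-1`` is the north seam.
    """

    cell_label_grid: np.ndarray   # (nx, ny) int, cell ids 0..31
    x_face_labels: np.ndarray     # (nx, ny) int, includes east seam column
    y_face_labels: np.ndarray     # (nx, ny) int, includes north seam row
    cell_dims: np.ndarray         # (32, 2) float, designed (length, width) um
    h: float = 8.0
    d: float = 10.0
    meta: dict = field(default_factory=dict)

    @property
    def nx(self) -> int:
        return self.cell_label_grid.shape[0]

    @property
    def ny(self) -> int:
        return self.cell_label_grid.shape[1]

    @property
    def n_cells(self) -> int:
        return int(self.cell_label_grid.max()) + 1

    @property
    def span_um(self) -> tuple[float, float]:
        return (self.nx * self.h, self.ny * self.h)


@dataclass(frozen=True)
class TissueGeometry:
    """A tiled tissue sheet: cell ids plus labels of all interior faces.

    Domain-boundary faces are not stored; the solver closes them with the
    no-flux (membrane) condition.
    """

    cell_label_grid: np.ndarray   # (nx, ny)
    x_face_labels: np.ndarray     # (nx-1, ny)
    y_face_labels: np.ndarray     # (nx, ny-1)
    h: float = 8.0
    d: float = 10.0

    @property
    def nx(self) -> int:
        return self.cell_label_grid.shape[0]

    @property
    def ny(self) -> int:
        return self.cell_label_grid.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.nx * self.ny

    def __post_init__(self) -> None:
        nx, ny = self.cell_label_grid.shape
        if self.x_face_labels.shape != (nx - 1, ny):
            raise ValueError("x_face_labels shape mismatch")
        if self.y_face_labels.shape != (nx, ny - 1):
            raise ValueError("y_face_labels shape mismatch")


@dataclass(frozen=True)
class FaceField:
    """Per-face effective conductivities (uS/um) on interior faces."""

    sigma_x: np.ndarray   # (nx-1, ny)
    sigma_y: np.ndarray   # (nx, ny-1)


@dataclass(frozen=True)
class CellStats:
    mean_length: float
    sd_length: float
    mean_width: float
    sd_width: float
    mean_neighbors: float


_TEMPLATE_RESOURCE = "basic_unit.json"


def _unit_from_dict(doc: dict) -> BasicUnit:
    return BasicUnit(
        cell_label_grid=np.array(doc["cell_label_grid"], dtype=np.int32),
        x_face_labels=np.array(doc["x_face_labels"], dtype=np.int8),
        y_face_labels=np.array(doc["y_face_labels"], dtype=np.int8),
        cell_dims=np.array(doc["cell_dims"], dtype=float),
        h=float(doc["h"]),
        d=float(doc["d"]),
        meta=doc.get("meta", {}),
    )


def build_basic_unit() -> BasicUnit:
    """Load the shipped 32-cell basic template unit.

    Deterministic: repeated calls return identical structures.
    """
    ref = resources.files("micromyo.data").joinpath(_TEMPLATE_RESOURCE)
    doc = json.loads(ref.read_text())
    return _unit_from_dict(doc)


def tile_units(unit: BasicUnit, ux: int, uy: int) -> TissueGeometry:
    """Tile ``ux`` x ``uy`` copies of the unit into a tissue sheet.

    Faces interior to each copy repeat the template; faces between adjacent
    copies carry the template's designed seam labels.  Each copy contributes
    32 distinct cell ids (``id = template_id + 32 * copy_index``); the
    template cells that wrap its periodic seam therefore appear as two raster
    pieces whose eastern piece continues into the neighbouring copy.
    """
    if ux < 1 or uy < 1:
        raise ValueError("unit counts must be >= 1")
    tnx, tny = unit.nx, unit.ny
    nx, ny = tnx * ux, tny * uy

    copy_index = np.add.outer(
        np.repeat(np.arange(ux), tnx), ux * np.repeat(np.arange(uy), tny)
    )
    cells = np.tile(unit.cell_label_grid, (ux, uy)) + unit.n_cells * copy_index

    xf = np.tile(unit.x_face_labels, (ux, uy))[: nx - 1, :]
    yf = np.tile(unit.y_face_labels, (ux, uy))[:, : ny - 1]
    return TissueGeometry(
        cell_label_grid=cells.astype(np.int32),
        x_face_labels=xf,
        y_face_labels=yf,
        h=unit.h,
        d=unit.d,
    )


def crop(geom: TissueGeometry, nx: int, ny: int) -> TissueGeometry:
    """Cut the lower-left ``nx`` x ``ny`` volumes out of a tissue sheet.

    The new domain boundary behaves as membrane (no flux), like any tissue
    edge.  Used to reach physical sizes that are not multiples of the unit.
    """
    if not (1 <= nx <= geom.nx and 1 <= ny <= geom.ny):
        raise ValueError("crop size outside geometry")
    return TissueGeometry(
        cell_label_grid=geom.cell_label_grid[:nx, :ny],
        x_face_labels=geom.x_face_labels[: nx - 1, :ny],
        y_face_labels=geom.y_face_labels[:nx, : ny - 1],
        h=geom.h,
        d=geom.d,
    )


def assign_face_conductances(
    geom: TissueGeometry, params: ConductanceParams | None = None
) -> FaceField:
    """Map connection labels to effective face conductivities (uS/um).

    membrane -> 0, cytoplasm -> sigma_c, gap junctions -> G/d.
    """
    params = params or ConductanceParams()
    lut = params.face_lookup()
    for name, labels in (("x", geom.x_face_labels), ("y", geom.y_face_labels)):
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= len(lut):
            raise ValueError(f"unknown connection label on {name}-faces")
    return FaceField(
        sigma_x=lut[geom.x_face_labels.astype(np.intp)],
        sigma_y=lut[geom.y_face_labels.astype(np.intp)],
    )


def _accumulate_edges(cells_a, cells_b, labels, edges) -> None:
    gj = (labels >= int(ConnectionKind.PLICATE))
    for a, b in zip(cells_a[gj].ravel(), cells_b[gj].ravel()):
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))


def neighbor_graph(geom: TissueGeometry) -> dict[int, set[int]]:
    """Cell adjacency through gap junctions (membrane contact is not adjacency).

    Returns a mapping cell id -> set of adjacent cell ids; every cell id
    present in the geometry appears as a key.
    """
    edges: set[tuple[int, int]] = set()
    c = geom.cell_label_grid
    _accumulate_edges(c[:-1, :], c[1:, :], geom.x_face_labels, edges)
    _accumulate_edges(c[:, :-1], c[:, 1:], geom.y_face_labels, edges)
    adj: dict[int, set[int]] = {int(i): set() for i in np.unique(c)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def periodic_neighbor_degrees(unit: BasicUnit) -> np.ndarray:
    """Gap-junction degree of each template cell under periodic closure.

    The unit is closed onto a torus: the east seam faces couple column
    ``nx-1`` back to column 0 and the north seam row couples row ``ny-1``
    back to row 0, exactly as in an infinite tiling.
    """
    c = unit.cell_label_grid
    edges: set[tuple[int, int]] = set()
    _accumulate_edges(c[:-1, :], c[1:, :], unit.x_face_labels[:-1, :], edges)
    _accumulate_edges(c[-1:, :], c[:1, :], unit.x_face_labels[-1:, :], edges)
    _accumulate_edges(c[:, :-1], c[:, 1:], unit.y_face_labels[:, :-1], edges)
    _accumulate_edges(c[:, -1:], c[:, :1], unit.y_face_labels[:, -1:], edges)
    deg = np.zeros(unit.n_cells, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def cell_statistics(unit: BasicUnit) -> CellStats:
    """Summary statistics of the designed cell dimensions and connectivity.

    Means and standard deviations (sample SD, n-1 denominator) are taken over
    the 32 continuous pre-raster (length, width) pairs; the mean neighbour
    count comes from the periodic gap-junction adjacency of the unit.
    """
    dims = unit.cell_dims
    deg = periodic_neighbor_degrees(unit)
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return CellStats(
        mean_length=float(np.mean(dims[:, 0])),
        sd_length=sd(dims[:, 0]),
        mean_width=float(np.mean(dims[:, 1])),
        sd_width=sd(dims[:, 1]),
        mean_neighbors=float(np.mean(deg)),
    )
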