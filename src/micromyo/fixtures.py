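"""Small named deterministic geometries for tests and examples."""

from __future__ import annotations

import numpy as np

from .microstructure import ConnectionKind, TissueGeometry

__all__ = ["fixture_geometries"]

_MEM = int(ConnectionKind.MEMBRANE)
_CYT = int(ConnectionKind.CYTOPLASM)
_PLI = int(ConnectionKind.PLICATE)
_INT = int(ConnectionKind.INTERPLICATE)
_COM = int(ConnectionKind.COMBINED_PLICATE)


def _geom(cells, xf, yf):
    return TissueGeometry(
        cell_label_grid=np.asarray(cells, np.int32),
        x_face_labels=np.asarray(xf, np.int8),
        y_face_labels=np.asarray(yf, np.int8),
    )


def fixture_geometries() -> dict[str, TissueGeometry]:
    """Registry of deterministic small meshes.

    - ``chain3``: one cell of 3 volumes in a row (2 cytoplasm faces).
    - ``pair-gap``: two single-volume cells joined by one plicate face.
    - ``pair-membrane``: two single-volume cells with a membrane face only.
    - ``het4x4``: 4 x 4 patch of 4 cells with mixed face labels.
    - ``oracle20``: 20 x 20 patch with seeded pseudo-random labels, used
      against brute-force assembly oracles.
    """
    out: dict[str, TissueGeometry] = {}

    out["chain3"] = _geom(
        [[0], [0], [0]],
        [[_CYT], [_CYT]],
        np.empty((3, 0), np.int8),
    )
    out["pair-gap"] = _geom(
        [[0], [1]], [[_PLI]], np.empty((2, 0), np.int8)
    )
    out["pair-membrane"] = _geom(
        [[0], [1]], [[_MEM]], np.empty((2, 0), np.int8)
    )

    cells = np.zeros((4, 4), np.int32)
    cells[2:, :] = 1
    cells[:2, 2:] = 2
    cells[2:, 2:] = 3
    xf = np.full((3, 4), _CYT, np.int8)
    xf[1, :2] = _PLI
    xf[1, 2:] = _MEM
    yf = np.full((4, 3), _CYT, np.int8)
    yf[:2, 1] = _INT
    yf[2:, 1] = _COM
    out["het4x4"] = _geom(cells, xf, yf)

    rng = np.random.default_rng(20)
    cells = (np.arange(20)[:, None] // 5 * 4 + np.arange(20)[None, :] // 5)
    xf = rng.integers(0, 5, size=(19, 20)).astype(np.int8)
    yf = rng.integers(0, 5, size=(20, 19)).astype(np.int8)
    out["oracle20"] = _geom(cells.astype(np.int32), xf, yf)

    return out
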