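import dataclasses

import numpy as np
import pytest

from micromyo._template_builder import build_template
from micromyo.microstructure import (ConductanceParams, ConnectionKind,
                                     FaceField, TissueGeometry,
                                     assign_face_conductances, build_basic_unit,
                                     cell_statistics, crop, neighbor_graph,
                                     periodic_neighbor_degrees, tile_units)

GJ = {int(ConnectionKind.PLICATE), int(ConnectionKind.INTERPLICATE),
      int(ConnectionKind.COMBINED_PLICATE)}


class TestBasicUnit:
    def test_unit_has_32_cells_on_81x18_grid(self, unit):
        assert unit.n_cells == 32
        assert unit.cell_label_grid.shape == (81, 18)
        assert unit.span_um == (648.0, 144.0)

    def test_every_volume_assigned_and_areas_partition(self, unit):
        areas = np.bincount(unit.cell_label_grid.ravel(), minlength=32)
        assert (areas > 0).all()
        assert areas.sum() == 81 * 18
        # total cell area equals the unit area
        assert areas.sum() * unit.h ** 2 == 648 * 144

    def test_cells_edge_connected_under_periodic_closure(self, unit):
        grid = unit.cell_label_grid
        nx, ny = grid.shape
        for c in range(unit.n_cells):
            mask = grid == c
            idx = np.argwhere(mask)
            seen = {tuple(idx[0])}
            stack = [tuple(idx[0])]
            while stack:
                i, j = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = ((i + di) % nx, (j + dj) % ny)
                    if mask[nb] and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert len(seen) == mask.sum(), f"cell {c} is disconnected"

    def test_face_labels_consistent_with_cell_ownership(self, unit):
        g = unit.cell_label_grid
        # interior x-faces: cytoplasm iff both volumes belong to one cell
        same = g[:-1, :] == g[1:, :]
        xf = unit.x_face_labels[:-1, :]
        assert (xf[same] == int(ConnectionKind.CYTOPLASM)).all()
        assert (xf[~same] != int(ConnectionKind.CYTOPLASM)).all()
        same_y = g[:, :-1] == g[:, 1:]
        yf = unit.y_face_labels[:, :-1]
        assert (yf[same_y] == int(ConnectionKind.CYTOPLASM)).all()
        assert (yf[~same_y] != int(ConnectionKind.CYTOPLASM)).all()

    def test_plicate_on_ends_interplicate_on_lateral_borders(self, unit):
        # longitudinal (x) inter-cell faces only carry plicate junctions;
        # lateral (y) inter-cell faces only interplicate / combined plicate
        g = unit.cell_label_grid
        xf = unit.x_face_labels[:-1, :][g[:-1, :] != g[1:, :]]
        assert set(np.unique(xf[np.isin(xf, list(GJ))])) == {
            int(ConnectionKind.PLICATE)}
        yf = unit.y_face_labels[:, :-1][g[:, :-1] != g[:, 1:]]
        lateral = set(np.unique(yf[np.isin(yf, list(GJ))]))
        assert lateral == {int(ConnectionKind.INTERPLICATE),
                           int(ConnectionKind.COMBINED_PLICATE)}

    def test_determinism_and_builder_provenance(self, unit):
        again = build_basic_unit()
        for f in ("cell_label_grid", "x_face_labels", "y_face_labels",
                  "cell_dims"):
            assert (getattr(unit, f) == getattr(again, f)).all()
        built = build_template()
        assert (built.cell_label_grid == unit.cell_label_grid).all()
        assert (built.x_face_labels == unit.x_face_labels).all()
        assert (built.y_face_labels == unit.y_face_labels).all()
        assert np.allclose(built.cell_dims, unit.cell_dims, rtol=0, atol=1e-12)


class TestCellStatistics:
    def test_shipped_unit_matches_reference_morphometry(self, unit):
        st = cell_statistics(unit)
        assert st.mean_length == pytest.approx(120.9, abs=0.05)
        assert st.sd_length == pytest.approx(27.8, abs=0.05)
        assert st.mean_width == pytest.approx(18.3, abs=0.05)
        assert st.sd_width == pytest.approx(3.5, abs=0.05)
        assert st.mean_neighbors == pytest.approx(6.0, abs=1e-12)

    def test_every_cell_has_six_gap_junction_neighbors(self, unit):
        assert (periodic_neighbor_degrees(unit) == 6).all()

    def test_zero_variance_for_identical_cells(self, unit):
        clone = dataclasses.replace(
            unit, cell_dims=np.full((32, 2), [100.0, 20.0]))
        st = cell_statistics(clone)
        assert st.sd_length == 0.0 and st.sd_width == 0.0
        assert st.mean_length == 100.0 and st.mean_width == 20.0

    def test_two_cell_mean_is_arithmetic(self, unit):
        dims = unit.cell_dims.copy()
        dims[:16, 0] = 100.0
        dims[16:, 0] = 140.0
        st = cell_statistics(dataclasses.replace(unit, cell_dims=dims))
        assert st.mean_length == pytest.approx(120.0)


class TestTiling:
    def test_identity_tiling_reproduces_the_unit(self, unit):
        g = tile_units(unit, 1, 1)
        assert (g.cell_label_grid == unit.cell_label_grid).all()
        assert (g.x_face_labels == unit.x_face_labels[:-1, :]).all()
        assert (g.y_face_labels == unit.y_face_labels[:, :-1]).all()

    def test_2x3_tiling_counts(self, unit):
        g = tile_units(unit, 2, 3)
        assert (g.nx, g.ny) == (162, 54)
        assert len(np.unique(g.cell_label_grid)) == 192

    def test_2x1_longitudinal_span(self, unit):
        g = tile_units(unit, 2, 1)
        assert g.nx * g.h == 1296.0

    def test_seam_faces_carry_gap_junctions_not_only_membrane(self, unit):
        g = tile_units(unit, 2, 2)
        seam_x = g.x_face_labels[80, :]        # between copy columns
        assert np.isin(seam_x, list(GJ)).any()
        seam_y = g.y_face_labels[:, 17]        # between copy rows
        assert np.isin(seam_y, list(GJ)).any()

    def test_tiling_preserves_per_copy_areas(self, unit):
        g = tile_units(unit, 2, 3)
        base = np.bincount(unit.cell_label_grid.ravel(), minlength=32)
        areas = np.bincount(g.cell_label_grid.ravel())
        assert (areas.reshape(6, 32) == base).all()

    def test_nonpositive_counts_rejected(self, unit):
        with pytest.raises(ValueError):
            tile_units(unit, 0, 1)

    def test_crop_keeps_lower_left_block(self, unit):
        g = tile_units(unit, 1, 4)
        c = crop(g, 62, 62)
        assert (c.nx, c.ny) == (62, 62)
        assert (c.cell_label_grid == g.cell_label_grid[:62, :62]).all()
        with pytest.raises(ValueError):
            crop(g, 0, 10)
        with pytest.raises(ValueError):
            crop(g, 1000, 10)


class TestFaceConductances:
    def test_label_to_conductivity_map(self, unit):
        p = ConductanceParams()
        assert p.face_value(ConnectionKind.MEMBRANE) == 0.0
        assert p.face_value(ConnectionKind.CYTOPLASM) == 0.4
        assert p.face_value(ConnectionKind.PLICATE) == pytest.approx(0.05)
        assert p.face_value(ConnectionKind.INTERPLICATE) == pytest.approx(0.033)
        assert p.face_value(ConnectionKind.COMBINED_PLICATE) == pytest.approx(0.0062)

    def test_assignment_covers_all_faces(self, unit):
        g = tile_units(unit, 2, 1)
        ff = assign_face_conductances(g)
        assert ff.sigma_x.shape == (g.nx - 1, g.ny)
        assert ff.sigma_y.shape == (g.nx, g.ny - 1)
        assert (ff.sigma_x >= 0).all() and (ff.sigma_y >= 0).all()

    def test_unknown_label_rejected(self, geoms):
        g = geoms["chain3"]
        bad = TissueGeometry(
            cell_label_grid=g.cell_label_grid,
            x_face_labels=np.full_like(g.x_face_labels, 7),
            y_face_labels=g.y_face_labels,
        )
        with pytest.raises(ValueError, match="unknown connection label"):
            assign_face_conductances(bad)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            ConductanceParams(sigma_c=-1.0)


class TestNeighborGraph:
    def test_gap_junction_pair_is_adjacent(self, geoms):
        adj = neighbor_graph(geoms["pair-gap"])
        assert adj == {0: {1}, 1: {0}}

    def test_membrane_contact_is_not_adjacency(self, geoms):
        adj = neighbor_graph(geoms["pair-membrane"])
        assert adj == {0: set(), 1: set()}

    def test_interior_tissue_mean_degree_approaches_six(self, unit):
        # finite sheets lose adjacency at the boundary; a larger tiling
        # should approach (from below) the periodic value of 6
        small = np.mean([len(v) for v in neighbor_graph(tile_units(unit, 2, 2)).values()])
        big = np.mean([len(v) for v in neighbor_graph(tile_units(unit, 4, 4)).values()])
        assert small < big < 6.0
        assert big > 5.5
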