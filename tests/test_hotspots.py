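import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialih import hotspots as hs
from spatialih.celltable import make_cell_table

from conftest import label_map_from_names


def cells_from_xy(x, y, label="cancer"):
    return make_cell_table(np.asarray(x, float), np.asarray(y, float),
                           np.full(len(x), label))


class TestRasterize:
    def test_single_cell_binned_to_origin_grid(self):
        spec = hs.GridSpec(0, 0, 50, 2, 2)
        lat = hs.rasterize(cells_from_xy([25.0], [25.0]), spec)
        assert lat.cancer[0, 0] == 1
        assert lat.cancer.sum() == 1
        assert lat.tissue[0, 0]

    def test_half_open_boundary_goes_to_upper_bin(self):
        spec = hs.GridSpec(0, 0, 50, 2, 2)
        lat = hs.rasterize(cells_from_xy([50.0], [25.0]), spec)
        assert lat.cancer[0, 1] == 1
        assert lat.cancer[0, 0] == 0

    def test_channel_sums_conserved_against_bruteforce(self):
        rng = np.random.default_rng(0)
        n = 1000
        x = rng.uniform(0, 500, n)
        y = rng.uniform(0, 500, n)
        labels = rng.choice(["cancer", "lymphocyte", "stromal"], n)
        cells = make_cell_table(x, y, labels)
        spec = hs.GridSpec.from_cells(cells)
        lat = hs.rasterize(cells, spec)
        assert lat.cancer.sum() == np.sum(labels == "cancer")
        assert lat.lymphocyte.sum() == np.sum(labels == "lymphocyte")
        # brute-force per-cell binning
        expect_c = np.zeros(spec.shape, int)
        expect_l = np.zeros(spec.shape, int)
        for xi, yi, li in zip(x, y, labels):
            r = int((yi - spec.y0) // spec.g)
            c = int((xi - spec.x0) // spec.g)
            if li == "cancer":
                expect_c[r, c] += 1
            elif li == "lymphocyte":
                expect_l[r, c] += 1
        np.testing.assert_array_equal(lat.cancer, expect_c)
        np.testing.assert_array_equal(lat.lymphocyte, expect_l)

    def test_out_of_bounds_cells_rejected_with_count(self):
        spec = hs.GridSpec(0, 0, 50, 2, 2)
        with pytest.raises(ValueError, match="2 cells"):
            hs.rasterize(cells_from_xy([25, 150, 160], [25, 25, 25]), spec)

    def test_stromal_counts_tissue_but_no_channel(self):
        spec = hs.GridSpec(0, 0, 50, 1, 1)
        lat = hs.rasterize(cells_from_xy([10.0], [10.0], "stromal"), spec)
        assert lat.tissue[0, 0]
        assert lat.cancer.sum() == 0 and lat.lymphocyte.sum() == 0


class TestNeighbors:
    def test_interior_order1_excl_self_has_8(self):
        spec = hs.GridSpec(0, 0, 50, 10, 10)
        w = hs.build_neighbors(spec, max_order=1, include_self=False)
        assert len(w.neighbor_indices(5, 5)) == 8

    def test_interior_order4_excl_self_has_80(self):
        spec = hs.GridSpec(0, 0, 50, 20, 20)
        w = hs.build_neighbors(spec, max_order=4, include_self=False)
        nbrs = w.neighbor_indices(10, 10)
        assert len(nbrs) == 80
        # enumeration oracle over the 9x9 window
        expected = {
            (r, c)
            for r in range(6, 15)
            for c in range(6, 15)
            if (r, c) != (10, 10)
        }
        assert set(nbrs) == expected

    def test_corner_order1_excl_self_has_3(self):
        spec = hs.GridSpec(0, 0, 50, 10, 10)
        w = hs.build_neighbors(spec, max_order=1, include_self=False)
        assert len(w.neighbor_indices(0, 0)) == 3

    def test_include_self_adds_focal_grid(self):
        spec = hs.GridSpec(0, 0, 50, 10, 10)
        w = hs.build_neighbors(spec, max_order=1, include_self=True)
        assert (5, 5) in w.neighbor_indices(5, 5)
        assert len(w.neighbor_indices(5, 5)) == 9

    def test_symmetry(self):
        spec = hs.GridSpec(0, 0, 50, 8, 8)
        w = hs.build_neighbors(spec, max_order=2, include_self=False)
        for i in [(0, 0), (3, 4), (7, 7)]:
            for j in w.neighbor_indices(*i):
                assert i in w.neighbor_indices(*j)

    def test_bad_order_rejected(self):
        spec = hs.GridSpec(0, 0, 50, 4, 4)
        with pytest.raises(ValueError):
            hs.build_neighbors(spec, max_order=0)


def random_lattice(rng, max_side=30, p_tissue=0.8):
    nr = int(rng.integers(5, max_side + 1))
    nc = int(rng.integers(5, max_side + 1))
    spec = hs.GridSpec(0, 0, 50, nc, nr)
    counts = rng.poisson(2.0, size=(nr, nc))
    tissue = rng.uniform(size=(nr, nc)) < p_tissue
    counts[~tissue] = 0
    return hs.CountLattice(spec, counts, np.zeros_like(counts), tissue)


class TestGetisOrd:
    def test_zero_variance_degenerate(self):
        spec = hs.GridSpec(0, 0, 50, 5, 5)
        counts = np.full((5, 5), 3)
        lat = hs.CountLattice(spec, counts, counts.copy(), np.ones((5, 5), bool))
        z, p = hs.getis_ord(lat, hs.build_neighbors(spec), "cancer")
        assert np.isnan(z).all() and np.isnan(p).all()
        lm = hs.label_compartments(lat, hs.build_neighbors(spec))
        assert (lm.labels == hs.NONE_LABEL).all()
        assert lm.metadata["degenerate"]

    def test_center_spike_matches_loop_oracle(self):
        spec = hs.GridSpec(0, 0, 50, 21, 21)
        counts = np.zeros((21, 21), dtype=np.int64)
        counts[10, 10] = 100
        lat = hs.CountLattice(spec, counts, np.zeros_like(counts), np.ones((21, 21), bool))
        w = hs.build_neighbors(spec, 4, include_self=True)
        z, p = hs.getis_ord(lat, w, "cancer")
        z_loop = hs.getis_ord_loop(lat, w, "cancer")
        np.testing.assert_allclose(z[10, 10], z_loop[10, 10], atol=1e-9)
        assert z[10, 10] > 0
        # independent closed-form check at the center grid (full 9x9 window)
        n = 21 * 21
        vals = counts.ravel().astype(float)
        xbar, S = vals.mean(), vals.std()
        wsum = 81.0
        expected = (100.0 - xbar * wsum) / (
            S * np.sqrt((n * wsum - wsum**2) / (n - 1))
        )
        np.testing.assert_allclose(z[10, 10], expected, atol=1e-9)

    @pytest.mark.parametrize("include_self", [True, False])
    def test_loop_oracle_equivalence_random(self, include_self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            lat = random_lattice(rng)
            if lat.cancer[lat.tissue].std() == 0 or lat.tissue.sum() < 2:
                continue
            w = hs.build_neighbors(lat.spec, 4, include_self)
            z, _ = hs.getis_ord(lat, w, "cancer")
            z_loop = hs.getis_ord_loop(lat, w, "cancer")
            np.testing.assert_allclose(z, z_loop, atol=1e-9, equal_nan=True)

    def test_invariant_to_zero_nontissue_border(self):
        rng = np.random.default_rng(3)
        lat = random_lattice(rng, max_side=15)
        w = hs.build_neighbors(lat.spec, 4)
        z, _ = hs.getis_ord(lat, w, "cancer")
        pad = 3
        spec2 = hs.GridSpec(0, 0, 50, lat.spec.n_cols + 2 * pad, lat.spec.n_rows + 2 * pad)
        lat2 = hs.CountLattice(
            spec2,
            np.pad(lat.cancer, pad),
            np.pad(lat.lymphocyte, pad),
            np.pad(lat.tissue, pad),
        )
        z2, _ = hs.getis_ord(lat2, hs.build_neighbors(spec2, 4), "cancer")
        np.testing.assert_allclose(
            z2[pad:-pad, pad:-pad], z, atol=1e-9, equal_nan=True
        )

    def test_monotone_in_own_count(self):
        rng = np.random.default_rng(11)
        spec = hs.GridSpec(0, 0, 50, 15, 15)
        counts = rng.poisson(2.0, size=(15, 15))
        lat = hs.CountLattice(spec, counts, np.zeros_like(counts), np.ones((15, 15), bool))
        w = hs.build_neighbors(lat.spec, 4)
        tissue_idx = np.argwhere(lat.tissue)
        r, c = tissue_idx[len(tissue_idx) // 2]
        z1, _ = hs.getis_ord(lat, w, "cancer")
        bumped = lat.cancer.copy()
        bumped[r, c] += 5
        lat2 = hs.CountLattice(lat.spec, bumped, lat.lymphocyte, lat.tissue)
        z2, _ = hs.getis_ord(lat2, w, "cancer")
        assert z2[r, c] >= z1[r, c] - 1e-12

    def test_too_few_tissue_grids_rejected(self):
        spec = hs.GridSpec(0, 0, 50, 3, 3)
        lat = hs.CountLattice(
            spec, np.zeros((3, 3), int), np.zeros((3, 3), int), np.zeros((3, 3), bool)
        )
        with pytest.raises(ValueError):
            hs.getis_ord(lat, hs.build_neighbors(spec), "cancer")


class TestLabels:
    @pytest.mark.parametrize(
        "p_c,p_l,expected",
        [
            (0.01, 0.20, hs.CH),
            (0.20, 0.01, hs.IH_PERI),
            (0.01, 0.01, hs.IH_INTRA),
            (0.20, 0.20, hs.NONE_LABEL),
            (0.05, 0.01, hs.IH_PERI),  # tie at alpha is non-significant
            (0.05, 0.05, hs.NONE_LABEL),
        ],
    )
    def test_truth_table(self, p_c, p_l, expected):
        spec = hs.GridSpec(0, 0, 50, 1, 1)
        one = np.array([[0.0]])
        tissue = np.array([[True]])
        lm = hs.label_from_pvalues(
            spec, one, one, np.array([[p_c]]), np.array([[p_l]]), tissue
        )
        assert lm.labels[0, 0] == expected

    def test_non_tissue_grids_are_none_with_nan_z(self, nest_slide_config):
        from spatialih import synthetic as syn

        cells = syn.generate_slide(nest_slide_config)
        spec = hs.GridSpec.from_cells(cells)
        lat = hs.rasterize(cells, spec)
        lm = hs.label_compartments(lat, hs.build_neighbors(spec))
        assert (lm.labels[~lm.tissue] == hs.NONE_LABEL).all()
        assert np.isnan(lm.z_cancer[~lm.tissue]).all()

    def test_partition_of_tissue(self, nest_slide_config):
        from spatialih import synthetic as syn

        cells = syn.generate_slide(nest_slide_config)
        spec = hs.GridSpec.from_cells(cells)
        lat = hs.rasterize(cells, spec)
        lm = hs.label_compartments(lat, hs.build_neighbors(spec))
        counts = lm.label_counts()
        n_none_tissue = int(np.sum((lm.labels == hs.NONE_LABEL) & lm.tissue))
        assert (
            counts["CH"] + counts["IH_peri"] + counts["IH_intra"] + n_none_tissue
            == int(lm.tissue.sum())
        )


class TestScores:
    def test_hand_computed_fractions(self):
        names = np.full((10, 10), "NONE", dtype=object)
        names.ravel()[:2] = "IH_intra"
        names.ravel()[2:8] = "IH_peri"
        names.ravel()[8:16] = "CH"
        lm = label_map_from_names(names)
        s = hs.spatial_scores(lm)
        assert s.s_intra_immune == 0.25
        assert s.s_intra_cancer == 0.20
        assert s.s_intra_tissue == 0.02

    def test_zero_numerator(self):
        names = np.full((4, 4), "NONE", dtype=object)
        names[0, :2] = "IH_peri"
        s = hs.spatial_scores(label_map_from_names(names))
        assert s.s_intra_immune == 0.0

    def test_saturation(self):
        names = np.full((4, 4), "NONE", dtype=object)
        names[0, :2] = "IH_intra"
        s = hs.spatial_scores(label_map_from_names(names))
        assert s.s_intra_immune == 1.0

    def test_zero_denominator_returns_none_with_reason(self):
        names = np.full((4, 4), "NONE", dtype=object)
        s = hs.spatial_scores(label_map_from_names(names))
        assert s.s_intra_immune is None
        assert "s_intra_immune" in s.notes
        assert s.s_intra_tissue == 0.0

    def test_no_tissue_is_error(self):
        lm = label_map_from_names(np.full((3, 3), "NONE", dtype=object))
        lm.tissue[:] = False
        with pytest.raises(ValueError):
            hs.spatial_scores(lm)

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(1, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_scores_in_unit_interval(self, n_intra, n_peri, n_ch, n_extra):
        total = n_intra + n_peri + n_ch + n_extra
        side = int(np.ceil(np.sqrt(total)))
        names = np.full(side * side, "NONE", dtype=object)
        names[:n_intra] = "IH_intra"
        names[n_intra:n_intra + n_peri] = "IH_peri"
        names[n_intra + n_peri:n_intra + n_peri + n_ch] = "CH"
        s = hs.spatial_scores(label_map_from_names(names.reshape(side, side)))
        for val in (s.s_intra_immune, s.s_intra_cancer, s.s_intra_tissue):
            if val is not None:
                assert 0.0 <= val <= 1.0
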