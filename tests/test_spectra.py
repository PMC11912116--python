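"""Peak/grid data model, CSV round-trips, binning, and conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrflow import (
    GridSpectrum,
    PeakSpectrum,
    bin_grid,
    grid_to_peaks,
    read_grid,
    read_library_manifest,
    read_peaklist,
    scale_spectrum,
    total_weight,
    write_grid,
    write_library_manifest,
    write_peaklist,
)
from nmrflow.spectra import FormatError

from conftest import make_entry, make_spectrum
from nmrflow import CompoundLibrary


class TestPeakSpectrum:
    def test_total_weight_empty_spectrum_is_zero(self):
        empty = PeakSpectrum(id="e", dim=2, positions=np.empty((0, 2)), weights=[])
        assert total_weight(empty) == 0.0

    def test_total_weight_sums_peak_weights(self):
        assert total_weight(make_spectrum([[1, 2], [3, 4]], [2, 3])) == 5.0

    @pytest.mark.parametrize("factor,expected", [(1.0, [2, 3]), (0.0, [0, 0]), (0.5, [1, 1.5])])
    def test_scale_multiplies_weights_only(self, factor, expected):
        s = make_spectrum([[1, 2], [3, 4]], [2, 3])
        scaled = scale_spectrum(s, factor)
        assert np.array_equal(scaled.positions, s.positions)
        assert np.allclose(scaled.weights, expected)

    def test_scale_rejects_negative_factor(self):
        with pytest.raises(ValueError):
            scale_spectrum(make_spectrum([[1, 2]], [1]), -0.5)

    @given(st.floats(0, 100), st.lists(st.floats(0, 1e6), min_size=1, max_size=30))
    def test_scaling_is_linear_in_total_weight(self, a, weights):
        s = make_spectrum([[float(i), 0.0] for i in range(len(weights))], weights)
        assert total_weight(scale_spectrum(s, a)) == pytest.approx(
            a * total_weight(s), rel=1e-12, abs=1e-300
        )

    def test_rejects_negative_weights_and_bad_dim(self):
        with pytest.raises(ValueError):
            make_spectrum([[1, 2]], [-1.0])
        with pytest.raises(ValueError):
            PeakSpectrum(id="x", dim=3, positions=[[1, 2]], weights=[1.0])


class TestPeaklistIO:
    def test_parse_two_row_file(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("shift_1,shift_2,weight\n1.0,20.0,2.0\n3.0,50.0,1.5\n")
        s = read_peaklist(p, dim=2)
        assert s.n_peaks == 2 and s.total_weight == 3.5
        assert np.allclose(s.positions, [[1, 20], [3, 50]])

    def test_empty_data_section_gives_empty_spectrum(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("shift_1,shift_2,weight\n")
        assert read_peaklist(p, dim=2).n_peaks == 0

    def test_round_trip_random_spectrum(self, tmp_path):
        rng = np.random.default_rng(7)
        s = make_spectrum(
            np.column_stack([rng.uniform(0, 10, 100), rng.uniform(0, 160, 100)]),
            rng.uniform(0, 5, 100),
            id="s",
        )
        path = tmp_path / "s.csv"
        write_peaklist(s, path)
        assert read_peaklist(path, dim=2, id="s") == s

    @pytest.mark.parametrize(
        "body,msg",
        [
            ("shift_1,weight\n1.0,1.0\n", "missing columns"),
            ("shift_1,shift_2,weight\n1.0,2.0,-1.0\n", "row 2"),
            ("shift_1,shift_2,weight\n1.0,2.0,1.0\n1.0,oops,1.0\n", "row 3"),
        ],
    )
    def test_malformed_files_rejected_with_row(self, tmp_path, body, msg):
        p = tmp_path / "bad.csv"
        p.write_text(body)
        with pytest.raises(FormatError, match=msg):
            read_peaklist(p, dim=2)


class TestGridIO:
    def test_matrix_layout_with_axis_headers(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",10.0,20.0\n1.0,1,2\n2.0,3,4\n3.0,5,6\n")
        g = read_grid(p)
        assert g.shape == (3, 2)
        assert np.allclose(g.axes[0], [1, 2, 3])
        assert np.allclose(g.values, [[1, 2], [3, 4], [5, 6]])

    def test_single_row_grid_accepted(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",10.0,20.0,30.0\n5.0,1,2,3\n")
        assert read_grid(p).shape == (1, 3)

    def test_round_trip_random_grid(self, tmp_path):
        rng = np.random.default_rng(8)
        g = GridSpectrum(
            axes=(np.sort(rng.uniform(0, 10, 64)), np.sort(rng.uniform(0, 160, 64))[::-1]),
            values=rng.normal(size=(64, 64)),
        )
        path = tmp_path / "g.csv"
        write_grid(g, path)
        assert read_grid(path) == g

    def test_1d_round_trip(self, tmp_path):
        g = GridSpectrum(axes=(np.array([1.0, 2.0, 3.0]),), values=np.array([0.5, -1.0, 2.0]))
        path = tmp_path / "g1.csv"
        write_grid(g, path)
        assert read_grid(path) == g

    def test_non_monotone_axis_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",10.0,10.0\n1.0,1,2\n")
        with pytest.raises(FormatError):
            read_grid(p)


class TestBinGrid:
    def test_sum_pooling_4x4_to_2x2(self):
        g = GridSpectrum(axes=(np.arange(4.0), np.arange(4.0)), values=np.ones((4, 4)))
        b = bin_grid(g, (2, 2))
        assert np.allclose(b.values, 4.0)
        assert b.values.sum() == g.values.sum()
        assert np.allclose(b.axes[0], [0.5, 2.5])

    def test_identity_shape_is_unchanged(self):
        g = GridSpectrum(axes=(np.arange(3.0), np.arange(5.0)),
                         values=np.arange(15.0).reshape(3, 5))
        assert bin_grid(g, (3, 5)) == g

    def test_remainder_cells_merge_into_last_bin(self):
        rng = np.random.default_rng(3)
        g = GridSpectrum(axes=(np.arange(10.0), np.arange(6.0)),
                         values=rng.uniform(size=(10, 6)))
        b = bin_grid(g, (3, 2))
        assert b.shape == (3, 2)
        # 10 -> bins of 3,3,4 cells: last bin absorbs the remainder
        assert b.values[2, :].sum() == pytest.approx(g.values[6:, :].sum(), rel=1e-12)
        assert b.values.sum() == pytest.approx(g.values.sum(), rel=1e-12)

    def test_invalid_target_shapes_rejected(self):
        g = GridSpectrum(axes=(np.arange(4.0),), values=np.ones(4))
        with pytest.raises(ValueError):
            bin_grid(g, (5,))
        with pytest.raises(ValueError):
            bin_grid(g, (0,))

    def test_descending_axis_direction_preserved(self):
        g = GridSpectrum(axes=(np.array([8.0, 6.0, 4.0, 2.0]),), values=np.ones(4))
        b = bin_grid(g, (2,))
        assert b.axes[0][0] > b.axes[0][1]


class TestGridToPeaks:
    def test_all_zero_grid_gives_empty_spectrum(self):
        g = GridSpectrum(axes=(np.arange(3.0),), values=np.zeros(3))
        assert grid_to_peaks(g).n_peaks == 0

    @pytest.mark.parametrize("floor,expected", [(0.0, [2.0, 5.0]), (3.0, [5.0])])
    def test_floor_filters_values(self, floor, expected):
        g = GridSpectrum(axes=(np.arange(4.0),), values=np.array([-1.0, 0.0, 2.0, 5.0]))
        s = grid_to_peaks(g, floor=floor)
        assert sorted(s.weights) == expected
        assert np.all(s.weights >= 0)

    def test_peak_positions_are_grid_coordinates(self):
        g = GridSpectrum(axes=(np.array([1.0, 2.0]), np.array([10.0, 20.0])),
                         values=np.array([[1.0, 0.0], [0.0, 2.0]]))
        s = grid_to_peaks(g)
        assert set(map(tuple, s.positions)) == {(1.0, 10.0), (2.0, 20.0)}

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_intensity_conservation_through_bin_and_convert(self, seed):
        rng = np.random.default_rng(seed)
        # nonnegative intensities: conversion may never emit negative weights
        g = GridSpectrum(axes=(np.arange(12.0), np.arange(7.0)),
                         values=rng.uniform(size=(12, 7)))
        binned = bin_grid(g, (5, 3))
        peaks = grid_to_peaks(binned, floor=-np.inf)
        assert peaks.total_weight == pytest.approx(g.values.sum(), rel=1e-12, abs=1e-12)


class TestLibrary:
    def test_manifest_round_trip(self, tmp_path):
        lib = CompoundLibrary(entries=(
            make_entry("ala", [[1.4, 17.0], [3.7, 51.0]], [2.0, 1.0]),
            make_entry("glc", [[5.2, 93.0]], [1.5], ref_conc=10.0),
        ))
        manifest = write_library_manifest(lib, tmp_path / "lib")
        back = read_library_manifest(manifest, dim=2)
        assert back.compound_ids == ["ala", "glc"]
        for a, b in zip(lib, back):
            assert a.spectrum == b.spectrum
            assert a.ref_concentration == b.ref_concentration

    def test_library_invariants_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            CompoundLibrary(entries=(
                make_entry("x", [[1, 2]], [1.0]), make_entry("x", [[2, 3]], [1.0]),
            ))
        with pytest.raises(ValueError, match="positive total weight"):
            CompoundLibrary(entries=(make_entry("x", [[1, 2]], [0.0]),))
        with pytest.raises(ValueError):
            make_entry("x", [[1, 2]], [1.0], ref_conc=0.0)
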