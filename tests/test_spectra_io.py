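"""Data model, channel-wavelength mapping, and table dialect round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drainspec.io import (
    parse_decimal,
    read_lab_table,
    read_spectra_table,
    write_lab_table,
    write_spectra_long,
    write_spectra_wide,
    write_supplement_workbook,
)
from drainspec.spectra import (
    ANALYTES,
    N_CHANNELS,
    LabPanel,
    SpectralCube,
    SpectraValidationError,
    WavelengthGrid,
    map_channel_to_wavelength,
)


class TestWavelengthMapping:
    @pytest.mark.parametrize(
        "channel,expected",
        [(0, 340.0), (287, 850.0), (143, 340.0 + 143 * 510.0 / 287.0)],
    )
    def test_linear_grid_values(self, channel, expected):
        assert map_channel_to_wavelength(channel, "linear") == pytest.approx(expected)

    def test_linear_grid_monotone_and_spans_range(self):
        grid = WavelengthGrid.linear()
        assert np.all(np.diff(grid.wavelengths) > 0)
        assert grid.wavelengths[0] == 340.0
        assert grid.wavelengths[-1] == 850.0

    def test_out_of_range_channel_rejected(self):
        with pytest.raises(IndexError):
            map_channel_to_wavelength(288, "linear")

    def test_wrong_length_calibration_rejected(self):
        with pytest.raises(SpectraValidationError):
            map_channel_to_wavelength(0, [340.0, 850.0])

    def test_explicit_calibration_overrides_linear(self):
        wl = np.linspace(350, 840, N_CHANNELS)
        assert map_channel_to_wavelength(10, wl) == pytest.approx(wl[10])

    def test_nearest_channel_resolves_reported_wavelengths(self):
        grid = WavelengthGrid.linear()
        ch = grid.nearest_channel(586.0)
        assert abs(grid[ch] - 586.0) <= 510.0 / 287.0 / 2 + 1e-9


class TestCubeInvariants:
    def test_intensity_above_ceiling_rejected(self):
        vec = np.full(N_CHANNELS, 100.0)
        vec[7] = 70000.0
        with pytest.raises(SpectraValidationError, match="channel"):
            SpectralCube("s1", "p1", {"DT": vec})

    def test_empty_patient_id_rejected(self):
        with pytest.raises(SpectraValidationError, match="patient"):
            SpectralCube("s1", "", {"DT": np.zeros(N_CHANNELS)})

    def test_unknown_pathway_rejected(self):
        with pytest.raises(SpectraValidationError, match="pathway"):
            SpectralCube("s1", "p1", {"XX": np.zeros(N_CHANNELS)})

    def test_missing_pathways_flagged_not_fatal(self):
        cube = SpectralCube("s1", "p1", {"DT": np.zeros(N_CHANNELS)})
        assert cube.missing_pathways == ("AT", "AR")


class TestRoundTrips:
    @pytest.fixture()
    def cohort(self, small_cohort):
        cubes, panels, _ = small_cohort
        return cubes[:5], panels[:5]

    def test_long_csv_round_trip_bit_exact(self, cohort, tmp_path):
        cubes, _ = cohort
        path = tmp_path / "long.csv"
        write_spectra_long(cubes, path)
        back = read_spectra_table(path, dialect="canonical_csv")
        assert len(back) == len(cubes)
        for a, b in zip(cubes, back):
            assert a.sample_id == b.sample_id and a.patient_id == b.patient_id
            for pw in a.pathway_spectra:
                np.testing.assert_array_equal(a.pathway_spectra[pw], b.pathway_spectra[pw])

    def test_wide_csv_round_trip_bit_exact(self, cohort, tmp_path):
        cubes, _ = cohort
        path = tmp_path / "wide.csv"
        write_spectra_wide(cubes, path)
        back = read_spectra_table(path, dialect="canonical_wide")
        for a, b in zip(cubes, back):
            for pw in a.pathway_spectra:
                np.testing.assert_array_equal(a.pathway_spectra[pw], b.pathway_spectra[pw])

    def test_supplement_workbook_round_trip(self, cohort, tmp_path):
        cubes, panels = cohort
        path = tmp_path / "s3.xlsx"
        write_supplement_workbook(cubes, panels, path)
        back_cubes = read_spectra_table(path, dialect="supplement_xlsx")
        back_panels = read_lab_table(path, dialect="supplement_xlsx")
        assert [c.patient_id for c in back_cubes] == [c.patient_id for c in cubes]
        for a, b in zip(cubes, back_cubes):
            for pw in a.pathway_spectra:
                np.testing.assert_allclose(a.pathway_spectra[pw], b.pathway_spectra[pw])
        for pa, pb in zip(panels, back_panels):
            assert pa.values == pytest.approx(pb.values)

    def test_out_of_range_intensity_names_sample_and_channel(self, tmp_path):
        vec = np.full(N_CHANNELS, 10.0)
        cube = SpectralCube("bad_sample", "p1", {"DT": vec})
        path = tmp_path / "long.csv"
        write_spectra_long([cube], path)
        df = pd.read_csv(path)
        df.loc[df["channel"] == 42, "intensity"] = 70000.0
        df.to_csv(path, index=False)
        with pytest.raises(SpectraValidationError, match=r"bad_sample.*42"):
            read_spectra_table(path, dialect="canonical_csv")
        clipped = read_spectra_table(path, dialect="canonical_csv", on_range_error="clip")
        assert clipped[0].intensity("DT", 42) == 65000.0

    def test_duplicate_channel_rejected(self, tmp_path):
        cube = SpectralCube("s1", "p1", {"DT": np.full(N_CHANNELS, 1.0)})
        path = tmp_path / "long.csv"
        write_spectra_long([cube], path)
        df = pd.read_csv(path)
        df.loc[1, "channel"] = 0
        df.to_csv(path, index=False)
        with pytest.raises(SpectraValidationError, match="duplicate"):
            read_spectra_table(path, dialect="canonical_csv")


class TestLabTable:
    def test_decimal_comma_parsed(self):
        assert parse_decimal("1,2") == 1.2
        assert parse_decimal("3,8") == 3.8
        assert np.isnan(parse_decimal(""))

    def test_missing_cell_stays_missing(self, tmp_path):
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "bilirubin": [1.5, np.nan], "hemoglobin": [0.0, 2.0]}
        )
        path = tmp_path / "lab.csv"
        df.to_csv(path, index=False)
        panels = read_lab_table(path)
        assert panels[1].is_missing("bilirubin")
        assert panels[0].get("bilirubin") == 1.5
        assert panels[0].get("hemoglobin") == 0.0  # zero is a value, not missing

    def test_negative_lab_value_rejected(self, tmp_path):
        pd.DataFrame({"sample_id": ["a"], "glucose": [-1.0]}).to_csv(
            tmp_path / "lab.csv", index=False
        )
        with pytest.raises(SpectraValidationError, match="negative"):
            read_lab_table(tmp_path / "lab.csv")

    def test_unknown_analyte_column_warned_and_ignored(self, tmp_path):
        pd.DataFrame({"sample_id": ["a"], "specific_gravity": [1.01]}).to_csv(
            tmp_path / "lab.csv", index=False
        )
        with pytest.warns(UserWarning, match="unknown analyte"):
            panels = read_lab_table(tmp_path / "lab.csv")
        assert panels[0].values == {}

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(
            st.one_of(st.none(), st.floats(0, 1e4, allow_nan=False)),
            min_size=14,
            max_size=14,
        )
    )
    def test_blanked_cells_never_become_numbers(self, values, tmp_path_factory):
        """Randomly blanked lab cells must come back missing, never 0."""
        path = tmp_path_factory.mktemp("lab") / "lab.csv"
        row = dict(zip(ANALYTES, values))
        pd.DataFrame([{"sample_id": "s", **row}]).to_csv(path, index=False)
        panel = read_lab_table(path)[0]
        for analyte, value in row.items():
            if value is None:
                assert panel.is_missing(analyte)
            else:
                assert panel.get(analyte) == pytest.approx(value)

    def test_panel_rejects_nan_value(self):
        with pytest.raises(SpectraValidationError):
            LabPanel("s", {"glucose": float("nan")})
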