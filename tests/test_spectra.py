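import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind import (
    Spectrum,
    correct_inner_filter,
    find_peaks,
    read_spectrum_csv,
    resample_to_grid,
    second_derivative,
    write_spectrum_csv,
)
from tests.conftest import gaussian_spectrum_values


class TestSpectrumInvariants:
    def test_rejects_decreasing_wavelengths(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum([300, 299, 301], [1, 2, 3])

    def test_rejects_length_mismatch_and_short(self):
        with pytest.raises(ValueError, match="length mismatch"):
            Spectrum([300, 301], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 2"):
            Spectrum([300], [1])

    def test_rejects_negative_absorbance_and_nonfinite(self):
        with pytest.raises(ValueError, match="absorbance"):
            Spectrum([300, 301], [0.1, -0.1], kind="absorbance")
        with pytest.raises(ValueError, match="finite"):
            Spectrum([300, 301], [1.0, np.nan])


class TestCsvIO:
    def test_reads_two_column_file_with_header(self, tmp_path):
        p = tmp_path / "em.csv"
        p.write_text("λ,I\n300,0\n340,100\n380,0\n")
        s = read_spectrum_csv(p, kind="emission")
        assert len(s) == 3
        assert s.kind == "emission"
        assert s.values[1] == 100

    def test_out_of_order_rows_are_sorted(self, tmp_path):
        p = tmp_path / "em.csv"
        p.write_text("380,0\n300,5\n340,100\n")
        s = read_spectrum_csv(p)
        assert list(s.wavelengths) == [300, 340, 380]
        assert list(s.values) == [5, 100, 0]

    def test_write_read_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        s = Spectrum(np.sort(rng.uniform(250, 450, 40)), rng.uniform(0, 1e3, 40))
        p = tmp_path / "rt.csv"
        write_spectrum_csv(s, p)
        s2 = read_spectrum_csv(p)
        assert np.array_equal(s.wavelengths, s2.wavelengths)
        assert np.array_equal(s.values, s2.values)

    def test_tsv_dialect_autodetected(self, tmp_path):
        p = tmp_path / "em.tsv"
        p.write_text("wl\tval\n300\t1\n310\t2\n")
        s = read_spectrum_csv(p)
        assert list(s.values) == [1, 2]

    @pytest.mark.parametrize(
        "content,match",
        [
            ("300,1\n300,2\n310,3\n", "duplicate wavelength"),
            ("header,h\n300,1\n", "fewer than 2"),
            ("300,1\n310,oops\n", "line 2"),
        ],
    )
    def test_malformed_files_raise(self, tmp_path, content, match):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_spectrum_csv(p)


class TestInnerFilter:
    @pytest.mark.parametrize(
        "F,aex,aem,mode,expected",
        [
            (100.0, 0.0, 0.0, "standard", 100.0),
            (100.0, 0.1, 0.1, "standard", 100.0 * 10**0.1),  # 125.893
            (100.0, 0.1, 0.1, "literature_alt", 100.0),  # exponent (A_ex−A_em)/2 = 0
        ],
    )
    def test_known_values(self, F, aex, aem, mode, expected):
        assert correct_inner_filter(F, aex, aem, mode=mode) == pytest.approx(expected, rel=1e-9)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            correct_inner_filter(100.0, -0.01, 0.0)

    @given(F=st.floats(0, 1e6), aex=st.floats(0, 2), aem=st.floats(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_standard_correction_never_decreases_intensity(self, F, aex, aem):
        out = correct_inner_filter(F, aex, aem, mode="standard")
        assert out >= F
        if F > 0 and (aex + aem) > 1e-9:
            assert out > F


class TestResample:
    def test_constant_spectrum_stays_constant(self):
        s = Spectrum(np.arange(300, 320.0), np.full(20, 7.0))
        r = resample_to_grid(s, np.linspace(301, 318, 13))
        assert np.allclose(r.values, 7.0)

    def test_linear_midpoint(self):
        s = Spectrum([300.0, 302.0], [0.0, 2.0])
        assert resample_to_grid(s, [301.0, 302.0]).values[0] == pytest.approx(1.0)
        assert s.value_at(301.0) == pytest.approx(1.0)

    def test_no_extrapolation(self):
        s = Spectrum([300.0, 310.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="outside source range"):
            resample_to_grid(s, [299.0, 305.0])

    def test_idempotent_on_own_grid_and_exact_on_source_points(self):
        rng = np.random.default_rng(0)
        s = Spectrum(np.arange(300, 340.0), rng.uniform(0, 10, 40), kind="cd", meta={"x": 1})
        r = resample_to_grid(s, s.wavelengths)
        assert np.array_equal(r.values, s.values)
        assert r.kind == "cd" and r.meta["x"] == 1
        r2 = resample_to_grid(s, s.wavelengths[5:10])
        assert np.array_equal(r2.values, s.values[5:10])


class TestSecondDerivative:
    def test_quadratic_gives_analytic_constant_interior(self):
        wl = np.arange(250.0, 300.0, 0.5)
        a = 3.7
        s = Spectrum(wl, a * wl**2)
        d2 = second_derivative(s, window=7)
        assert np.allclose(d2.values[3:-3], 2 * a, rtol=1e-9)

    def test_linear_gives_zero_interior(self):
        wl = np.arange(250.0, 300.0)
        s = Spectrum(wl, 5.0 * wl - 100)
        d2 = second_derivative(s, window=5)
        assert np.allclose(d2.values[2:-2], 0.0, atol=1e-9)

    def test_gaussian_band_minimum_at_center(self):
        wl = np.arange(260.0, 296.0, 1.0)
        s = Spectrum(wl, gaussian_spectrum_values(wl, 278.0, 5.0, 100.0))
        d2 = second_derivative(s, window=7)
        assert abs(wl[np.argmin(d2.values)] - 278.0) <= 1.0

    def test_nonuniform_grid_instructs_resample(self):
        s = Spectrum([300, 301, 303, 304.0], [1, 2, 3, 4.0])
        with pytest.raises(ValueError, match="resample"):
            second_derivative(s, window=3)

    def test_window_validation(self):
        s = Spectrum(np.arange(300.0, 310.0), np.ones(10))
        for w in (2, 4, 11):
            with pytest.raises(ValueError):
                second_derivative(s, window=w)


class TestFindPeaks:
    def test_single_gaussian_located_within_half_nm(self):
        wl = np.arange(300.0, 381.0)
        s = Spectrum(wl, gaussian_spectrum_values(wl, 340.3, 12.0, 100.0))
        peaks = find_peaks(s, 0.1)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(340.3, abs=0.5)

    def test_flat_spectrum_yields_nothing(self):
        s = Spectrum(np.arange(300.0, 320.0), np.full(20, 4.0))
        assert find_peaks(s, 0.1) == []

    def test_two_separated_gaussians_returned_in_wavelength_order(self):
        wl = np.arange(280.0, 381.0, 0.5)
        vals = gaussian_spectrum_values(wl, 302.0, 6.0, 80.0) + gaussian_spectrum_values(
            wl, 340.0, 8.0, 100.0)
        peaks = find_peaks(Spectrum(wl, vals), 0.2)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(302.0, abs=0.5)
        assert peaks[1][0] == pytest.approx(340.0, abs=0.5)

    def test_prominence_threshold_suppresses_minor_bumps(self):
        wl = np.arange(280.0, 381.0, 0.5)
        vals = gaussian_spectrum_values(wl, 340.0, 8.0, 100.0) + gaussian_spectrum_values(
            wl, 300.0, 3.0, 4.0)
        assert len(find_peaks(Spectrum(wl, vals), 0.1)) == 1
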