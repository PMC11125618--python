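"""Amide-I window extraction, band detection, Gaussian-sum fitting, assignment."""

import numpy as np
import pytest

from specbind import InsufficientDataError, Spectrum, ValidationError
from specbind.ftir import (
    AmideBand,
    StructureClass,
    analyze_amide_i,
    assign_and_summarize,
    classify_center,
    detect_bands,
    extract_amide_window,
    fit_bands,
)
from specbind.io import AxisKind, SignalKind
from specbind.simulate import GeneratorConfig, gen_amide_composite

X = np.arange(1580.0, 1721.0, 1.0)


def _ftir(y, x=X):
    return Spectrum(axis=x, intensity=y, axis_kind=AxisKind.WAVENUMBER_CM1,
                    signal_kind=SignalKind.FTIR_ABSORBANCE)


def _gauss(x, amp, cen, sig):
    return amp * np.exp(-0.5 * ((x - cen) / sig) ** 2)


class TestWindowExtraction:
    def test_constant_absorbance_becomes_zero(self):
        window = extract_amide_window(_ftir(np.full(X.size, 0.3)))
        assert window.axis[0] == 1600 and window.axis[-1] == 1700
        np.testing.assert_allclose(window.intensity, 0.0, atol=1e-12)

    def test_sloped_baseline_removed_peak_preserved(self):
        y = _gauss(X, 1.0, 1655.0, 5.0) + 0.2 + 0.001 * (X - 1580)
        window = extract_amide_window(_ftir(y))
        peak = window.axis[np.argmax(window.intensity)]
        assert abs(peak - 1655.0) < 0.5
        # baseline ends pinned to zero
        assert window.intensity[0] == pytest.approx(0.0, abs=1e-9)

    def test_partial_coverage_rejected(self):
        x = np.arange(1650.0, 1701.0)
        with pytest.raises(InsufficientDataError, match="coverage"):
            extract_amide_window(_ftir(np.ones(x.size), x=x))

    def test_internal_gap_rejected(self):
        x = np.concatenate([np.arange(1580.0, 1640.0), np.arange(1665.0, 1721.0)])
        with pytest.raises(InsufficientDataError, match="gap"):
            extract_amide_window(_ftir(np.ones(x.size), x=x))


class TestDetection:
    def test_single_gaussian_single_candidate(self):
        window = extract_amide_window(_ftir(_gauss(X, 1.0, 1655.0, 5.0)))
        centers = detect_bands(window)
        assert len(centers) == 1
        assert abs(centers[0] - 1655.0) <= 1.0

    def test_two_separated_gaussians(self):
        y = _gauss(X, 1.0, 1625.0, 5.0) + _gauss(X, 0.8, 1675.0, 5.0)
        centers = detect_bands(extract_amide_window(_ftir(y)))
        assert len(centers) == 2
        assert abs(centers[0] - 1625.0) <= 1.0 and abs(centers[1] - 1675.0) <= 1.0

    def test_all_zero_window_empty(self):
        assert detect_bands(extract_amide_window(_ftir(np.zeros(X.size)))) == []


class TestFit:
    def test_single_band_parameters_recovered(self):
        truth = (0.9, 1652.0, 6.0)
        window = extract_amide_window(_ftir(_gauss(X, *truth)))
        bands = fit_bands(window, detect_bands(window))
        assert len(bands) == 1
        band = bands[0]
        assert band.amplitude == pytest.approx(truth[0], rel=0.01)
        assert band.center == pytest.approx(truth[1], rel=0.01)
        assert band.sigma == pytest.approx(truth[2], rel=0.01)

    def test_area_ratio_recovered_within_one_point(self):
        # 30:70 area split between a sheet band and a helix band
        a1, a2 = 3.0, 7.0
        y = (
            _gauss(X, a1 / (4 * np.sqrt(2 * np.pi)), 1625.0, 4.0)
            + _gauss(X, a2 / (4 * np.sqrt(2 * np.pi)), 1655.0, 4.0)
        )
        window = extract_amide_window(_ftir(y))
        bands = fit_bands(window, detect_bands(window))
        total = sum(b.area for b in bands)
        shares = sorted(100 * b.area / total for b in bands)
        assert shares[0] == pytest.approx(30.0, abs=1.0)
        assert shares[1] == pytest.approx(70.0, abs=1.0)

    def test_zero_signal_gives_zero_amplitudes(self):
        window = extract_amide_window(_ftir(np.zeros(X.size)))
        bands = fit_bands(window, [1650.0])
        assert all(b.amplitude == 0.0 for b in bands)

    def test_requires_a_guess(self):
        window = extract_amide_window(_ftir(np.zeros(X.size)))
        with pytest.raises(ValidationError):
            fit_bands(window, [])


class TestAssignment:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (1625.0, StructureClass.BETA_SHEET),
            (1645.0, StructureClass.RANDOM_COIL),
            (1655.0, StructureClass.ALPHA_HELIX),
            (1670.0, StructureClass.BETA_TURN),
            (1685.0, StructureClass.BETA_ANTIPARALLEL),
            # shared endpoints resolve to the higher-wavenumber class
            (1640.0, StructureClass.RANDOM_COIL),
            (1650.0, StructureClass.ALPHA_HELIX),
            (1660.0, StructureClass.BETA_TURN),
            (1680.0, StructureClass.BETA_ANTIPARALLEL),
            (1692.0, StructureClass.BETA_ANTIPARALLEL),
            # edges of the amide-I region carry no assignment
            (1605.0, StructureClass.UNASSIGNED),
            (1695.0, StructureClass.UNASSIGNED),
        ],
    )
    def test_window_table(self, center, expected):
        assert classify_center(center) is expected

    def test_single_band_is_hundred_percent(self):
        result = assign_and_summarize([AmideBand(center=1655.0, sigma=5.0, amplitude=1.0)])
        assert result.alpha_helix == pytest.approx(100.0)
        assert sum(result.as_dict().values()) == pytest.approx(100.0, abs=0.1)

    def test_two_band_area_arithmetic(self):
        s = np.sqrt(2 * np.pi)
        bands = [
            AmideBand(center=1625.0, sigma=5.0, amplitude=30.0 / (5 * s)),
            AmideBand(center=1655.0, sigma=5.0, amplitude=70.0 / (5 * s)),
        ]
        result = assign_and_summarize(bands)
        assert result.beta_sheet == pytest.approx(30.0, rel=1e-9)
        assert result.alpha_helix == pytest.approx(70.0, rel=1e-9)

    def test_unassigned_excluded_from_base(self):
        bands = [
            AmideBand(center=1605.0, sigma=5.0, amplitude=1.0),  # unassigned
            AmideBand(center=1655.0, sigma=5.0, amplitude=1.0),
        ]
        result = assign_and_summarize(bands)
        assert result.alpha_helix == pytest.approx(100.0)

    def test_zero_assigned_area_is_error(self):
        with pytest.raises(ValidationError):
            assign_and_summarize([AmideBand(center=1605.0, sigma=5.0, amplitude=1.0)])


class TestEndToEnd:
    def test_pure_helix_composite(self):
        spectrum = gen_amide_composite([0, 0, 1, 0, 0])
        _, result = analyze_amide_i(spectrum)
        assert result.alpha_helix == pytest.approx(100.0, abs=0.1)

    def test_two_class_composite_recovered_within_two_points(self):
        spectrum = gen_amide_composite([0.3, 0, 0.7, 0, 0])
        _, result = analyze_amide_i(spectrum)
        assert result.beta_sheet == pytest.approx(30.0, abs=2.0)
        assert result.alpha_helix == pytest.approx(70.0, abs=2.0)

    def test_five_class_noisy_composite(self):
        fractions = np.array([0.15, 0.20, 0.30, 0.25, 0.10])
        spectrum = gen_amide_composite(
            fractions, config=GeneratorConfig(seed=11, noise_fraction=0.005)
        )
        _, result = analyze_amide_i(spectrum)
        recovered = np.array(list(result.as_dict().values()))
        assert sum(recovered) == pytest.approx(100.0, abs=0.1)
        np.testing.assert_allclose(recovered, 100 * fractions, atol=2.0)

    def test_deterministic(self):
        spectrum = gen_amide_composite(
            [0.2, 0.2, 0.2, 0.2, 0.2], config=GeneratorConfig(seed=3, noise_fraction=0.005)
        )
        _, r1 = analyze_amide_i(spectrum)
        _, r2 = analyze_amide_i(spectrum)
        assert r1.as_dict() == r2.as_dict()
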