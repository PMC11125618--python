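"""Overlap integral, Förster radius, efficiency, distance and validity checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import AbsorptionSpectrum, Spectrum, ValidationError
from specbind.fret import (
    check_validity,
    donor_acceptor_distance,
    forster_radius,
    fret_analysis,
    overlap_integral,
    transfer_efficiency,
)
from specbind.simulate import GeneratorConfig, gen_optical_spectra


def brute_force_overlap(emission, absorption, step_nm=0.01):
    """Independent oracle: dense-grid quadrature of the same discrete-sum definition."""
    lo = max(emission.axis[0], absorption.axis[0])
    hi = min(emission.axis[-1], absorption.axis[-1])
    grid = np.arange(lo, hi + step_nm / 2, step_nm)
    F = np.interp(grid, emission.axis, emission.intensity)
    eps = np.interp(grid, absorption.axis, absorption.molar_absorptivity())
    lam = grid * 1e-7
    return np.trapezoid(F * eps * lam**4, lam) / np.trapezoid(F, lam)


def _flat_pair(lo, hi, eps=1e4, conc=1e-5):
    axis = np.linspace(lo, hi, max(int(hi - lo) + 1, 2))
    emission = Spectrum(axis=axis, intensity=np.ones_like(axis))
    absorption = AbsorptionSpectrum(
        axis=axis, intensity=np.full_like(axis, eps * conc), molar_concentration=conc
    )
    return emission, absorption


class TestOverlapIntegral:
    def test_disjoint_spectra_give_zero_with_warning(self):
        emission = Spectrum(axis=[300, 310, 320], intensity=[0, 1, 0])
        absorption = AbsorptionSpectrum(axis=[400, 410, 420], intensity=[0, 1, 0])
        with pytest.warns(UserWarning, match="overlap"):
            assert overlap_integral(emission, absorption) == 0.0

    def test_flat_bands_closed_form(self):
        # F constant cancels; J = eps * <lambda^4> over 340-341 nm
        emission, absorption = _flat_pair(340, 341)
        J = overlap_integral(emission, absorption)
        assert J == pytest.approx(1e4 * (340.5e-7) ** 4, rel=1e-4)
        assert J == pytest.approx(1.344e-14, rel=1e-3)

    def test_zero_emission_in_overlap_is_error(self):
        emission = Spectrum(axis=[330, 340, 350], intensity=[0, 0, 0])
        _, absorption = _flat_pair(330, 350)
        with pytest.raises(ValidationError, match="zero"):
            overlap_integral(emission, absorption)

    def test_agrees_with_dense_quadrature_oracle(self):
        emission, absorption = gen_optical_spectra()
        J = overlap_integral(emission, absorption)
        J_oracle = brute_force_overlap(emission, absorption)
        assert J == pytest.approx(J_oracle, rel=1e-3)

    def test_invariant_under_emission_scaling(self):
        emission, absorption = gen_optical_spectra()
        scaled = Spectrum(axis=emission.axis, intensity=123.4 * emission.intensity)
        assert overlap_integral(scaled, absorption) == pytest.approx(
            overlap_integral(emission, absorption), rel=1e-12
        )


class TestForsterRadius:
    def test_printed_worked_example(self):
        # J = 6.70e-14 with the standard constants must give R0 = 3.50 nm
        assert forster_radius(6.70e-14, K2=2 / 3, N=1.34, phi=0.15) == pytest.approx(3.50, abs=0.005)

    def test_zero_overlap_gives_zero_radius(self):
        assert forster_radius(0.0) == 0.0

    def test_sixth_power_scaling(self):
        assert forster_radius(64 * 6.70e-14) == pytest.approx(2 * forster_radius(6.70e-14), rel=1e-12)

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValidationError):
            forster_radius(-1e-14)

    @settings(deadline=None, max_examples=25)
    @given(
        j=st.floats(min_value=1e-16, max_value=1e-12),
        factor=st.floats(min_value=1.01, max_value=3.0),
    )
    def test_monotonicity(self, j, factor):
        base = forster_radius(j, K2=2 / 3, N=1.34, phi=0.15)
        assert forster_radius(j * factor) > base
        assert forster_radius(j, K2=2 / 3 * factor) > base
        assert forster_radius(j, phi=min(0.15 * factor, 1.0)) > base
        assert forster_radius(j, N=1.34 * factor) < base


class TestEfficiencyAndDistance:
    @pytest.mark.parametrize("f,f0,expected", [(100, 100, 0.0), (0, 100, 1.0), (82, 100, 0.18)])
    def test_efficiency(self, f, f0, expected):
        assert transfer_efficiency(f, f0) == pytest.approx(expected)

    def test_efficiency_rejects_enhancement(self):
        with pytest.raises(ValidationError):
            transfer_efficiency(110, 100)

    def test_printed_distance_worked_example(self):
        # PFHS pair: R0 = 3.44 nm, E = 0.18 -> r = 4.43 nm
        assert donor_acceptor_distance(3.44, 0.18) == pytest.approx(4.43, abs=0.005)

    def test_half_transfer_is_critical_distance(self):
        assert donor_acceptor_distance(3.5, 0.5) == pytest.approx(3.5, rel=1e-12)

    def test_formula_value_where_print_rounds_differently(self):
        # R0 = 4.07, E = 0.21 evaluates to 5.08 by the closed form
        assert donor_acceptor_distance(4.07, 0.21) == pytest.approx(5.08, abs=0.005)

    def test_zero_efficiency_is_error(self):
        with pytest.raises(ValidationError, match="infinite"):
            donor_acceptor_distance(3.5, 0.0)

    def test_full_transfer_warns_and_returns_contact(self):
        with pytest.warns(UserWarning):
            assert donor_acceptor_distance(3.5, 1.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        r0=st.floats(min_value=0.5, max_value=10.0),
        e=st.floats(min_value=1e-3, max_value=1 - 1e-3),
    )
    def test_efficiency_distance_identity(self, r0, e):
        """E (R0^6 + r^6) = R0^6 for the composed operations."""
        r = donor_acceptor_distance(r0, e)
        assert e * (r0**6 + r**6) == pytest.approx(r0**6, rel=1e-10)


class TestValidity:
    def test_printed_case_is_valid(self):
        valid, reasons = check_validity(4.87, 3.50)
        assert valid and not reasons

    @pytest.mark.parametrize(
        "r,r0,fragment",
        [(8.0, 6.0, "7 nm"), (1.2, 3.0, "0.5 R0"), (6.9, 4.0, "1.5 R0")],
    )
    def test_violations_reported(self, r, r0, fragment):
        valid, reasons = check_validity(r, r0)
        assert not valid
        assert any(fragment in reason for reason in reasons)


def test_full_pipeline_on_synthetic_pair():
    emission, absorption = gen_optical_spectra(config=GeneratorConfig(seed=1, noise_fraction=0.0))
    result = fret_analysis(emission, absorption, F=870.0, F0=1000.0)
    assert result.J == pytest.approx(6.7e-14, rel=0.10)
    assert result.R0_nm == pytest.approx(3.50, abs=0.06)
    assert result.E == pytest.approx(0.13)
    assert result.valid, result.reasons
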