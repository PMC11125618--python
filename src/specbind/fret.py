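"""Förster resonance energy transfer: overlap integral, R0, efficiency, distance.

The donor emission spectrum F(lambda) and acceptor molar absorptivity
eps(lambda) define the spectral overlap integral

    J = sum F(l) eps(l) l^4 dl / sum F(l) dl

with the wavelength expressed in cm and eps in L mol^-1 cm^-1, giving J in
cm^3 L mol^-1 (the convention under which the Förster prefactor below is
valid and printed J values of order 1e-14 arise). The Förster critical
radius follows from

    R0^6 = 8.8e-25 K^2 N^-4 Phi J     [cm^6]

with orientation factor K^2 (2/3 for freely rotating dipoles), medium
refractive index N (~1.34 for aqueous protein solutions) and donor quantum
yield Phi. Transfer efficiency at 1:1 donor:acceptor molar ratio,

    E = 1 - F/F0 = R0^6 / (R0^6 + r^6),

inverts to the donor-acceptor distance r = R0 ((1-E)/E)^(1/6). FRET-based
distances are trustworthy only when r lies within 0.5-1.5 R0 and below
~7 nm; ``check_validity`` reports that verdict with the violated conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import AbsorptionSpectrum, Spectrum

__all__ = [
    "FretResult",
    "DEFAULT_K2",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_QUANTUM_YIELD",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "donor_acceptor_distance",
    "check_validity",
    "fret_analysis",
]

DEFAULT_K2 = 2.0 / 3.0
DEFAULT_REFRACTIVE_INDEX = 1.34
DEFAULT_QUANTUM_YIELD = 0.15

#: Förster prefactor for J in cm^3 L mol^-1, R0^6 in cm^6.
_FORSTER_PREFACTOR = 8.8e-25

_NM_TO_CM = 1.0e-7


@dataclass
class FretResult:
    J: float                      # cm^3 L mol^-1
    R0_nm: float
    E: float
    r_nm: float
    K2: float = DEFAULT_K2
    N_refractive: float = DEFAULT_REFRACTIVE_INDEX
    phi: float = DEFAULT_QUANTUM_YIELD
    valid: bool = False
    reasons: list[str] = field(default_factory=list)


def overlap_integral(emission: Spectrum, absorption: AbsorptionSpectrum) -> float:
    """Spectral overlap integral J in cm^3 L mol^-1 on a shared 1 nm grid.

    Both curves are linearly interpolated onto integer-nm points of the
    common wavelength interval; the sums are evaluated as trapezoids with
    the wavelength in cm. Disjoint spectra give J = 0 with a warning.
    """
    lo = max(emission.axis[0], absorption.axis[0])
    hi = min(emission.axis[-1], absorption.axis[-1])
    grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)
    if grid.size < 2:
        warnings.warn("emission and absorption spectra share no usable wavelength overlap; J = 0",
                      stacklevel=2)
        return 0.0
    F = np.interp(grid, emission.axis, emission.intensity)
    eps = np.interp(grid, absorption.axis, absorption.molar_absorptivity())
    lam_cm = grid * _NM_TO_CM
    denom = np.trapezoid(F, lam_cm)
    if denom <= 0:
        raise ValidationError("total emission over the overlap interval is zero; J undefined")
    numer = np.trapezoid(F * eps * lam_cm**4, lam_cm)
    return float(numer / denom)


def forster_radius(
    J: float,
    K2: float = DEFAULT_K2,
    N: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> float:
    """Critical transfer distance R0 in nm from the overlap integral."""
    if J < 0:
        raise ValidationError("overlap integral J must be non-negative")
    if N <= 0:
        raise ValidationError("refractive index must be positive")
    if not 0 < phi <= 1:
        raise ValidationError("quantum yield must be in (0, 1]")
    r0_cm = (_FORSTER_PREFACTOR * K2 * N**-4 * phi * J) ** (1.0 / 6.0)
    return float(r0_cm / _NM_TO_CM)


def transfer_efficiency(F: float, F0: float) -> float:
    """E = 1 - F/F0 at 1:1 donor:acceptor molar ratio."""
    if F0 <= 0:
        raise ValidationError("F0 must be positive")
    if F < 0 or F > F0:
        raise ValidationError("F must satisfy 0 <= F <= F0 (negative efficiency is not meaningful)")
    return 1.0 - F / F0


def donor_acceptor_distance(R0_nm: float, E: float) -> float:
    """r = R0 ((1-E)/E)^(1/6), nm."""
    if R0_nm <= 0:
        raise ValidationError("R0 must be positive")
    if E <= 0:
        raise ValidationError("E = 0 implies infinite donor-acceptor distance")
    if E >= 1:
        if E > 1:
            raise ValidationError("E must not exceed 1")
        warnings.warn("E = 1 implies donor-acceptor contact; returning r = 0", stacklevel=2)
        return 0.0
    return float(R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0))


def check_validity(r_nm: float, R0_nm: float) -> tuple[bool, list[str]]:
    """Energy-transfer validity: 0.5 R0 <= r <= 1.5 R0 and r < 7 nm."""
    if r_nm <= 0 or R0_nm <= 0:
        raise ValidationError("r and R0 must be positive")
    reasons = []
    if r_nm < 0.5 * R0_nm:
        reasons.append(f"r = {r_nm:.2f} nm below 0.5 R0 = {0.5 * R0_nm:.2f} nm")
    if r_nm > 1.5 * R0_nm:
        reasons.append(f"r = {r_nm:.2f} nm above 1.5 R0 = {1.5 * R0_nm:.2f} nm")
    if r_nm >= 7.0:
        reasons.append(f"r = {r_nm:.2f} nm not below 7 nm")
    return (not reasons, reasons)


def fret_analysis(
    emission: Spectrum,
    absorption: AbsorptionSpectrum,
    F: float,
    F0: float,
    K2: float = DEFAULT_K2,
    N: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> FretResult:
    """Full pipeline: J -> R0 -> E -> r -> validity, in one call."""
    J = overlap_integral(emission, absorption)
    R0 = forster_radius(J, K2=K2, N=N, phi=phi)
    E = transfer_efficiency(F, F0)
    r = donor_acceptor_distance(R0, E)
    valid, reasons = check_validity(r, R0) if r > 0 else (False, ["r = 0"])
    return FretResult(J=J, R0_nm=R0, E=E, r_nm=r, K2=K2, N_refractive=N, phi=phi,
                      valid=valid, reasons=reasons)
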