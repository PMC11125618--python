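"""Synthetic spectra, titrations and EEMs with known ground truth.

No raw spectra are deposited with typical protein-ligand spectroscopy
studies, so every analysis stage in this package is exercised against
generated inputs whose true parameters are known exactly:

- ``gen_titration``: static-quenching titrations from the forward model
  F = F0 / (1 + Ka [Q]^n) — the exact inverse of the double-logarithm fit —
  on the conventional 0..9e-7 mol/L ligand grid. Defaults: Ka = 2e6 L/mol
  (the 1e6-order affinity regime of strong protein-PFSA binding), n = 1.
- ``gen_optical_spectra``: a Gaussian tryptophan-like donor emission peaked
  at 340 nm and a Gaussian acceptor absorption band on the 300-450 nm
  UV-Vis scan range; the default peak absorptivity 5.5e4 L mol^-1 cm^-1 is
  set (closed-form Gaussian-overlap calculation) so the default pair has an
  overlap integral at the ~6.7e-14 cm^3 L mol^-1 magnitude typical of these
  systems.
- ``gen_amide_composite``: amide-I composites of up to five Gaussian bands,
  one per secondary-structure class, with areas proportional to requested
  fractions.
- ``gen_eem``: 2-D Gaussian fluorescence peaks plus a first-order Rayleigh
  ridge along Em = Ex, on the conventional 200-450 nm / 5 nm grid.

Noise is multiplicative Gaussian (photodetector noise scales with signal),
default 1% relative; every generator is a deterministic function of its
``GeneratorConfig`` (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .ftir import ASSIGNMENT_WINDOWS, StructureClass
from .io import AbsorptionSpectrum, AxisKind, EEMap, SignalKind, Spectrum, TitrationSeries

__all__ = [
    "GeneratorConfig",
    "DEFAULT_CONCENTRATIONS",
    "gen_titration",
    "gen_optical_spectra",
    "gen_amide_composite",
    "gen_eem",
]

#: Conventional titration grid: 0..9 x 1e-7 mol/L.
DEFAULT_CONCENTRATIONS = tuple(i * 1e-7 for i in range(10))

#: Default amide-I band centers, one per class, each inside its window.
DEFAULT_AMIDE_CENTERS = {
    StructureClass.BETA_SHEET: 1625.0,
    StructureClass.RANDOM_COIL: 1645.0,
    StructureClass.ALPHA_HELIX: 1655.0,
    StructureClass.BETA_TURN: 1670.0,
    StructureClass.BETA_ANTIPARALLEL: 1686.0,
}

_CLASS_ORDER = [
    StructureClass.BETA_SHEET,
    StructureClass.RANDOM_COIL,
    StructureClass.ALPHA_HELIX,
    StructureClass.BETA_TURN,
    StructureClass.BETA_ANTIPARALLEL,
]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    noise_fraction: float = 0.01

    def __post_init__(self):
        if self.noise_fraction < 0:
            raise ValidationError("noise_fraction must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_titration(
    Ka: float = 2.0e6,
    n: float = 1.0,
    F0: float = 1000.0,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    temperature_K: float = 298.0,
    config: GeneratorConfig = GeneratorConfig(),
) -> TitrationSeries:
    """Static-quenching titration: F = F0 / (1 + Ka [Q]^n), noisy at [Q] > 0."""
    if Ka <= 0 or n <= 0 or F0 <= 0:
        raise ValidationError("Ka, n and F0 must be positive")
    q = np.asarray(concentrations, dtype=float)
    f = np.empty_like(q)
    f[q == 0] = F0
    nz = q > 0
    f[nz] = F0 / (1.0 + Ka * q[nz] ** n)
    if config.noise_fraction > 0:
        f[nz] *= 1.0 + config.noise_fraction * config.rng().standard_normal(nz.sum())
    return TitrationSeries(ligand_concentrations=q, intensities=f, temperature_K=temperature_K)


def gen_optical_spectra(
    emission_center_nm: float = 340.0,
    emission_sigma_nm: float = 20.0,
    absorption_center_nm: float = 340.0,
    absorption_sigma_nm: float = 40.0,
    epsilon_max: float = 5.5e4,
    emission_range_nm: tuple[float, float] = (280.0, 420.0),
    absorption_range_nm: tuple[float, float] = (300.0, 450.0),
    molar_concentration: float = 1.0e-5,
    path_length_cm: float = 1.0,
    config: GeneratorConfig = GeneratorConfig(noise_fraction=0.0),
) -> tuple[Spectrum, AbsorptionSpectrum]:
    """Gaussian donor emission and acceptor absorption band on 1 nm grids."""
    if emission_sigma_nm <= 0 or absorption_sigma_nm <= 0:
        raise ValidationError("band sigmas must be positive")
    rng = config.rng()
    em_axis = np.arange(emission_range_nm[0], emission_range_nm[1] + 0.5, 1.0)
    em_int = np.exp(-0.5 * ((em_axis - emission_center_nm) / emission_sigma_nm) ** 2)
    ab_axis = np.arange(absorption_range_nm[0], absorption_range_nm[1] + 0.5, 1.0)
    absorptivity = epsilon_max * np.exp(
        -0.5 * ((ab_axis - absorption_center_nm) / absorption_sigma_nm) ** 2
    )
    absorbance = absorptivity * molar_concentration * path_length_cm
    if config.noise_fraction > 0:
        em_int = em_int * (1.0 + config.noise_fraction * rng.standard_normal(em_int.size))
        absorbance = absorbance * (1.0 + config.noise_fraction * rng.standard_normal(absorbance.size))
        em_int = np.clip(em_int, 0.0, None)
        absorbance = np.clip(absorbance, 0.0, None)
    emission = Spectrum(
        axis=em_axis,
        intensity=em_int,
        axis_kind=AxisKind.WAVELENGTH_NM,
        signal_kind=SignalKind.FLUORESCENCE_EMISSION,
        label="synthetic donor emission",
    )
    absorption = AbsorptionSpectrum(
        axis=ab_axis,
        intensity=absorbance,
        axis_kind=AxisKind.WAVELENGTH_NM,
        signal_kind=SignalKind.UV_VIS_ABSORBANCE,
        label="synthetic acceptor absorption",
        molar_concentration=molar_concentration,
        path_length_cm=path_length_cm,
    )
    return emission, absorption


def gen_amide_composite(
    fractions: Sequence[float],
    centers: Sequence[float] | None = None,
    sigmas: Sequence[float] | None = None,
    total_area: float = 10.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    config: GeneratorConfig = GeneratorConfig(noise_fraction=0.0),
) -> Spectrum:
    """Amide-I composite: Gaussian bands with areas proportional to fractions.

    ``fractions`` are per-class (beta-sheet, coil, helix, turn, antiparallel),
    non-negative, summing to 1. Each center must lie inside its class window.
    The spectrum spans 1580-1720 cm^-1 at 1 cm^-1 steps, optionally with a
    linear baseline (intercept, slope per cm^-1 relative to 1580) and
    multiplicative noise.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 5 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0, atol=1e-9):
        raise ValidationError("fractions must be 5 non-negative values summing to 1")
    centers = list(centers) if centers is not None else [DEFAULT_AMIDE_CENTERS[c] for c in _CLASS_ORDER]
    sigmas = list(sigmas) if sigmas is not None else [4.0] * 5
    if len(centers) != 5 or len(sigmas) != 5:
        raise ValidationError("centers and sigmas must have 5 entries (one per class)")
    for frac, center, (lo, hi, cls) in zip(fr, centers, ASSIGNMENT_WINDOWS):
        if frac > 0 and not (lo <= center <= hi):
            raise ValidationError(
                f"center {center} cm^-1 outside the {cls.value} window [{lo}, {hi}]"
            )
    x = np.arange(1580.0, 1720.0 + 0.5, 1.0)
    y = np.zeros_like(x)
    for frac, center, sigma in zip(fr, centers, sigmas):
        if frac <= 0:
            continue
        area = total_area * frac
        amp = area / (sigma * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if config.noise_fraction > 0:
        y *= 1.0 + config.noise_fraction * config.rng().standard_normal(y.size)
        y = np.clip(y, 0.0, None)
    y = y + baseline[0] + baseline[1] * (x - x[0])
    return Spectrum(
        axis=x,
        intensity=y,
        axis_kind=AxisKind.WAVENUMBER_CM1,
        signal_kind=SignalKind.FTIR_ABSORBANCE,
        label="synthetic amide-I composite",
    )


def gen_eem(
    peaks: Sequence[tuple[float, float, float, float]] = (
        (280.0, 340.0, 800.0, 15.0),
        (230.0, 340.0, 600.0, 15.0),
    ),
    rayleigh_height: float = 1000.0,
    rayleigh_sigma_nm: float = 6.0,
    axis_start_nm: float = 200.0,
    axis_stop_nm: float = 450.0,
    axis_step_nm: float = 5.0,
    config: GeneratorConfig = GeneratorConfig(noise_fraction=0.0),
) -> EEMap:
    """EEM of 2-D Gaussian peaks (Ex, Em, height, sigma) plus a Rayleigh ridge.

    Default peak placements mirror the two tryptophan-region fluorophore
    peaks (protein backbone peak near Ex 230 nm and aromatic-residue peak
    near Ex 280 nm, both emitting around 340 nm) riding on the Em = Ex
    first-order scatter diagonal. The returned map is unmasked.
    """
    axis = np.arange(axis_start_nm, axis_stop_nm + axis_step_nm / 2, axis_step_nm)
    ex = axis[:, None]
    em = axis[None, :]
    z = rayleigh_height * np.exp(-0.5 * ((em - ex) / rayleigh_sigma_nm) ** 2)
    for ex0, em0, height, sigma in peaks:
        if not (axis[0] <= ex0 <= axis[-1] and axis[0] <= em0 <= axis[-1]):
            raise ValidationError(f"peak ({ex0}, {em0}) outside the axis range")
        z = z + height * np.exp(-0.5 * (((ex - ex0) ** 2 + (em - em0) ** 2) / sigma**2))
    if config.noise_fraction > 0:
        z = z * (1.0 + config.noise_fraction * config.rng().standard_normal(z.shape))
        z = np.clip(z, 0.0, None)
    return EEMap(excitation_axis=axis.copy(), emission_axis=axis.copy(), intensity=z)
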