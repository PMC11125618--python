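"""Amide-I deconvolution and secondary-structure composition from FTIR.

Protein backbone C=O stretching absorbs in 1600-1700 cm^-1 (amide I), and
the band position of each overlapping component reports its secondary
structure:

    1610-1640  beta-sheet        1660-1680  beta-turn
    1640-1650  random coil       1680-1692  antiparallel beta-sheet
    1650-1660  alpha-helix

The workflow mirrors the standard deconvolution-then-fit treatment:

1. ``extract_amide_window`` cuts 1600-1700 cm^-1 and subtracts a linear
   baseline through the window endpoints;
2. ``detect_bands`` places candidate band centers at negative minima of the
   Savitzky-Golay-smoothed second derivative (second derivatives resolve
   overlapped amide-I components);
3. ``fit_bands`` runs a bounded nonlinear least-squares fit of a Gaussian
   sum;
4. ``assign_and_summarize`` maps each fitted center to its class window and
   converts band areas to percentage composition.

Shared window endpoints are resolved half-open with the tie going to the
higher-wavenumber class; 1600-1610 and 1692-1700 carry no assignment and are
excluded from the percentage base.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .errors import FitError, InsufficientDataError, ValidationError
from .io import Spectrum

__all__ = [
    "StructureClass",
    "AmideBand",
    "SecondaryStructure",
    "ASSIGNMENT_WINDOWS",
    "extract_amide_window",
    "detect_bands",
    "fit_bands",
    "assign_and_summarize",
    "analyze_amide_i",
]

AMIDE_I_RANGE = (1600.0, 1700.0)
SIGMA_BOUNDS = (2.0, 25.0)
CENTER_SLACK = 8.0  # cm^-1 each side of a detected guess
MAX_BANDS = 8


class StructureClass(str, enum.Enum):
    BETA_SHEET = "beta_sheet"
    RANDOM_COIL = "random_coil"
    ALPHA_HELIX = "alpha_helix"
    BETA_TURN = "beta_turn"
    BETA_ANTIPARALLEL = "beta_antiparallel"
    UNASSIGNED = "unassigned"


#: (low, high, half-open-high?) -> class; ties at shared endpoints go to the
#: higher-wavenumber class, so all but the last window are half-open.
ASSIGNMENT_WINDOWS: list[tuple[float, float, StructureClass]] = [
    (1610.0, 1640.0, StructureClass.BETA_SHEET),
    (1640.0, 1650.0, StructureClass.RANDOM_COIL),
    (1650.0, 1660.0, StructureClass.ALPHA_HELIX),
    (1660.0, 1680.0, StructureClass.BETA_TURN),
    (1680.0, 1692.0, StructureClass.BETA_ANTIPARALLEL),
]


def classify_center(center: float) -> StructureClass:
    """Assign a band center (cm^-1) to its secondary-structure class."""
    for i, (lo, hi, cls) in enumerate(ASSIGNMENT_WINDOWS):
        last = i == len(ASSIGNMENT_WINDOWS) - 1
        if (lo <= center < hi) or (last and lo <= center <= hi):
            return cls
    return StructureClass.UNASSIGNED


@dataclass
class AmideBand:
    center: float       # cm^-1
    sigma: float        # Gaussian sigma, cm^-1
    amplitude: float
    assignment: StructureClass = StructureClass.UNASSIGNED

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("band sigma must be positive")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be non-negative")
        self.assignment = classify_center(self.center)

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass
class SecondaryStructure:
    """Percent composition per structure class; sums to 100 within 0.1."""

    beta_sheet: float = 0.0
    random_coil: float = 0.0
    alpha_helix: float = 0.0
    beta_turn: float = 0.0
    beta_antiparallel: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_sheet": self.beta_sheet,
            "random_coil": self.random_coil,
            "alpha_helix": self.alpha_helix,
            "beta_turn": self.beta_turn,
            "beta_antiparallel": self.beta_antiparallel,
        }


def extract_amide_window(spectrum: Spectrum) -> Spectrum:
    """Cut [1600, 1700] cm^-1 and subtract the endpoint-to-endpoint baseline.

    Negative residuals are clipped to zero; a warning is issued if the clip
    removes more than 2% of the maximum absorbance.
    """
    lo, hi = AMIDE_I_RANGE
    if spectrum.axis[0] > lo or spectrum.axis[-1] < hi:
        raise InsufficientDataError(
            f"spectrum covers {spectrum.axis[0]:.0f}-{spectrum.axis[-1]:.0f} cm^-1; "
            f"amide-I analysis needs full coverage of {lo:.0f}-{hi:.0f} cm^-1"
        )
    window = spectrum.crop(lo, hi)
    if len(window) < 10:
        raise InsufficientDataError("fewer than 10 points inside the amide-I window")
    gaps = np.diff(window.axis)
    if np.max(gaps) > 10.0:
        raise InsufficientDataError(
            f"coverage gap of {np.max(gaps):.1f} cm^-1 inside the amide-I window"
        )
    x, y = window.axis, window.intensity
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    corrected = y - baseline
    clip_depth = -corrected.min() if corrected.min() < 0 else 0.0
    corrected = np.clip(corrected, 0.0, None)
    if corrected.max() > 0 and clip_depth > 0.02 * corrected.max():
        warnings.warn(
            f"baseline clip removed {100 * clip_depth / corrected.max():.1f}% of max absorbance; "
            "baseline model may be inadequate",
            stacklevel=2,
        )
    return replace(window, intensity=corrected)


def detect_bands(window: Spectrum) -> list[float]:
    """Candidate band centers from negative second-derivative minima.

    The window is smoothed with a 9-point cubic Savitzky-Golay filter whose
    second derivative is evaluated analytically; minima of that derivative
    (peaks of its negative) mark component centers. Candidates need
    absorbance of at least 1% of the window maximum. At most 8 candidates
    (strongest second-derivative response first) are kept, returned sorted
    by center.
    """
    x, y = window.axis, window.intensity
    if y.max() <= 0:
        return []
    delta = float(np.median(np.diff(x)))
    wl = min(9, len(y) if len(y) % 2 else len(y) - 1)
    if wl < 5:
        return [float(x[np.argmax(y)])]
    d2 = savgol_filter(y, window_length=wl, polyorder=3, deriv=2, delta=delta)
    neg = -d2
    idx, props = find_peaks(neg, height=0.0, prominence=0.01 * float(np.max(neg)))
    idx = idx[y[idx] >= 0.01 * y.max()]
    if idx.size == 0:
        # fall back: one band at the global maximum
        return [float(x[np.argmax(y)])]
    if idx.size > MAX_BANDS:
        keep = np.argsort(neg[idx])[::-1][:MAX_BANDS]
        idx = idx[np.sort(keep)]
    return sorted(float(x[i]) for i in idx)


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for k in range(0, len(params), 3):
        amp, cen, sig = params[k : k + 3]
        y = y + amp * np.exp(-0.5 * ((x - cen) / sig) ** 2)
    return y


def fit_bands(window: Spectrum, guesses: list[float], max_restarts: int = 3) -> list[AmideBand]:
    """Bounded least-squares fit of a sum of Gaussians at the guessed centers.

    Centers may move at most +-8 cm^-1 from their guesses (and stay inside
    the amide-I window); sigmas are bounded to [2, 25] cm^-1; amplitudes are
    non-negative. Restarts with perturbed initial widths on failure.
    """
    if not guesses:
        raise ValidationError("fit_bands needs at least one initial center guess")
    x, y = window.axis, window.intensity
    if y.max() <= 0:
        return [AmideBand(center=g, sigma=8.0, amplitude=0.0) for g in guesses]

    lo, hi = AMIDE_I_RANGE
    p0, lower, upper = [], [], []
    for g in guesses:
        amp0 = max(float(np.interp(g, x, y)), 1e-3 * y.max())
        p0 += [amp0, g, 8.0]
        lower += [0.0, max(lo, g - CENTER_SLACK), SIGMA_BOUNDS[0]]
        upper += [5.0 * y.max(), min(hi, g + CENTER_SLACK), SIGMA_BOUNDS[1]]

    best_resid = np.inf
    rng = np.random.default_rng(0)  # restart jitter only; fit is deterministic per input
    for attempt in range(max_restarts + 1):
        trial = list(p0)
        if attempt:
            for k in range(2, len(trial), 3):
                trial[k] = float(np.clip(trial[k] * rng.uniform(0.5, 1.8), *SIGMA_BOUNDS))
        try:
            popt, _ = curve_fit(
                _gaussian_sum, x, y, p0=trial, bounds=(lower, upper), maxfev=20000
            )
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((y - _gaussian_sum(x, *popt)) ** 2)))
        if resid < best_resid:
            best_resid, best = resid, popt
    if not np.isfinite(best_resid):
        raise FitError("amide-I band fit failed to converge", best_residual=None)
    bands = [
        AmideBand(amplitude=float(best[k]), center=float(best[k + 1]), sigma=float(best[k + 2]))
        for k in range(0, len(best), 3)
    ]
    return sorted(bands, key=lambda b: b.center)


def assign_and_summarize(bands: list[AmideBand]) -> SecondaryStructure:
    """Percentage composition from band areas over the assigned-area base."""
    totals: dict[StructureClass, float] = {}
    for band in bands:
        totals[band.assignment] = totals.get(band.assignment, 0.0) + band.area
    assigned = sum(v for k, v in totals.items() if k is not StructureClass.UNASSIGNED)
    if assigned <= 0:
        raise ValidationError("no band area falls inside an assignable amide-I window")
    pct = {
        k.value: 100.0 * v / assigned
        for k, v in totals.items()
        if k is not StructureClass.UNASSIGNED
    }
    return SecondaryStructure(**pct)


def analyze_amide_i(spectrum: Spectrum) -> tuple[list[AmideBand], SecondaryStructure]:
    """Full pipeline: window -> detect -> fit -> assign."""
    window = extract_amide_window(spectrum)
    guesses = detect_bands(window)
    if not guesses:
        raise InsufficientDataError("no amide-I signal detected")
    bands = fit_bands(window, guesses)
    return bands, assign_and_summarize(bands)
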