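"""Stern-Volmer and double-logarithm analysis of fluorescence quenching.

A quencher Q added to a fluorophore obeys the Stern-Volmer relation

    F0 / F = 1 + Ksv [Q] = 1 + Kq tau0 [Q]

where Ksv is the quenching constant, tau0 the unperturbed fluorescence
lifetime (~1e-8 s for tryptophan-like protein emission) and Kq = Ksv / tau0
the bimolecular quenching rate constant. A Kq above the diffusion-limited
maximum of 2e10 L mol^-1 s^-1 cannot arise from collisional (dynamic)
quenching and diagnoses static quenching, i.e. ground-state complex
formation.

For static quenching with a single class of n equivalent sites,

    log10[(F0 - F) / F] = log10 Ka + n log10 [Q]

so an ordinary least-squares line on the double-log axes yields the apparent
binding constant Ka (10^intercept) and the binding-site number n (slope).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import TitrationSeries

__all__ = [
    "Mechanism",
    "QuenchingResult",
    "DYNAMIC_LIMIT_KQ",
    "DEFAULT_TAU0_S",
    "fit_stern_volmer",
    "classify_mechanism",
    "fit_double_log",
    "analyze_titration",
]

#: Diffusion-limited maximum dynamic quenching rate constant, L mol^-1 s^-1.
DYNAMIC_LIMIT_KQ = 2.0e10

#: Default intrinsic fluorescence lifetime, s.
DEFAULT_TAU0_S = 1.0e-8


class Mechanism(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"


@dataclass
class QuenchingResult:
    """Fitted quenching parameters; fields not produced by a given fit are None.

    Invariant: ``Kq == Ksv / tau0`` exactly whenever Ksv is populated.
    """

    Ksv: float | None = None            # L mol^-1
    Kq: float | None = None             # L mol^-1 s^-1
    tau0: float = DEFAULT_TAU0_S        # s
    Ka: float | None = None             # L mol^-1
    n: float | None = None              # binding-site number
    intercept_sv: float | None = None
    r_squared_sv: float | None = None
    r_squared_dl: float | None = None
    mechanism: Mechanism | None = None
    temperature_K: float | None = None
    flags: list[str] = field(default_factory=list)


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0_S) -> QuenchingResult:
    """Least-squares Stern-Volmer line F0/F vs [Q]; slope = Ksv, Kq = Ksv/tau0.

    The intercept is left free (the model fixes it at 1; deviation beyond 5%
    is flagged as a diagnostic). Flat data (no quenching) returns Ksv = 0.
    """
    if tau0 <= 0:
        raise ValidationError("tau0 must be positive")
    q = series.ligand_concentrations
    f = series.intensities
    if np.count_nonzero(q > 0) < 3:
        raise InsufficientDataError("Stern-Volmer fit needs >= 3 nonzero-concentration points")
    if np.any(f <= 0):
        raise ValidationError("all fluorescence intensities must be positive")
    ratio = series.F0 / f
    if np.allclose(ratio, ratio[0]):
        # zero slope: no quenching, not an error
        result = QuenchingResult(Ksv=0.0, Kq=0.0, tau0=tau0, intercept_sv=float(ratio[0]),
                                 r_squared_sv=1.0, temperature_K=series.temperature_K)
    else:
        fit = stats.linregress(q, ratio)
        ksv = float(fit.slope)
        result = QuenchingResult(
            Ksv=ksv,
            Kq=ksv / tau0,
            tau0=tau0,
            intercept_sv=float(fit.intercept),
            r_squared_sv=float(fit.rvalue) ** 2,
            temperature_K=series.temperature_K,
        )
    if result.intercept_sv is not None and abs(result.intercept_sv - 1.0) > 0.05:
        result.flags.append(
            f"Stern-Volmer intercept {result.intercept_sv:.4f} deviates from 1 by more than 5%"
        )
    result.mechanism = classify_mechanism(max(result.Kq, 0.0)) if result.Kq is not None else None
    return result


def classify_mechanism(Kq: float) -> Mechanism:
    """Static iff Kq strictly exceeds the diffusion limit 2e10 L mol^-1 s^-1."""
    if Kq < 0:
        raise ValidationError("Kq must be non-negative")
    return Mechanism.STATIC if Kq > DYNAMIC_LIMIT_KQ else Mechanism.DYNAMIC


def fit_double_log(series: TitrationSeries) -> QuenchingResult:
    """OLS of log10((F0-F)/F) on log10([Q]); n = slope, Ka = 10^intercept.

    Points with F >= F0 at nonzero [Q] (no net quenching; log undefined) are
    dropped with a warning rather than clamped.
    """
    q = series.ligand_concentrations[1:]
    f = series.intensities[1:]
    f0 = series.F0
    usable = f < f0
    n_dropped = int(np.count_nonzero(~usable))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} point(s) with F >= F0 at nonzero [Q] from double-log fit",
            stacklevel=2,
        )
    q, f = q[usable], f[usable]
    if q.size < 3:
        raise InsufficientDataError(
            f"double-log fit needs >= 3 points with F < F0; only {q.size} usable"
        )
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    fit = stats.linregress(x, y)
    return QuenchingResult(
        Ka=float(10.0 ** fit.intercept),
        n=float(fit.slope),
        r_squared_dl=float(fit.rvalue) ** 2,
        temperature_K=series.temperature_K,
    )


def analyze_titration(series: TitrationSeries, tau0: float = DEFAULT_TAU0_S) -> QuenchingResult:
    """Run both fits on one series and merge into a single QuenchingResult."""
    sv = fit_stern_volmer(series, tau0=tau0)
    try:
        dl = fit_double_log(series)
        sv.Ka, sv.n, sv.r_squared_dl = dl.Ka, dl.n, dl.r_squared_dl
    except InsufficientDataError as exc:
        sv.flags.append(f"double-log fit skipped: {exc}")
    return sv
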