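"""Excitation-emission matrix analysis: scatter masking, peak picking, shifts.

Rayleigh scatter contaminates an EEM along Em = Ex (first order) and
Em = 2 Ex (second order); both ridges are masked to a configurable
half-width before any peak statistics. Fluorescence peaks are strict
8-neighbour local maxima over the unmasked cells; plateaus contribute one
peak each, at their lexicographically smallest (Ex, Em) cell, so output is
deterministic. ``compare_eems`` matches peaks between a reference and a
treated map and reports per-peak excitation/emission shifts (negative
emission shift = blue shift) and intensity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import EEMap

__all__ = [
    "EEMPeak",
    "PeakShift",
    "DEFAULT_SCATTER_HALF_WIDTH_NM",
    "mask_scatter",
    "find_peaks",
    "compare_eems",
]

DEFAULT_SCATTER_HALF_WIDTH_NM = 15.0


@dataclass(frozen=True)
class EEMPeak:
    excitation_nm: float
    emission_nm: float
    intensity: float
    label: str = ""


@dataclass(frozen=True)
class PeakShift:
    reference: EEMPeak
    treated: EEMPeak | None
    delta_excitation_nm: float | None
    delta_emission_nm: float | None   # negative = blue shift
    intensity_ratio: float | None
    matched: bool


def mask_scatter(eem: EEMap, half_width_nm: float = DEFAULT_SCATTER_HALF_WIDTH_NM) -> EEMap:
    """Mask first-order (Em = Ex) and second-order (Em = 2 Ex) Rayleigh ridges.

    Masking is additive to any existing mask and idempotent.
    """
    if half_width_nm < 0:
        raise ValidationError("half_width_nm must be >= 0")
    ex = eem.excitation_axis[:, None]
    em = eem.emission_axis[None, :]
    first = np.abs(em - ex) <= half_width_nm
    second = np.abs(em - 2.0 * ex) <= half_width_nm
    return replace(eem, mask=eem.mask | first | second)


def find_peaks(eem: EEMap, max_peaks: int = 2) -> list[EEMPeak]:
    """Strict 8-neighbour local maxima over unmasked cells.

    Masked and out-of-bounds neighbours are ignored. Connected plateaus of
    equal value yield one peak at the lexicographically smallest (Ex, Em)
    cell. Peaks are sorted by intensity descending (ties lexicographic) and
    truncated to ``max_peaks``.
    """
    z = np.where(eem.mask, -np.inf, eem.intensity)
    if not np.any(np.isfinite(z)):
        return []
    # cell is a candidate if >= all 8 neighbours (maximum_filter) and unmasked
    footprint = np.ones((3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(z, footprint=footprint, mode="constant", cval=-np.inf)
    candidates = (z == local_max) & ~eem.mask
    if not np.any(candidates):
        return []
    # one peak per connected equal-valued plateau of candidate cells
    labels, n_lab = ndimage.label(candidates, structure=footprint)
    peaks: list[EEMPeak] = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        # plateau components may merge cells of unequal value only if the
        # candidate region is connected with equal z; keep min (ex, em) of max-z cells
        vals = z[cells[:, 0], cells[:, 1]]
        cells = cells[vals == vals.max()]
        i, j = min((int(a), int(b)) for a, b in cells)
        peaks.append(
            EEMPeak(
                excitation_nm=float(eem.excitation_axis[i]),
                emission_nm=float(eem.emission_axis[j]),
                intensity=float(eem.intensity[i, j]),
            )
        )
    peaks.sort(key=lambda p: (-p.intensity, p.excitation_nm, p.emission_nm))
    peaks = peaks[:max_peaks]
    return [replace(p, label=f"peak {chr(ord('a') + k)}") for k, p in enumerate(peaks)]


def compare_eems(
    reference: EEMap,
    treated: EEMap,
    max_peaks: int = 2,
    scatter_half_width_nm: float = DEFAULT_SCATTER_HALF_WIDTH_NM,
    match_radius_nm: float = 20.0,
) -> list[PeakShift]:
    """Match reference peaks to nearest treated peaks and report shifts.

    Matching is Euclidean in the (Ex, Em) plane; a reference peak with no
    treated peak within ``match_radius_nm`` is flagged unmatched rather than
    raising.
    """
    if reference.shape != treated.shape or not (
        np.array_equal(reference.excitation_axis, treated.excitation_axis)
        and np.array_equal(reference.emission_axis, treated.emission_axis)
    ):
        raise ValidationError("reference and treated EEMs must share identical axes")
    ref_peaks = find_peaks(mask_scatter(reference, scatter_half_width_nm), max_peaks)
    trt_peaks = find_peaks(mask_scatter(treated, scatter_half_width_nm), max_peaks)
    shifts: list[PeakShift] = []
    for rp in ref_peaks:
        if trt_peaks:
            dists = [
                np.hypot(tp.excitation_nm - rp.excitation_nm, tp.emission_nm - rp.emission_nm)
                for tp in trt_peaks
            ]
            k = int(np.argmin(dists))
            if dists[k] <= match_radius_nm:
                tp = trt_peaks[k]
                shifts.append(
                    PeakShift(
                        reference=rp,
                        treated=tp,
                        delta_excitation_nm=tp.excitation_nm - rp.excitation_nm,
                        delta_emission_nm=tp.emission_nm - rp.emission_nm,
                        intensity_ratio=tp.intensity / rp.intensity if rp.intensity else None,
                        matched=True,
                    )
                )
                continue
        shifts.append(PeakShift(rp, None, None, None, None, matched=False))
    return shifts
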