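"""Spectral data model and plain-text readers/writers.

Containers
----------
``Spectrum``
    One measured curve: a strictly increasing axis (nm for optical data,
    cm^-1 for FTIR) and a matched intensity/absorbance array.
``AbsorptionSpectrum``
    A ``Spectrum`` of UV-Vis absorbance plus the chromophore concentration and
    cuvette path length, so molar absorptivity eps(lambda) = A/(c*l) is
    computable (Beer-Lambert).
``TitrationSeries``
    Fluorescence at a fixed emission peak versus ligand concentration at one
    temperature; the zero-concentration intensity is F0.
``EEMap``
    Excitation-emission matrix with a boolean scatter mask.

File formats are deliberately minimal instrument-export style text:
two-column delimited (comma or whitespace) for curves and titrations, and a
matrix layout (first row = emission axis, first column = excitation axis)
for EEMs. Delimiter sniffing tries comma first, then whitespace. Duplicate
axis values are collapsed by mean (repeated scans), never rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientDataError, ParseError, ValidationError

__all__ = [
    "AxisKind",
    "SignalKind",
    "Spectrum",
    "AbsorptionSpectrum",
    "TitrationSeries",
    "EEMap",
    "read_spectrum",
    "write_spectrum",
    "read_titration",
    "write_titration",
    "read_eem",
    "write_eem",
]


class AxisKind(str, enum.Enum):
    WAVELENGTH_NM = "wavelength_nm"
    WAVENUMBER_CM1 = "wavenumber_cm-1"


class SignalKind(str, enum.Enum):
    FLUORESCENCE_EMISSION = "fluorescence_emission"
    UV_VIS_ABSORBANCE = "uv_vis_absorbance"
    FTIR_ABSORBANCE = "ftir_absorbance"


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Spectrum:
    """A single spectral curve with axis-kind and signal-kind metadata."""

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: AxisKind = AxisKind.WAVELENGTH_NM
    signal_kind: SignalKind = SignalKind.FLUORESCENCE_EMISSION
    label: str = ""

    def __post_init__(self):
        self.axis = _as_1d_float(self.axis, "axis")
        self.intensity = _as_1d_float(self.intensity, "intensity")
        self.axis_kind = AxisKind(self.axis_kind)
        self.signal_kind = SignalKind(self.signal_kind)
        if self.axis.size != self.intensity.size:
            raise ValidationError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) lengths differ"
            )
        if self.axis.size and not np.all(np.diff(self.axis) > 0):
            raise ValidationError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensity)):
            raise ValidationError("axis and intensity must be finite")

    def __len__(self) -> int:
        return self.axis.size

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum restricted to axis values in [lo, hi]."""
        sel = (self.axis >= lo) & (self.axis <= hi)
        return replace(self, axis=self.axis[sel], intensity=self.intensity[sel])


@dataclass
class AbsorptionSpectrum(Spectrum):
    """Absorbance curve carrying the Beer-Lambert context (c in mol/L, l in cm)."""

    molar_concentration: float = 1.0e-5
    path_length_cm: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if self.molar_concentration <= 0:
            raise ValidationError("molar_concentration must be > 0")
        if self.path_length_cm <= 0:
            raise ValidationError("path_length_cm must be > 0")

    def molar_absorptivity(self) -> np.ndarray:
        """eps(lambda) = A(lambda) / (c * l), in L mol^-1 cm^-1."""
        return self.intensity / (self.molar_concentration * self.path_length_cm)


@dataclass
class TitrationSeries:
    """Fluorescence-vs-ligand-concentration series at one temperature.

    Concentrations are mol/L, strictly increasing from 0; F0 is the intensity
    of the ligand-free protein (first entry).
    """

    ligand_concentrations: np.ndarray
    intensities: np.ndarray
    temperature_K: float = 298.0
    peak_wavelength_nm: float = 340.0

    def __post_init__(self):
        self.ligand_concentrations = _as_1d_float(self.ligand_concentrations, "ligand_concentrations")
        self.intensities = _as_1d_float(self.intensities, "intensities")
        if self.ligand_concentrations.size != self.intensities.size:
            raise ValidationError("concentration and intensity lengths differ")
        if self.ligand_concentrations.size < 1 or self.ligand_concentrations[0] != 0.0:
            raise ValidationError(
                "first ligand concentration must be exactly 0 (defines F0, the unquenched intensity)"
            )
        if not np.all(np.diff(self.ligand_concentrations) > 0):
            raise ValidationError("ligand concentrations must be strictly increasing")
        if not np.all(self.intensities > 0):
            raise ValidationError("fluorescence intensities must be positive")
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive")

    @property
    def F0(self) -> float:
        return float(self.intensities[0])

    def __len__(self) -> int:
        return self.ligand_concentrations.size


@dataclass
class EEMap:
    """Excitation-emission matrix: intensity[i, j] at (excitation_axis[i], emission_axis[j]).

    ``mask`` is True where a cell is scatter-excluded; masked cells never enter
    peak statistics.
    """

    excitation_axis: np.ndarray
    emission_axis: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.excitation_axis = _as_1d_float(self.excitation_axis, "excitation_axis")
        self.emission_axis = _as_1d_float(self.emission_axis, "emission_axis")
        self.intensity = np.asarray(self.intensity, dtype=float)
        for name, ax in (("excitation_axis", self.excitation_axis), ("emission_axis", self.emission_axis)):
            if not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        expected = (self.excitation_axis.size, self.emission_axis.size)
        if self.intensity.shape != expected:
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match axes {expected}"
            )
        if self.mask is None:
            self.mask = np.zeros(expected, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != expected:
                raise ValidationError(f"mask shape {self.mask.shape} does not match axes {expected}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


# ---------------------------------------------------------------------------
# parsing helpers

def _split_line(line: str) -> list[str]:
    # comma first, then whitespace — covers typical instrument exports
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    return line.split()


def _read_pairs(path) -> list[tuple[float, float]]:
    """Parse a two-column text file, tolerating a single header line."""
    pairs: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_allowed = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = _split_line(line)
        try:
            values = [float(t) for t in tokens if t != ""]
        except ValueError:
            if header_allowed:
                header_allowed = False
                continue
            raise ParseError(f"{path}: non-numeric row at line {lineno}: {line!r}")
        header_allowed = False
        if len(values) != 2:
            raise ParseError(f"{path}: expected two columns at line {lineno}, got {len(values)}")
        pairs.append((values[0], values[1]))
    return pairs


def _collapse_duplicates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by x and mean-collapse repeated x values."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size == x.size:
        return x, y
    sums = np.bincount(inverse, weights=y)
    counts = np.bincount(inverse)
    return ux, sums / counts


def read_spectrum(
    path,
    axis_kind: AxisKind = AxisKind.WAVELENGTH_NM,
    signal_kind: SignalKind = SignalKind.FLUORESCENCE_EMISSION,
    label: str = "",
) -> Spectrum:
    """Read a two-column delimited text file into a validated ``Spectrum``.

    Rows are sorted by axis; duplicate axis values are collapsed by mean.
    """
    pairs = _read_pairs(path)
    if len(pairs) < 3:
        raise InsufficientDataError(f"{path}: need at least 3 data points, found {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    x, y = _collapse_duplicates(x, y)
    return Spectrum(axis=x, intensity=y, axis_kind=axis_kind, signal_kind=signal_kind, label=label)


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("axis,intensity\n")
        for a, i in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{a:.12e},{i:.12e}\n")


def read_titration(path, temperature_K: float = 298.0, peak_wavelength_nm: float = 340.0) -> TitrationSeries:
    """Read a concentration/intensity file; the first concentration must be 0 (F0 row)."""
    pairs = _read_pairs(path)
    if not pairs:
        raise InsufficientDataError(f"{path}: empty titration file")
    conc = np.array([p[0] for p in pairs])
    inten = np.array([p[1] for p in pairs])
    if conc[0] != 0.0:
        raise ValidationError(
            f"{path}: first row must have concentration 0 — F0 (unquenched intensity) is required"
        )
    return TitrationSeries(
        ligand_concentrations=conc,
        intensities=inten,
        temperature_K=temperature_K,
        peak_wavelength_nm=peak_wavelength_nm,
    )


def write_titration(series: TitrationSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concentration_mol_per_L,intensity\n")
        for c, i in zip(series.ligand_concentrations, series.intensities):
            fh.write(f"{c:.12e},{i:.12e}\n")


def read_eem(path) -> EEMap:
    """Read a matrix text file: first row emission axis, first column excitation axis."""
    with open(path, "r", encoding="utf-8") as fh:
        rows = [line.strip() for line in fh if line.strip()]
    if len(rows) < 2:
        raise ParseError(f"{path}: EEM file needs a header row and at least one data row")
    header = _split_line(rows[0])
    # first header cell may be a corner label (e.g. "ex\\em"); drop it if non-numeric
    try:
        float(header[0])
    except ValueError:
        header = header[1:]
    try:
        emission = np.array([float(t) for t in header])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric emission axis entry in header: {exc}")
    width = emission.size
    excitation, body = [], []
    for r, row in enumerate(rows[1:], start=2):
        tokens = _split_line(row)
        if len(tokens) != width + 1:
            raise ParseError(
                f"{path}: ragged row {r}: expected {width + 1} cells, got {len(tokens)}"
            )
        vals = []
        for c, tok in enumerate(tokens):
            try:
                vals.append(float(tok))
            except ValueError:
                raise ParseError(f"{path}: non-numeric cell at row {r}, column {c + 1}: {tok!r}")
        excitation.append(vals[0])
        body.append(vals[1:])
    return EEMap(
        excitation_axis=np.array(excitation),
        emission_axis=emission,
        intensity=np.array(body),
    )


def write_eem(eem: EEMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ex\\em," + ",".join(f"{v:.12e}" for v in eem.emission_axis) + "\n")
        for i, ex in enumerate(eem.excitation_axis):
            fh.write(f"{ex:.12e}," + ",".join(f"{v:.12e}" for v in eem.intensity[i]) + "\n")
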