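# specbind

Desk analysis of spectroscopic protein–ligand binding experiments.

When a small-molecule ligand binds a fluorescent protein (for example a
perfluoroalkyl sulfonate pollutant binding the G protein-coupled estrogen
receptor), a handful of standard calculations turn raw spectra into binding
constants, distances, thermodynamics and structural change. `specbind`
implements that whole desk-side pipeline as a tested Python library:

- **Fluorescence quenching** — Stern–Volmer fit `F0/F = 1 + Ksv[Q]`, the
  bimolecular rate `Kq = Ksv/τ0` against the 2×10¹⁰ L mol⁻¹ s⁻¹ diffusion
  limit (static vs dynamic mechanism), and the double-logarithm binding fit
  `log[(F0−F)/F] = log Ka + n log[Q]`.
- **FRET distances** — overlap integral
  `J = Σ F(λ)ε(λ)λ⁴Δλ / Σ F(λ)Δλ`, Förster radius
  `R0⁶ = 8.8×10⁻²⁵ K² N⁻⁴ Φ J`, efficiency `E = 1 − F/F0`, distance
  `r = R0((1−E)/E)^{1/6}`, and the 0.5 R0 ≤ r ≤ 1.5 R0, r < 7 nm validity
  check.
- **Thermodynamics** — van't Hoff ΔH/ΔS from Ka(T), ΔG via `−RT ln Ka` or
  `ΔH − TΔS`, the (sign ΔH, sign ΔS) → binding-force classification, and
  ligand efficiency `LE = |ΔG_binding| / N_heavy` from docking energies.
- **FTIR secondary structure** — amide-I (1600–1700 cm⁻¹) baseline removal,
  second-derivative band detection, bounded Gaussian-sum deconvolution, and
  class percentages from the standard assignment windows (β-sheet
  1610–1640, coil 1640–1650, α-helix 1650–1660, β-turn 1660–1680,
  antiparallel β 1680–1692 cm⁻¹).
- **EEM analysis** — Rayleigh scatter masking (Em = Ex and Em = 2Ex),
  deterministic peak picking, and peak-shift/intensity comparison between
  free and ligand-bound excitation–emission matrices.
- **Synthetic data** — generators for every input class with known ground
  truth (`specbind.simulate`), so the full pipeline is testable without any
  instrument data.

Plain-text I/O only: two-column delimited files for spectra and titrations,
a matrix layout for EEMs.

## Worked example

```python
from specbind.fret import fret_analysis
from specbind.simulate import gen_optical_spectra

emission, absorption = gen_optical_spectra()   # 340 nm donor + matched acceptor band
result = fret_analysis(emission, absorption, F=870.0, F0=1000.0)
print(f"J  = {result.J:.3e} cm^3 L/mol")
print(f"R0 = {result.R0_nm:.2f} nm   r = {result.r_nm:.2f} nm   valid = {result.valid}")
```

prints

```
J  = 6.791e-14 cm^3 L/mol
R0 = 3.50 nm   r = 4.81 nm   valid = True
```

i.e. the donor–acceptor spectral overlap puts the critical transfer radius
at 3.50 nm, and a 13% quench at 1:1 molar ratio places the ligand 4.81 nm
from the protein fluorophore — inside the 0.5–1.5 R0, < 7 nm window where
non-radiative energy transfer is a credible quenching contribution.

Each capability has a narrative script under `examples/` (quenching,
FRET, thermodynamics, FTIR, EEM, and a files-on-disk full study via
`specbind.report.run_full_study`); every script prints the numbers it
computes and one line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the two closed-form FRET worked examples with the library — the
Förster radius from a printed overlap integral with the standard constants
(K² = 2/3, N = 1.34, Φ = 0.15), and a donor–acceptor distance from a
printed (R0, E) pair — and writes them as JSON.
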