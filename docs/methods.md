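# Methods

This note documents the models implemented in `specbind`, the defaults and
numerical choices, what the synthetic generators do and do not emulate, and
the known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Quenching (`specbind.quenching`)

**Model.** Stern–Volmer: `F0/F = 1 + Ksv[Q] = 1 + Kq τ0 [Q]`, fitted by
ordinary least squares of `F0/F` on `[Q]` over all titration points
(including the zero-concentration anchor, whose ratio is exactly 1). The
intercept is deliberately left free rather than constrained to 1: the model
fixes it, so a fitted deviation beyond 5% is a useful instrument-drift
diagnostic and is reported in `flags`. Perfectly flat data returns
`Ksv = 0` (no quenching is a result, not an error).

**Mechanism rule.** `Kq = Ksv/τ0` with τ0 defaulting to 1×10⁻⁸ s (typical
intrinsic lifetime of tryptophan-dominated protein emission; overridable
since it is only approximately known). Static quenching is declared iff
`Kq > 2×10¹⁰ L mol⁻¹ s⁻¹` **strictly** — the diffusion-controlled maximum
for collisional quenching; a value exactly at the limit is classified
dynamic.

**Binding fit.** `log10[(F0−F)/F] = log10 Ka + n log10[Q]` by OLS on the
nonzero-concentration points. Logarithms are base 10, so `Ka =
10^intercept`. Points with `F ≥ F0` at `[Q] > 0` have no defined ordinate
and are dropped with a warning (clamping them would bias the slope); at
least 3 usable points are required.

**Noise sensitivity.** The intercept of the double-log line sits at
`log10[Q] = 0`, roughly 6.5 decades below a 10⁻⁷–10⁻⁶ M concentration
window, so per-point noise on `log10[(F0−F)/F]` is amplified ~7× into
`log10 Ka`. At 1% multiplicative intensity noise individual replicate Ka
estimates scatter by roughly ±20%, while the estimator is median-unbiased:
the recovery guarantee asserted by the tests is that the **median**
recovered Ka over 100 seeded replicates lies within 5% of the generating
value. A user wanting tighter single-experiment Ka precision needs either
lower noise, a wider concentration range, or a nonlinear fit of the
untransformed binding isotherm (out of scope here, since the double-log
line is the field's standard reporting form).

## FRET (`specbind.fret`)

**Overlap integral.** Emission and molar absorptivity (from absorbance via
Beer–Lambert, `ε = A/(c·l)`, default path length 1 cm) are linearly
interpolated onto a shared 1 nm grid over the common wavelength interval and
combined as `J = ∫F ε λ⁴ dλ / ∫F dλ` with trapezoid sums. **Wavelength is
converted to cm inside the integral**: only that convention makes the
`8.8×10⁻²⁵` prefactor of the Förster relation return the published radii
from published J values (verified analytically and by the acceptance
worked examples), giving J in cm³ L mol⁻¹ at the familiar 10⁻¹⁴ magnitude.
Disjoint spectra yield `J = 0` with a warning; zero emission over the
overlap is an error (the normalisation is undefined). The 1 nm grid agrees
with a 0.01 nm brute-force quadrature within 0.1% for smooth band shapes
(property-tested).

**Constants.** `K² = 2/3` (isotropic dynamic averaging of the dipole
orientation factor), `N = 1.34` (aqueous protein solution), `Φ = 0.15`
(tryptophan-like donor quantum yield). All overridable — they are
approximations, and any published comparison should quote them.

**Distance and validity.** `E = 1 − F/F0` at 1:1 donor:acceptor molar ratio
(a documentation-level requirement: only intensities enter the code);
`r = R0((1−E)/E)^{1/6}`. `E = 0` raises (infinite distance); `E = 1`
returns `r = 0` with a warning. The distance is deemed reliable iff
`0.5 R0 ≤ r ≤ 1.5 R0` and `r < 7 nm` — outside that window the sixth-power
law loses sensitivity and reported distances are not meaningful.

## Thermodynamics (`specbind.thermo`)

`ΔH` from the van't Hoff relation: the two-point closed form
`ΔH = R ln(K2/K1)/(1/T1 − 1/T2)`, or for more than two temperatures the
slope of OLS `ln Ka` on `1/T` (`ΔH = −slope·R`), which reduces to the
closed form at two points. `ΔS` comes from the same line's intercept
(`ΔS = R·intercept`), and the stored per-temperature `ΔG` map is evaluated
from `(ΔH, ΔS)` via `ΔG = ΔH − TΔS`, so the Gibbs identity holds to
machine precision for every stored temperature. `R = 8.314 J mol⁻¹ K⁻¹`;
units follow the field's reporting convention (ΔH, ΔG in kJ/mol; ΔS in
J mol⁻¹ K⁻¹).

**Force classification.** `(+ΔH, +ΔS)` hydrophobic; `(−, −)` hydrogen
bonding / van der Waals; `(−, +)` electrostatic; `(+, −)` has no assignment
in the standard table and maps to `unclassified`, as does any value within
1×10⁻⁹ of zero (with a warning) — signs indistinguishable from zero should
not silently pick a force.

**Ligand efficiency.** `LE = |ΔG_binding|/N_heavy`, reported positive
(binding energies are negative-favourable; efficiency is a magnitude).
Heavy atoms are counted from a Hill-style formula with full element-symbol
validation; **the caller supplies the anion formula for salts** (e.g.
`C4F9O3S` for a potassium perfluorobutanesulfonate salt) so counter-ions do
not inflate the count.

## Amide-I deconvolution (`specbind.ftir`)

**Window and baseline.** The 1600–1700 cm⁻¹ window is cut (full coverage
required; internal gaps over 10 cm⁻¹ rejected) and a straight line through
the window endpoints subtracted. Negatives are clipped to zero; a clip
deeper than 2% of the maximum triggers a warning that the linear baseline
model is inadequate.

**Band detection.** Centers are negative minima of the second derivative of
a 9-point, order-3 Savitzky–Golay smooth (derivative evaluated analytically
by the filter). Second derivatives resolve overlapped amide-I components
at separations down to ≈2.5σ. Candidates need ≥1% of the maximum
absorbance; at most 8 are kept. No Fourier self-deconvolution preprocessing
is applied — the second-derivative route needs no tunable bandwidth/
enhancement parameters and serves the same role; this is a deliberate
interpretation of the usual "deconvolution fitting" workflow.

**Fit.** Nonlinear least squares (trust-region reflective, scipy) of a
Gaussian sum. Gaussians rather than Voigt/Lorentzian profiles: the standard
choice for amide-I curve fitting when no lineshape evidence says otherwise.
Bounds: centers within ±8 cm⁻¹ of their guesses and inside the window;
σ ∈ [2, 25] cm⁻¹; amplitudes ≥ 0. Up to three restarts with perturbed
initial widths (fixed internal seed — the pipeline is deterministic for a
given input); failure raises `FitError` carrying the best residual.

**Assignment.** Half-open windows with ties at the shared endpoints
1640/1650/1660/1680 going to the higher-wavenumber class (a convention the
shared published ranges force one to fix; it is tested explicitly).
1600–1610 and 1692–1700 cm⁻¹ carry no assignment in the standard table;
bands there are excluded from the percentage base rather than merged into a
neighbour. Percentages are band-area shares of the assigned area and always
sum to 100 ± 0.1.

## EEM analysis (`specbind.eem`)

Scatter masking removes `|Em − Ex| ≤ w` (first-order Rayleigh) and
`|Em − 2Ex| ≤ w` (second order) with `w` defaulting to 15 nm — three grid
steps at the conventional 5 nm instrument increment; the width is not a
published quantity, so it is configurable. Peaks are 8-neighbour local
maxima over unmasked cells; connected equal-valued plateaus contribute one
peak at their lexicographically smallest (Ex, Em) cell, making output
deterministic. No sub-grid interpolation is performed: shifts are reported
at grid resolution, which suffices for the few-nm shifts of interest
(generate on a 1 nm grid when a 3 nm shift must be resolved exactly).
Peak matching between two maps is nearest-neighbour Euclidean in (Ex, Em)
with a 20 nm matching radius; unmatched peaks are flagged, not errors.

## Synthetic generators (`specbind.simulate`)

All generators are deterministic functions of `GeneratorConfig(seed,
noise_fraction)`; noise is multiplicative Gaussian (detector noise scales
with signal), default 1%.

- **Titrations**: `F = F0/(1 + Ka[Q]^n)` — the exact inverse of the
  double-log model, so the noiseless fit target is well-specified; defaults
  Ka = 2×10⁶ L/mol, n = 1 (the strong-binding, single-site regime of
  protein–perfluoroalkyl sulfonate systems) on the conventional 0–9×10⁻⁷ M
  grid. Noise applies only at [Q] > 0 (F0 is the reference).
- **Optical pair**: Gaussian donor emission (340 nm, σ 20 nm — the typical
  tryptophan emission peak position) and Gaussian acceptor absorption
  (centre 340 nm, σ 40 nm on the 300–450 nm UV-Vis scan range). The default
  peak absorptivity 5.5×10⁴ L mol⁻¹ cm⁻¹ was fixed analytically (Gaussian
  product integral) so the default pair's overlap integral lands at the
  ~6.7×10⁻¹⁴ cm³ L mol⁻¹ magnitude of real protein–ligand pairs, i.e. a
  peak absorbance of 0.55 at the default 10⁻⁵ M — realistic instrument
  territory.
- **Amide-I composites**: up to five Gaussian bands, one per class, at
  default centers 1625/1645/1655/1670/1686 cm⁻¹ with σ = 4 cm⁻¹ — inside
  the fit bounds and narrow enough (≥2.5σ separation) for second-derivative
  detection to resolve the 10 cm⁻¹-spaced coil/helix windows. Areas are
  proportional to the requested class fractions; active-band centers are
  validated against their class windows.
- **EEMs**: two 2-D Gaussian fluorophore peaks (defaults Ex 280/230 nm, Em
  340 nm — the aromatic-residue and peptide-backbone excitation regions)
  plus a first-order Rayleigh ridge along Em = Ex, on the 200–450 nm grid.

**What a green test establishes — and does not.** The generators produce
smooth, noise-scaled, single-model data. They do not emulate inner-filter
absorption of exciting/emitted light, lifetime kinetics, mixed
static+dynamic quenching, Raman scatter, non-Gaussian band shapes, sloping
fluorescence backgrounds in EEMs, or wavenumber-dependent FTIR baselines
beyond a straight line. Recovery of generator truth therefore validates the
estimators and their numerics, not robustness to every instrument artefact.

## Known limitations

- No sphere-of-action or combined static/dynamic quenching models; no
  global multi-temperature fitting of titrations.
- No orientation-factor estimation (K² fixed unless overridden); no
  lifetime-based FRET.
- Secondary-structure percentages depend on the detected band count; for
  heavily overlapped composites where a minor class sits entirely under a
  neighbour the area split is not identifiable from a single spectrum.
- EEM peak positions are grid-limited by design.
- The study runner (`specbind.report`) orchestrates files and collates
  results; it adds no statistics of its own.
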