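# Methods

## Scope and model

`slaterff` computes spherical (independent-atom) scattering factors as exact
analytic Fourier transforms of Slater-type atomic wavefunctions, converts
them to electron-diffraction factors through the Mott–Bethe relation, and
provides the surrounding crystallographic plumbing: reflection geometry,
Debye–Waller factors, kinematic structure factors, SHELX-type weighting and
R statistics, the `.tsc` interchange format, and FFT Fourier syntheses of
difference and residual density maps with a Meindl–Henn-style residual
analysis.  Least-squares refinement itself, non-spherical (Hirshfeld-atom)
scattering factors, dynamical diffraction, extinction corrections and
anomalous dispersion are out of scope.

## Conventions and their anchors

* **Units.**  Wavefunctions live in bohr (exponents `ζ` in bohr⁻¹, densities
  in e·bohr⁻³); everything crystallographic lives in ångströms.  The single
  conversion (1 bohr = 0.52917721 Å) happens at the scattering-vector
  boundary: the public API takes `s = sin θ/λ` in Å⁻¹ and internally uses
  `k = 4πs` converted to bohr⁻¹.
* **Density prefactor.**  The `1/(4π)` spherical-averaging factor sits in
  `radial_density`, so the Fourier transform carries the plain `4πr²` volume
  element.  The split is pinned by the invariant `f(0) =` electron count,
  which tests enforce to 1e−12 for every species.
* **Map synthesis.**  `ρ(x) = (1/V) Σ_h F(h) e^(−2πi h·x)` with
  `F(h) = Σ occ·f·DW·e^(+2πi h·x)`; validated by the constant-map, cosine-map
  and atom-peak-position tests.
* **Mott–Bethe prefactor.**  Computed from CODATA constants as
  `m₀e²/(8πε₀h²)` and independently as `1/(8π²a₀)`; the import fails unless
  they agree to 1e−9 relative.  This guards the `h` vs `ħ` / `8π` vs `8π²`
  unit trap in the transform.

## Numerical choices

* The STO transform reduces every density cross term `w·r^m e^(−Zr)` to
  `∫ r^(m+1) e^(−Zr) sin(kr) dr`.  The production path uses the closed form
  `m!·Im[(a−ib)^(−(m+1))]`; the two-term partial-integration recursion is a
  second, independent implementation kept for cross-checking (they agree to
  1e−12 relative for `m ≤ 16`; high-precision quadrature via mpmath is a
  third oracle in the tests).
* Below `k = 1e−8` bohr⁻¹ the transform switches to the analytic `k → 0`
  limit `(m+2)!/Z^(m+3)`; continuity across the switch is tested to 1e−9.
* Near `s = 0` the Mott–Bethe numerator `Z − f^X` is a difference of nearly
  equal numbers; below `k = 1e−2` bohr⁻¹ it is evaluated by the sinc Taylor
  series (terms to order `k²⁰`), which restores full relative accuracy
  through the `1/s²` amplification.  Neutral species then reach the analytic
  limit `⟨r²⟩/(3a₀)` smoothly; charged species raise a divergence error at
  `s = 0`, because their kinematic scattering genuinely diverges — the
  `.tsc` builder never requests `s = 0` (the 000 reflection is excluded), so
  electron-diffraction table generation cannot trip over it.
* The cross-term expansion of each squared contracted orbital is computed
  once per species and cached; results are bitwise identical to naive
  re-evaluation (same summation order).
* Structure factors expand sites to P1 before summation, de-duplicating
  symmetry images closer than 1e−4 fractional (minimal image), so special
  positions are not double counted; deposited occupancies are trusted as-is.
* `fourier_map` Friedel-completes its coefficient set, rejects coefficients
  the grid cannot index (`|h_i| > (n_i−1)/2`), and fails if the synthesized
  map is not real to 1e−10 relative.  F(000) is excluded from difference and
  residual maps (its scale is unknown there), making them zero-mean.
* `.tsc` values are quantized to the written 8-significant-digit precision
  at build time, so `read(write(t)) == t` holds exactly.
* R1 uses the `I > 2σ` cutoff; in the weighting scheme
  `w = 1/(σ² + (aP)² + bP)` with `P = (max(F_o², 0) + 2F_c²)/3`, negative
  observed intensities are preserved and clamped only inside `P`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| hydrogen ζ | 1.15 bohr⁻¹ | bonded-atom exponent (free-atom 1.0 selectable) |
| `d_min` | CLI required | resolution limit of the reflection sphere (Å) |
| map grid | axis step ≤ `d_min/4` | `default_dims`; any dims reachable explicitly, including coarse peak-search (e.g. 40×45×60) and fine fractal-analysis (120×144×180) regimes |
| fractal bins | 101 | equal-width density bins for the d^f curve; only non-empty bins are reported |
| weighting `a`, `b` | caller-supplied | SHELX-type weighting coefficients |
| dedup tolerance | 1e−4 fractional | special-position identification |

## Synthetic data

The fixture generator defines the conditions everything is tested under:

* **Wavefunctions.**  Hydrogen is exact.  Heavier bundled species are
  minimal-basis single-ζ wavefunctions from Slater's screening rules,
  labelled synthetic in file and docstring; they satisfy every structural
  invariant (unit-norm orbitals, electron counts, positive exponents) but do
  not reproduce literature-quality densities near the nucleus, so tests
  passing on them validate the machinery, not the chemistry of any specific
  published table.  Transcribed large-basis tables drop into the same text
  format.  Random multi-primitive species (`make_synthetic_species`)
  unit-normalize their contractions through the closed-form Gram matrix.
* **Gaussian models.**  The bundled 4G+c X-ray coefficients for H, C, N, O,
  Ca are the standard reference-table transcription (sums `Σa+c` match
  electron counts to < 0.01).  The Peng-style 4G electron model is a
  synthetic deterministic least-squares fit to this package's own
  Mott–Bethe curves, used where a Gaussian electron parameterization is
  needed structurally.
* **Toy crystals.**  P1 or P2₁/c cells (default 8×9×10 Å, 1–5 sites) with
  `F_o² = |F_c|²(1+ε)`, `ε ~ N(0, noise_fraction)` (default 2 %) and
  `σ(F_o²) = noise_fraction·|F_c|²` floored at 0.01 so zero-noise fixtures
  satisfy `σ > 0` and survive the two-decimal HKLF 4 format.  Output is
  byte-identical under a fixed seed.  What the toys do **not** emulate:
  absorption, extinction, dynamical scattering, twinning, anisotropic mosaic
  effects — conclusions about those cannot be drawn from these tests.

Problem sizes in the test-suite and acceptance script (reflection spheres to
`d_min = 1 Å` on 10 Å cells, ~3000 reflections; 22³–64³ map grids; ≤ 500
Fourier coefficients for direct-summation oracles) were chosen so each check
runs in seconds while leaving the quantities being verified (agreement with
oracles, conservation laws, peak positions) fully resolved.

## Known limitations

* Bundled non-hydrogen wavefunctions are minimal-basis synthetics; users
  wanting published-quality factors must supply transcribed coefficient
  tables (the format and ion-fallback logic support them directly).
* Only integer charges −1/0/+1 are modelled; no partial charges.
* The aufbau configuration in the Slater-rules generator ignores d-block
  exceptions (Cr, Cu, …).
* The fractal-dimension curve follows the standard histogram construction
  (`d^f = 3·ln N(ρ₀)/ln N_total`); its exact binning is a convention, so
  comparisons against other implementations should be qualitative.
* Kinematic intensities only; refinement against dynamical electron
  diffraction data needs machinery outside this package.
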