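# slaterff

Analytic atomic scattering factors for X-ray and electron diffraction,
computed directly from Slater-type atomic wavefunctions — no Gaussian
fitting, no interpolation — together with the machinery needed to use them
against crystallographic data: kinematic structure factors, the `.tsc`
scattering-factor interchange format with a command-line generator, and
Fourier difference/residual density maps with residual-density analysis.

## Who this is for

Crystallographers and method developers who want spherical (independent-atom)
scattering factors with the correct physics at both ends of the scattering
vector: the nuclear cusp that no finite Gaussian expansion can represent
(which shows up at high `sin θ/λ`), and the exponential long-range tail of
the atomic density (which shows up in the low-order reflections).  The
conventional four-Gaussian-plus-constant (4G+c) parameterization gets both
regimes slightly wrong, and the errors concentrate around heavy atoms as
structured residual density.

## The model

An atom's spherically averaged electron density from contracted Slater-type
orbitals (STOs) is

    ρ(r) = (1/4π) Σ_i o_i [ Σ_j N_j c_j r^(n_j−1) e^(−ζ_j r) ]² ,

with occupations `o_i`, contraction coefficients `c_j`, radial orders `n_j`,
exponents `ζ_j` (bohr⁻¹) and normalization `N = (2ζ)^(n+1/2)/√(2n)!`.  Its
X-ray form factor is the analytic Fourier transform

    f^X(s) = ∫ 4π r² ρ(r) sinc(kr) dr ,   k = 4π s ,  s = sin θ/λ ,

which for STOs reduces to elementary integrals
`∫ r^m e^(−ar) sin(br) dr = m!·Im[(a−ib)^(−(m+1))]`, evaluated both in
closed form and by a partial-integration recursion (the two are
cross-checked to 1e−12).  Electron-diffraction factors follow exactly from
the Mott–Bethe transformation

    f^e(s) = C (Z − f^X(s)) / s² ,   C = m₀e²/(8π ε₀ h²) = 1/(8π² a₀) ,

with the analytic limit `f^e(0) = ⟨r²⟩/(3a₀)` for neutral atoms and a
deliberate divergence error for ions at `s = 0` (the Coulomb monopole
genuinely diverges).  Kinematic structure factors, SHELX-type weighting
statistics (R1, wR2), `.tsc` tables and FFT Fourier syntheses of
difference/residual maps complete the pipeline.

Bundled light-atom wavefunctions are exact for hydrogen (single ζ, bonded
default ζ = 1.15 bohr⁻¹) and synthetic minimal-basis (Slater screening
rules) for heavier elements; the text table format accepts transcriptions of
published large-basis Hartree–Fock Slater tables unchanged.

## Worked example

```python
import numpy as np
from slaterff import (make_hydrogen, xray_form_factor, ed_form_factor,
                      ed_limit, MOTT_BETHE_C)

h_free = make_hydrogen(1.0)      # free atom, zeta = 1.0 bohr^-1
h_bond = make_hydrogen(1.15)     # bonded atom, zeta = 1.15 bohr^-1

print(xray_form_factor(h_free, 0.0))   # 1.0        (f(0) = electron count)
print(ed_limit(h_free))                # 0.5291772  (the Bohr radius, in A)
print(ed_limit(h_bond))                # 0.4001340  (a0 / 1.15^2)
print(MOTT_BETHE_C)                    # 0.0239337  (A^-1)
```

`f^X(0)` returns exactly the electron count, and the `s → 0` electron
scattering limit of free hydrogen is the Bohr radius in ångströms — two
closed-form anchors that pin the unit conventions of the whole pipeline.

Generating scattering-factor tables from the shell:

```sh
slaterff -cif toy.cif -IAM -dmin 0.8          # writes toy.tsc (X-ray)
slaterff -cif toy.cif -IAM -dmin 0.8 -ED      # Mott-Bethe electron factors
slaterff -cif toy.cif -IAM -dmin 0.8 -Anions O1 O2 -Cations Ca1
slaterff fixtures outdir/                     # emit the synthetic fixture bundle
```

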