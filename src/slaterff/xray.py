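"""Analytic X-ray form factors from Slater wavefunctions, and Gaussian models.

The X-ray atomic scattering factor is the three-dimensional Fourier transform
of the spherically averaged electron density,

    f(k) = integral_0^inf 4 pi r^2 rho(r) sin(k r)/(k r) dr ,

with scattering-vector length ``k = 4 pi sin(theta)/lambda``.  For Slater-type
densities every cross term is ``w r^m exp(-Z r)`` and the transform reduces to
elementary integrals

    I_sin(m, a, b) = integral_0^inf r^m e^(-a r) sin(b r) dr
    I_cos(m, a, b) = integral_0^inf r^m e^(-a r) cos(b r) dr

which obey a two-term partial-integration recursion and the closed forms
``m! Im/Re[(a - i b)^(-(m+1))]``.  Both routes are implemented and must agree;
the closed form is the production path.

Unit convention: the public API takes ``s = sin(theta)/lambda`` in A^-1 (the
axis every diffraction table uses); internally ``k = 4 pi s`` is converted to
bohr^-1 because the wavefunction exponents are tabulated in bohr^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .wavefunctions import (
    BOHR_ANGSTROM,
    SlaterWavefunction,
    WavefunctionError,
    density_terms,
)

#: below this |k| (bohr^-1) the analytic k->0 limit replaces the sinc integral
K_SMALL = 1e-8


def slater_sin_integral(m: int, a: float, b: float, method: str = "closed") -> float:
    """``integral_0^inf r^m e^(-a r) sin(b r) dr`` for m >= 0, a > 0.

    method="closed" evaluates ``m! * Im[(a - i b)^(-(m+1))]``;
    method="recursion" uses the partial-integration recursion seeded by the
    m = 0 kernels.  The two agree to near machine precision.
    """
    _check_ma(m, a)
    if method == "closed":
        return math.factorial(m) * ((a - 1j * b) ** (-(m + 1))).imag
    if method == "recursion":
        return _recursion(m, a, b)[0]
    raise ValueError(f"unknown method {method!r}")


def slater_cos_integral(m: int, a: float, b: float, method: str = "closed") -> float:
    """``integral_0^inf r^m e^(-a r) cos(b r) dr``; see :func:`slater_sin_integral`."""
    _check_ma(m, a)
    if method == "closed":
        return math.factorial(m) * ((a - 1j * b) ** (-(m + 1))).real
    if method == "recursion":
        return _recursion(m, a, b)[1]
    raise ValueError(f"unknown method {method!r}")


def _check_ma(m: int, a: float) -> None:
    if m < 0 or int(m) != m:
        raise ValueError(f"m must be a non-negative integer, got {m!r}")
    if a <= 0:
        raise ValueError(f"decay constant a must be positive, got {a!r}")


def _recursion(m: int, a: float, b: float) -> tuple[float, float]:
    """(I_sin, I_cos) by the two-term partial-integration recursion."""
    denom = a * a + b * b
    i_sin = b / denom
    i_cos = a / denom
    for k in range(1, m + 1):
        i_sin, i_cos = (
            k / denom * (a * i_sin + b * i_cos),
            k / denom * (a * i_cos - b * i_sin),
        )
    return i_sin, i_cos


def xray_form_factor(wf: SlaterWavefunction, s):
    """X-ray scattering factor f(s) in electrons; s = sin(theta)/lambda in A^-1.

    Vectorized over s.  ``f(0)`` is the analytic limit and equals the electron
    count for unit-normalized orbitals; the switch to the limit happens below
    ``k = 1e-8`` bohr^-1 and f is continuous there.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise WavefunctionError("sin(theta)/lambda must be non-negative")
    # k in bohr^-1: k[A^-1] = 4 pi s, then 1 A^-1 = BOHR_ANGSTROM bohr^-1
    k = 4.0 * math.pi * s_arr * BOHR_ANGSTROM
    out = np.zeros_like(s_arr)
    small = k < K_SMALL
    ks = np.where(small, 1.0, k)  # placeholder to avoid divide-by-zero
    for m, z, w in density_terms(wf):
        # term w r^m e^(-z r) of 4 pi rho contributes
        #   (w / k) * I_sin(m + 1, z, k)   for k > 0
        #   w * (m + 2)! / z^(m + 3)       in the k -> 0 limit
        mi = m + 1
        fac = math.factorial(mi)
        vals = fac * ((z - 1j * ks) ** (-(mi + 1))).imag / ks
        limit = math.factorial(m + 2) / z ** (m + 3)
        out = out + w * np.where(small, limit, vals)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gaussian reference models (4G+c and 5G parameterizations)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFFModel:
    """Sum-of-Gaussians form factor ``f(s) = sum a_i exp(-b_i s^2) + c``.

    The conventional 4G+c X-ray parameterization and Peng-style 4G electron
    parameterization (c = 0, values in A) both fit this shape; a fifth term
    covers 5G fits.
    """

    species: str
    a: tuple[float, ...]
    b: tuple[float, ...]          # A^2
    c: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(self.a))
        object.__setattr__(self, "b", tuple(self.b))
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have equal length")
        if any(bi < 0 for bi in self.b):
            raise ValueError("Gaussian widths b_i must be non-negative")


def gaussian_form_factor(model: GaussianFFModel, s):
    """Evaluate a Gaussian form-factor model at s = sin(theta)/lambda (A^-1)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise WavefunctionError("sin(theta)/lambda must be non-negative")
    s2 = s_arr * s_arr
    out = np.full_like(s_arr, model.c)
    for ai, bi in zip(model.a, model.b):
        out = out + ai * np.exp(-bi * s2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Tabulated curves
# ---------------------------------------------------------------------------

@dataclass
class ScatteringCurve:
    """A scattering factor tabulated on an s grid for one species.

    values are electrons for X-ray curves, angstroms for electron curves.
    """

    species: str
    radiation: str                 # "xray" | "electron"
    s_grid: np.ndarray             # A^-1, strictly increasing, >= 0
    values: np.ndarray

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radiation not in ("xray", "electron"):
            raise ValueError(f"radiation must be 'xray' or 'electron', got {self.radiation!r}")
        if self.s_grid.ndim != 1 or self.s_grid.size == 0:
            raise ValueError("s_grid must be a non-empty 1-d array")
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if self.s_grid[0] < 0:
            raise ValueError("s_grid must be non-negative")
        if self.values.shape != self.s_grid.shape:
            raise ValueError("values and s_grid shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def to_csv(self) -> str:
        lines = [f"# species={self.species} radiation={self.radiation}", "s,f"]
        lines += [f"{s:.8g},{v:.8g}" for s, v in zip(self.s_grid, self.values)]
        return "\n".join(lines) + "\n"


def tabulate_xray(wf: SlaterWavefunction, s_grid) -> ScatteringCurve:
    s_grid = np.asarray(s_grid, dtype=float)
    return ScatteringCurve(wf.species, "xray", s_grid, xray_form_factor(wf, s_grid))


def tabulate_gaussian(model: GaussianFFModel, s_grid, radiation: str = "xray") -> ScatteringCurve:
    s_grid = np.asarray(s_grid, dtype=float)
    return ScatteringCurve(model.species, radiation, s_grid, gaussian_form_factor(model, s_grid))


def difference_curve(curve_a: ScatteringCurve, curve_b: ScatteringCurve) -> ScatteringCurve:
    """Pointwise A - B; both curves must share the s grid and radiation."""
    if curve_a.radiation != curve_b.radiation:
        raise ValueError("cannot subtract curves of different radiation types")
    if curve_a.s_grid.shape != curve_b.s_grid.shape or not np.allclose(
        curve_a.s_grid, curve_b.s_grid, rtol=0, atol=1e-12
    ):
        raise ValueError("curves are tabulated on different s grids")
    return ScatteringCurve(
        f"{curve_a.species}-{curve_b.species}",
        curve_a.radiation,
        curve_a.s_grid.copy(),
        curve_a.values - curve_b.values,
    )
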