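"""Electron-diffraction scattering factors via the Mott-Bethe transformation.

The electron scattering factor of an atom follows from its X-ray factor as

    f_e(s) = C * (Z - f_x(s)) / s^2 ,        C = m0 e^2 / (8 pi eps0 h^2)

with s = sin(theta)/lambda in A^-1 and f_e in A.  The prefactor C equals
``1/(8 pi^2 a0)`` with a0 the Bohr radius; both routes are computed from
CODATA constants at import time and must agree, which guards the unit
bookkeeping of the transform.

For a *neutral* species the numerator vanishes quadratically as s -> 0 and

    f_e(0) = M2 / (3 a0) ,   M2 = integral rho(r) 4 pi r^4 dr  (A^2)

the total second moment of the electron density.  For an ion the Coulomb
monopole survives and f_e diverges as ``C q / s^2``; requesting s = 0 for a
charged species raises :class:`IonDivergenceError` rather than returning
infinity, because kinematic intensities of charged species genuinely blow up
at low resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.constants as const

from .wavefunctions import BOHR_ANGSTROM, SlaterWavefunction, WavefunctionError
from .xray import GaussianFFModel, ScatteringCurve, xray_form_factor


class IonDivergenceError(WavefunctionError):
    """The s -> 0 electron scattering factor of a charged species diverges."""


@dataclass(frozen=True)
class MottBetheConstants:
    """Physical constants entering the Mott-Bethe prefactor."""

    m0: float = const.m_e
    e: float = const.e
    eps0: float = const.epsilon_0
    h: float = const.h

    @property
    def prefactor(self) -> float:
        """C = m0 e^2 / (8 pi eps0 h^2), converted from m^-1 to A^-1."""
        return self.m0 * self.e ** 2 / (8.0 * math.pi * self.eps0 * self.h ** 2) * 1e-10


#: Bohr radius in angstrom, from CODATA
A0_ANGSTROM = const.physical_constants["Bohr radius"][0] * 1e10

#: Mott-Bethe prefactor in A^-1 (about 0.023934)
MOTT_BETHE_C = MottBetheConstants().prefactor

_cross_check = 1.0 / (8.0 * math.pi ** 2 * A0_ANGSTROM)
if abs(MOTT_BETHE_C - _cross_check) > 1e-9 * _cross_check:
    raise AssertionError(
        f"Mott-Bethe prefactor {MOTT_BETHE_C} disagrees with 1/(8 pi^2 a0) = {_cross_check}"
    )


def mott_bethe(f_x, z_nuclear: int, s):
    """Transform an X-ray scattering factor value to an electron one (A).

    s must be strictly positive; the s = 0 limit needs density moments and is
    handled by :func:`ed_form_factor`.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0):
        raise WavefunctionError("mott_bethe requires s > 0; use ed_form_factor for the limit")
    out = MOTT_BETHE_C * (z_nuclear - np.asarray(f_x, dtype=float)) / s_arr ** 2
    return out if out.ndim else float(out)


def ed_limit(wf: SlaterWavefunction) -> float:
    """Analytic s -> 0 electron scattering factor of a neutral species (A)."""
    if wf.charge != 0:
        raise IonDivergenceError(
            f"f_e(0) diverges for {wf.species}: net charge {wf.charge:+d}"
        )
    m2_ang2 = wf.second_moment() * BOHR_ANGSTROM ** 2
    return m2_ang2 / (3.0 * A0_ANGSTROM)


#: below this k (bohr^-1) the deficit Z - f_x is summed as a sinc series to
#: avoid catastrophic cancellation between two nearly equal numbers
K_SERIES = 1e-2


def _deficit_series(wf: SlaterWavefunction, k_bohr: np.ndarray) -> np.ndarray:
    """Cancellation-free ``N - f_x`` via the sinc Taylor series (k in bohr^-1).

    ``N - f(k) = sum_terms w * sum_{j>=1} (-1)^(j+1) k^(2j)/(2j+1)!
    * (m+2j+2)! / z^(m+2j+3)`` for density terms ``w r^m exp(-z r)``;
    converges rapidly for k below every orbital exponent.
    """
    from .wavefunctions import density_terms

    out = np.zeros_like(k_bohr)
    k2 = k_bohr * k_bohr
    for m, z, w in density_terms(wf):
        acc = np.zeros_like(k_bohr)
        for j in range(1, 11):
            coef = (
                (-1.0) ** (j + 1)
                / math.factorial(2 * j + 1)
                * math.factorial(m + 2 * j + 2)
                / z ** (m + 2 * j + 3)
            )
            acc = acc + coef * k2 ** j
        out = out + w * acc
    return out


def ed_form_factor(wf: SlaterWavefunction, s):
    """Electron scattering factor f_e(s) in A from a Slater wavefunction.

    Vectorized over s >= 0.  At s = 0 neutral species get the analytic limit;
    ions raise :class:`IonDivergenceError`.  Near s = 0 the Coulomb deficit
    ``Z - f_x`` is evaluated by a series instead of direct subtraction, so the
    transform stays accurate through the 1/s^2 amplification.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise WavefunctionError("sin(theta)/lambda must be non-negative")
    zero = s_arr == 0
    if np.any(zero) and wf.charge != 0:
        raise IonDivergenceError(
            f"f_e(0) diverges for {wf.species}: net charge {wf.charge:+d}"
        )
    s_safe = np.where(zero, 1.0, s_arr)
    k_bohr = 4.0 * math.pi * s_safe * BOHR_ANGSTROM
    small = (k_bohr < K_SERIES) & ~zero

    f_x = xray_form_factor(wf, s_safe)
    deficit = wf.z_nuclear - np.asarray(f_x)
    if np.any(small):
        series = wf.charge + _deficit_series(wf, k_bohr)
        deficit = np.where(small, series, deficit)
    out = MOTT_BETHE_C * deficit / s_safe ** 2
    if np.any(zero):
        out = np.where(zero, ed_limit(wf), out)
    return out if np.ndim(out) else float(out)


def peng_ed_form_factor(model: GaussianFFModel, s):
    """Evaluate a Peng-style 4G electron model ``sum a_i exp(-b_i s^2)`` (A).

    The constant term must be zero: a constant would Fourier-transform to a
    delta function, which has no place in an electron scattering factor.
    """
    if model.c != 0.0:
        raise ValueError(f"electron Gaussian model must have c = 0, got c = {model.c}")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise WavefunctionError("sin(theta)/lambda must be non-negative")
    s2 = s_arr * s_arr
    out = np.zeros_like(s_arr)
    for ai, bi in zip(model.a, model.b):
        out = out + ai * np.exp(-bi * s2)
    return out if out.ndim else float(out)


def tabulate_ed(wf: SlaterWavefunction, s_grid) -> ScatteringCurve:
    s_grid = np.asarray(s_grid, dtype=float)
    return ScatteringCurve(wf.species, "electron", s_grid, ed_form_factor(wf, s_grid))
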