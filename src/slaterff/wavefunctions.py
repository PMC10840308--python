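"""Slater-type atomic wavefunctions: data model, parsing and radial densities.

A free atom or monatomic ion is described by a set of contracted radial
Slater-type orbitals (STOs).  Each contracted orbital is a linear combination
of primitives ``N c r^(n-1) exp(-zeta r)`` with integer radial order *n* and
positive exponent *zeta* (in bohr^-1, as the literature tabulates them).  The
spherically averaged electron density is

    rho(r) = (1/4pi) * sum_i o_i * [ sum_j N_j c_j r^(n_j - 1) e^(-z_j r) ]^2

where ``o_i`` is the occupation of contracted orbital *i*.  The 1/(4pi)
spherical-averaging factor lives here so that the Fourier transform downstream
carries the plain ``4 pi r^2`` volume element and ``f(0)`` equals the electron
count; see :mod:`slaterff.xray`.

All lengths in this module are in bohr.  Conversion to the angstrom-based
scattering-vector convention happens only at the form-factor boundary.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

logger = logging.getLogger(__name__)

BOHR_ANGSTROM = 0.52917721  # CODATA; 1 bohr in angstrom

#: Element symbols, index = atomic number (Z = 1..103).
ELEMENTS = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr",
)

ATOMIC_NUMBER = {symbol: z for z, symbol in enumerate(ELEMENTS, start=1)}

_SHELL_L = {"s": 0, "p": 1, "d": 2, "f": 3}


class WavefunctionError(ValueError):
    """Invalid wavefunction data (violated invariant or bad argument)."""


class WavefunctionParseError(WavefunctionError):
    """Malformed wavefunction table text; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def slater_norm(n: int, zeta: float) -> float:
    """Normalization constant of a radial Slater primitive.

    ``N = (2 zeta)^(n + 1/2) / sqrt((2n)!)`` so that
    ``integral_0^inf (N r^(n-1) e^(-zeta r))^2 r^2 dr = 1`` exactly.
    """
    if n < 1 or int(n) != n:
        raise WavefunctionError(f"radial order n must be a positive integer, got {n!r}")
    if zeta <= 0:
        raise WavefunctionError(f"Slater exponent must be positive, got {zeta!r}")
    n = int(n)
    return (2.0 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


@dataclass(frozen=True)
class SlaterPrimitive:
    """One radial Slater primitive ``N c r^(n-1) exp(-zeta r)``."""

    n: int
    zeta: float          # bohr^-1
    coeff: float         # contraction coefficient, dimensionless

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", int(self.n))
        # slater_norm validates n >= 1 and zeta > 0
        slater_norm(self.n, self.zeta)

    @property
    def norm(self) -> float:
        return slater_norm(self.n, self.zeta)


@dataclass(frozen=True)
class AtomicOrbital:
    """A contracted radial orbital with an occupation number."""

    label: str                      # e.g. "1s", "3d"
    l_ang: int
    occupation: float               # electrons, 0 <= o <= 2(2l+1)
    primitives: tuple[SlaterPrimitive, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "primitives", tuple(self.primitives))
        if not self.primitives:
            raise WavefunctionError(f"orbital {self.label}: needs at least one primitive")
        if self.l_ang < 0:
            raise WavefunctionError(f"orbital {self.label}: l must be >= 0")
        cap = 2 * (2 * self.l_ang + 1)
        if not 0 <= self.occupation <= cap:
            raise WavefunctionError(
                f"orbital {self.label}: occupation {self.occupation} outside [0, {cap}]"
            )

    def norm_integral(self) -> float:
        """``integral R(r)^2 r^2 dr`` in closed form (1 for a unit-norm orbital)."""
        return self._moment(0)

    def r2_integral(self) -> float:
        """``integral R(r)^2 r^4 dr`` in closed form (bohr^2 for unit norm)."""
        return self._moment(2)

    def _moment(self, power: int) -> float:
        total = 0.0
        for pj in self.primitives:
            wj = pj.norm * pj.coeff
            for pl in self.primitives:
                m = pj.n + pl.n + power
                zsum = pj.zeta + pl.zeta
                total += wj * pl.norm * pl.coeff * math.factorial(m) / zsum ** (m + 1)
        return total


@dataclass(frozen=True)
class SlaterWavefunction:
    """A complete atomic (or singly ionic) Slater wavefunction."""

    element: str
    z_nuclear: int
    charge: int = 0
    orbitals: tuple[AtomicOrbital, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "orbitals", tuple(self.orbitals))
        if not 1 <= self.z_nuclear <= 103:
            raise WavefunctionError(f"atomic number {self.z_nuclear} outside 1..103")
        if self.charge not in (-1, 0, 1):
            raise WavefunctionError(f"charge must be -1, 0 or +1, got {self.charge}")
        n_elec = sum(o.occupation for o in self.orbitals)
        expected = self.z_nuclear - self.charge
        if abs(n_elec - expected) > 1e-9:
            raise WavefunctionError(
                f"{self.element}{self.charge:+d}: occupations sum to {n_elec}, "
                f"expected Z - q = {expected}"
            )

    @property
    def species(self) -> str:
        if self.charge == 0:
            return self.element
        return f"{self.element}{'+' if self.charge > 0 else '-'}"

    def electron_count(self) -> float:
        """Number of electrons, ``sum_i o_i``."""
        return sum(o.occupation for o in self.orbitals)

    def electron_count_integral(self) -> float:
        """Electron count via the closed-form radial integral of the density.

        Equals :meth:`electron_count` exactly when every contracted orbital is
        unit-normalized; computed from factorial identities, not quadrature.
        """
        return sum(o.occupation * o.norm_integral() for o in self.orbitals)

    def mean_square_radius(self) -> float:
        """Density-averaged ``<r^2>`` in bohr^2, in closed form."""
        num = sum(o.occupation * o.r2_integral() for o in self.orbitals)
        den = self.electron_count_integral()
        return num / den

    def second_moment(self) -> float:
        """Total second moment ``integral rho 4 pi r^4 dr`` (bohr^2 * electrons)."""
        return sum(o.occupation * o.r2_integral() for o in self.orbitals)


@lru_cache(maxsize=512)
def density_terms(wf: SlaterWavefunction) -> tuple[tuple[int, float, float], ...]:
    """Expand ``4 pi rho(r)`` into monomial terms ``w r^m exp(-z r)``.

    Each squared contracted orbital contributes cross terms
    ``o N_j c_j N_l c_l r^(n_j + n_l - 2) exp(-(z_j + z_l) r)``.  The expansion
    is cached per species; results are identical to naive re-evaluation.
    """
    terms: dict[tuple[int, float], float] = {}
    for orb in wf.orbitals:
        if orb.occupation == 0:
            continue
        for pj in orb.primitives:
            wj = pj.norm * pj.coeff
            for pl in orb.primitives:
                key = (pj.n + pl.n - 2, pj.zeta + pl.zeta)
                terms[key] = terms.get(key, 0.0) + orb.occupation * wj * pl.norm * pl.coeff
    return tuple((m, z, w) for (m, z), w in sorted(terms.items()))


def radial_density(wf: SlaterWavefunction, r):
    """Spherically averaged electron density rho(r) in e bohr^-3.

    Accepts a scalar or ndarray radius (bohr); r must be non-negative.
    """
    import numpy as np

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise WavefunctionError("radius must be non-negative")
    out = np.zeros_like(r_arr)
    for m, z, w in density_terms(wf):
        out = out + w * r_arr ** m * np.exp(-z * r_arr)
    out = out / (4.0 * math.pi)
    return out if out.ndim else float(out)


def electron_count(wf: SlaterWavefunction) -> float:
    return wf.electron_count()


def mean_square_radius(wf: SlaterWavefunction) -> float:
    return wf.mean_square_radius()


# ---------------------------------------------------------------------------
# Wavefunction table: lookup with ion fallback, text parsing, serialization
# ---------------------------------------------------------------------------

class WavefunctionTable:
    """Mapping of (element, charge) to :class:`SlaterWavefunction`.

    Looking up a missing ion falls back to the neutral species (with a logged
    warning), the convention used when an ionic wavefunction is unavailable.
    """

    def __init__(self, entries: Iterable[SlaterWavefunction] = ()):
        self.entries: dict[tuple[str, int], SlaterWavefunction] = {}
        for wf in entries:
            self.add(wf)

    def add(self, wf: SlaterWavefunction) -> None:
        self.entries[(wf.element, wf.charge)] = wf

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, element: str, charge: int = 0) -> SlaterWavefunction:
        """Fetch a species; charged species fall back to the neutral atom."""
        key = (element, charge)
        if key in self.entries:
            return self.entries[key]
        if charge != 0 and (element, 0) in self.entries:
            logger.warning(
                "no wavefunction for %s with charge %+d; using the neutral atom",
                element, charge,
            )
            return self.entries[(element, 0)]
        raise KeyError(f"no wavefunction for element {element!r} (charge {charge:+d})")


_FLOAT = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def parse_wavefunction_table(text: str) -> WavefunctionTable:
    """Parse the line-oriented wavefunction table format.

    Format::

        # comment
        ELEMENT <symbol> <Z> <charge>
        ORBITAL <label> <l> <occupation>
        PRIM <n> <zeta> <coeff>

    Entries are blank-line separated (a new ELEMENT line also starts a new
    entry).  Errors name the offending line number.
    """
    table = WavefunctionTable()

    cur: dict | None = None          # element under construction
    cur_orb: dict | None = None
    cur_line = 0

    def finish_orbital():
        nonlocal cur_orb
        if cur_orb is not None:
            try:
                cur["orbitals"].append(
                    AtomicOrbital(
                        label=cur_orb["label"],
                        l_ang=cur_orb["l"],
                        occupation=cur_orb["occ"],
                        primitives=tuple(cur_orb["prims"]),
                    )
                )
            except WavefunctionError as exc:
                raise WavefunctionParseError(str(exc), cur_orb["line"]) from exc
            cur_orb = None

    def finish_element():
        nonlocal cur
        if cur is not None:
            finish_orbital()
            try:
                wf = SlaterWavefunction(
                    element=cur["element"],
                    z_nuclear=cur["z"],
                    charge=cur["charge"],
                    orbitals=tuple(cur["orbitals"]),
                    source=cur["source"],
                )
            except WavefunctionError as exc:
                raise WavefunctionParseError(str(exc), cur["line"]) from exc
            table.add(wf)
            cur = None

    pending_source: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            pending_source.append(line.lstrip("# ").rstrip())
            continue
        if not line:
            finish_element()
            continue
        fields = line.split()
        tag = fields[0].upper()
        if tag == "ELEMENT":
            finish_element()
            if len(fields) != 4:
                raise WavefunctionParseError("ELEMENT needs: symbol Z charge", lineno)
            try:
                z, q = int(fields[2]), int(fields[3])
            except ValueError:
                raise WavefunctionParseError(f"bad ELEMENT numbers in {line!r}", lineno)
            cur = {
                "element": fields[1], "z": z, "charge": q,
                "orbitals": [], "line": lineno,
                "source": " ".join(pending_source),
            }
            pending_source = []
        elif tag == "ORBITAL":
            if cur is None:
                raise WavefunctionParseError("ORBITAL before any ELEMENT", lineno)
            finish_orbital()
            if len(fields) != 4:
                raise WavefunctionParseError("ORBITAL needs: label l occupation", lineno)
            try:
                cur_orb = {
                    "label": fields[1], "l": int(fields[2]),
                    "occ": float(fields[3]), "prims": [], "line": lineno,
                }
            except ValueError:
                raise WavefunctionParseError(f"bad ORBITAL numbers in {line!r}", lineno)
        elif tag == "PRIM":
            if cur_orb is None:
                raise WavefunctionParseError("PRIM before any ORBITAL", lineno)
            if len(fields) != 4:
                raise WavefunctionParseError("PRIM needs: n zeta coeff", lineno)
            if not (re.fullmatch(r"\d+", fields[1])
                    and re.fullmatch(_FLOAT, fields[2])
                    and re.fullmatch(_FLOAT, fields[3])):
                raise WavefunctionParseError(f"bad PRIM numbers in {line!r}", lineno)
            try:
                prim = SlaterPrimitive(int(fields[1]), float(fields[2]), float(fields[3]))
            except WavefunctionError as exc:
                raise WavefunctionParseError(str(exc), lineno) from exc
            cur_orb["prims"].append(prim)
        else:
            raise WavefunctionParseError(f"unknown record tag {fields[0]!r}", lineno)
    finish_element()
    return table


def serialize_wavefunction_table(table: WavefunctionTable) -> str:
    """Canonical text form (sorted by Z then charge); parse round-trip stable."""
    blocks = []
    for (element, charge), wf in sorted(
        table.entries.items(), key=lambda kv: (kv[1].z_nuclear, kv[0][1])
    ):
        lines = []
        if wf.source:
            lines.append(f"# {wf.source}")
        lines.append(f"ELEMENT {wf.element} {wf.z_nuclear} {wf.charge}")
        for orb in wf.orbitals:
            lines.append(f"ORBITAL {orb.label} {orb.l_ang} {orb.occupation:.10g}")
            for p in orb.primitives:
                lines.append(f"PRIM {p.n} {p.zeta:.10g} {p.coeff:.10g}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def shell_l(label: str) -> int:
    """Angular momentum from a shell label like '3d'."""
    return _SHELL_L[label[-1]]
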