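"""Crystal models, reflection geometry and kinematic structure factors.

Covers the plumbing around the scattering factors: a minimal CIF-subset
reader/writer (backed by gemmi's CIF parser), SHELX HKLF 4 reflection files,
the reciprocal-metric geometry ``s = sin(theta)/lambda``, Debye-Waller
attenuation from isotropic or anisotropic displacement parameters, the
kinematic structure factor

    F(h) = sum_sites occ * f(s) * DW(h) * exp(2 pi i h.x)

summed over the symmetry-expanded (P1) site list, and the SHELX-type
weighting scheme with its R1/wR2 statistics:

    P  = (max(Fo^2, 0) + 2 Fc^2) / 3
    w  = 1 / (sigma^2(Fo^2) + (a P)^2 + b P)
    wR2 = sqrt( sum w (Fo^2 - Fc^2)^2 / sum w (Fo^2)^2 )
    R1  = sum | |Fo| - |Fc| | / sum |Fo|      over Fo^2 > 2 sigma

Conventions: fractional coordinates, cell angles in degrees, ADPs as U values
in A^2 with the CIF U_ij convention (no B factors), occupancies trusted as
deposited.  Anomalous dispersion is not modelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: fractional-coordinate tolerance for identifying duplicate symmetry images
DEDUP_TOL = 1e-4

#: form-factor provider signature: (element, charge, s in A^-1) -> value
FormFactorProvider = Callable[[str, int, float], float]


class CifParseError(ValueError):
    """Missing or malformed CIF content."""


class HklParseError(ValueError):
    """Malformed HKLF 4 reflection file; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class SpeciesError(KeyError):
    """A form-factor provider does not cover a required species."""


@dataclass(frozen=True)
class UnitCell:
    """Unit cell with lengths in A and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.volume <= 0:
            raise ValueError("cell angles give non-positive volume")

    @cached_property
    def metric(self) -> np.ndarray:
        """Direct metric tensor G (A^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @cached_property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* (A^-2); symmetric positive-definite."""
        return np.linalg.inv(self.metric)

    @cached_property
    def volume(self) -> float:
        det = float(np.linalg.det(self.metric))
        return math.sqrt(det) if det > 0 else -1.0

    @cached_property
    def reciprocal_lengths(self) -> np.ndarray:
        """|a*|, |b*|, |c*| in A^-1."""
        return np.sqrt(np.diag(self.reciprocal_metric))


def stol(cell: UnitCell, hkl: Sequence[int]) -> float:
    """sin(theta)/lambda of a reflection in A^-1 (= d*/2)."""
    h = np.asarray(hkl, dtype=float)
    return 0.5 * math.sqrt(float(h @ cell.reciprocal_metric @ h))


def hkl_sphere(cell: UnitCell, d_min: float) -> list[tuple[int, int, int]]:
    """All reflections (Friedel mates included, 000 excluded) with d >= d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    smax = 1.0 / (2.0 * d_min)
    # box bound: |h_i| <= d*_max / |a*_i|
    limits = [int(math.floor(2.0 * smax / li)) for li in cell.reciprocal_lengths]
    out = []
    for h in range(-limits[0], limits[0] + 1):
        for k in range(-limits[1], limits[1] + 1):
            for l in range(-limits[2], limits[2] + 1):
                if h == k == l == 0:
                    continue
                if stol(cell, (h, k, l)) <= smax + 1e-12:
                    out.append((h, k, l))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Sites, symmetry, Debye-Waller
# ---------------------------------------------------------------------------

@dataclass
class AtomSite:
    """One crystallographic site with fractional coordinates and ADPs."""

    label: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    charge: int = 0                       # ionic-species hint for providers
    u_iso: float | None = None            # A^2
    u_aniso: np.ndarray | None = None     # 3x3 symmetric, A^2, CIF U_ij

    def __post_init__(self) -> None:
        self.xyz = tuple(float(x) for x in self.xyz)
        if not 0 < self.occupancy <= 1:
            raise ValueError(f"site {self.label}: occupancy {self.occupancy} outside (0, 1]")
        if self.u_iso is not None and self.u_iso < 0:
            raise ValueError(f"site {self.label}: negative U_iso")
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
            if self.u_aniso.shape != (3, 3):
                raise ValueError(f"site {self.label}: U matrix must be 3x3")
            if not np.allclose(self.u_aniso, self.u_aniso.T, atol=1e-10):
                raise ValueError(f"site {self.label}: U matrix must be symmetric")
            if np.linalg.eigvalsh(self.u_aniso).min() < -1e-8:
                logger.warning("site %s: deposited U matrix is not positive-semidefinite",
                               self.label)


Identity = (np.eye(3, dtype=int), np.zeros(3))


@dataclass
class CrystalModel:
    """Unit cell, explicit symmetry operations and the asymmetric-unit sites."""

    cell: UnitCell
    symops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=lambda: [Identity])
    sites: list[AtomSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.symops = [
            (np.asarray(r, dtype=int), np.asarray(t, dtype=float) % 1.0)
            for r, t in self.symops
        ]
        if not any(
            np.array_equal(r, np.eye(3, dtype=int)) and np.allclose(t % 1.0, 0)
            for r, t in self.symops
        ):
            raise ValueError("symmetry operation list must contain the identity")
        self._check_closure()

    def _check_closure(self) -> None:
        keys = {self._op_key(r, t) for r, t in self.symops}
        for r1, t1 in self.symops:
            for r2, t2 in self.symops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if self._op_key(r, t) not in keys:
                    logger.warning("symmetry operations are not closed under composition")
                    return

    @staticmethod
    def _op_key(r: np.ndarray, t: np.ndarray) -> tuple:
        return (tuple(np.asarray(r, dtype=int).ravel()),
                tuple(np.round((np.asarray(t) % 1.0) * 1e6).astype(int) % 1000000))


def expand_to_p1(model: CrystalModel) -> list[tuple[AtomSite, np.ndarray]]:
    """Symmetry-expand every site to P1, de-duplicating special positions.

    Two images closer than ``DEDUP_TOL`` (fractional, minimal image) are one
    site.  Deposited occupancies are kept verbatim.
    """
    expanded: list[tuple[AtomSite, np.ndarray]] = []
    for site in model.sites:
        x0 = np.asarray(site.xyz, dtype=float)
        images: list[np.ndarray] = []
        for r, t in model.symops:
            x = (r @ x0 + t) % 1.0
            dup = False
            for seen in images:
                d = np.abs(x - seen)
                d = np.minimum(d, 1.0 - d)
                if np.all(d < DEDUP_TOL):
                    dup = True
                    break
            if not dup:
                images.append(x)
        expanded.extend((site, x) for x in images)
    return expanded


def debye_waller(site: AtomSite, cell: UnitCell, hkl: Sequence[int]) -> float:
    """Debye-Waller attenuation in (0, 1] for one site and reflection.

    Isotropic: ``exp(-8 pi^2 U_iso s^2)``.  Anisotropic (CIF U_ij):
    ``exp(-2 pi^2 sum_ij h_i h_j a*_i a*_j U_ij)``.
    """
    h = np.asarray(hkl, dtype=float)
    if site.u_aniso is not None:
        rl = cell.reciprocal_lengths
        q = float((h * rl) @ site.u_aniso @ (h * rl))
        return math.exp(-2.0 * math.pi ** 2 * q)
    u = site.u_iso or 0.0
    s = stol(cell, hkl)
    return math.exp(-8.0 * math.pi ** 2 * u * s * s)


def structure_factor(
    model: CrystalModel,
    hkl: Sequence[int],
    ff_provider: FormFactorProvider,
    expanded: list[tuple[AtomSite, np.ndarray]] | None = None,
) -> complex:
    """Kinematic structure factor F(hkl) from the symmetry-expanded model.

    ``expanded`` may carry a precomputed :func:`expand_to_p1` result when many
    reflections are evaluated against the same model.
    """
    if expanded is None:
        expanded = expand_to_p1(model)
    h = np.asarray(hkl, dtype=float)
    s = stol(model.cell, hkl)
    f_cache: dict[tuple[str, int], float] = {}
    total = 0.0 + 0.0j
    for site, x in expanded:
        key = (site.element, site.charge)
        if key not in f_cache:
            try:
                f_cache[key] = ff_provider(site.element, site.charge, s)
            except KeyError as exc:
                raise SpeciesError(
                    f"form-factor provider does not cover species "
                    f"{site.element!r} (charge {site.charge:+d})"
                ) from exc
        dw = debye_waller(site, model.cell, hkl)
        total += site.occupancy * f_cache[key] * dw * np.exp(2j * math.pi * float(h @ x))
    return complex(total)


# ---------------------------------------------------------------------------
# Reflection records and the SHELX-type weighting statistics
# ---------------------------------------------------------------------------

@dataclass
class ReflectionRecord:
    """One reflection: indices, geometry and observed/calculated quantities."""

    hkl: tuple[int, int, int]
    Fo2: float
    sigFo2: float
    s: float = 0.0
    Fc: complex | None = None


def weights_and_rstats(
    records: Sequence[ReflectionRecord], a: float, b: float = 0.0
) -> tuple[float, float, np.ndarray]:
    """SHELX-type weights and (R1, wR2) for a refined reflection set.

    Every record needs Fc and sigma(Fo^2) > 0.  Negative Fo^2 are preserved
    and clamped to zero only inside P, as the weighting scheme prescribes.
    """
    if not records:
        raise ValueError("empty reflection set")
    fo2 = np.array([r.Fo2 for r in records], dtype=float)
    sig = np.array([r.sigFo2 for r in records], dtype=float)
    if np.any(sig <= 0):
        raise ValueError("all sigma(Fo^2) must be positive")
    if any(r.Fc is None for r in records):
        raise ValueError("all records need a calculated Fc")
    fc2 = np.array([abs(r.Fc) ** 2 for r in records], dtype=float)

    p = (np.maximum(fo2, 0.0) + 2.0 * fc2) / 3.0
    w = 1.0 / (sig ** 2 + (a * p) ** 2 + b * p)
    wr2 = math.sqrt(float(np.sum(w * (fo2 - fc2) ** 2) / np.sum(w * fo2 ** 2)))

    strong = fo2 > 2.0 * sig
    if np.any(strong):
        fo = np.sqrt(np.maximum(fo2[strong], 0.0))
        fc = np.sqrt(fc2[strong])
        r1 = float(np.sum(np.abs(fo - fc)) / np.sum(fo))
    else:
        r1 = float("nan")
    return r1, wr2, w


# ---------------------------------------------------------------------------
# CIF subset I/O (cell + symop strings + sites + optional aniso loop)
# ---------------------------------------------------------------------------

def _parse_symop(xyz: str) -> tuple[np.ndarray, np.ndarray]:
    import gemmi

    op = gemmi.Op(xyz.strip().lower())
    rot = np.asarray(op.rot, dtype=float) / op.DEN
    tran = np.asarray(op.tran, dtype=float) / op.DEN
    if not np.allclose(rot, np.round(rot)):
        raise CifParseError(f"non-integer rotation in symop {xyz!r}")
    return np.round(rot).astype(int), tran


def _cif_num(text: str) -> float:
    """CIF number, stripping a parenthesized standard uncertainty."""
    return float(text.split("(")[0])


def read_cif_minimal(text: str) -> CrystalModel:
    """Read cell, symmetry operations and atom sites from CIF text.

    Uses ``_atom_site_U_iso_or_equiv`` unless the site appears in the aniso
    loop, in which case the full U matrix is attached.
    """
    import gemmi

    doc = gemmi.cif.read_string(text)
    block = doc.sole_block()

    cell_vals = []
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        v = block.find_value(tag)
        if v is None:
            raise CifParseError(f"missing {tag}")
        cell_vals.append(_cif_num(v))
    cell = UnitCell(*cell_vals)

    symops = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        strings = [gemmi.cif.as_string(v) for v in col]
        if strings:
            symops = [_parse_symop(s) for s in strings]
            break
    if not symops:
        symops = [Identity]

    labels = block.find_loop("_atom_site_label")
    if not list(labels):
        raise CifParseError("missing _atom_site loop")

    def col(tag):
        return [gemmi.cif.as_string(v) for v in block.find_loop(tag)]

    lab = col("_atom_site_label")
    typ = col("_atom_site_type_symbol") or lab
    fx = col("_atom_site_fract_x")
    fy = col("_atom_site_fract_y")
    fz = col("_atom_site_fract_z")
    occ = col("_atom_site_occupancy") or ["1"] * len(lab)
    uiso = col("_atom_site_U_iso_or_equiv") or ["0"] * len(lab)
    if not (len(lab) == len(fx) == len(fy) == len(fz)):
        raise CifParseError("ragged _atom_site loop")

    aniso: dict[str, np.ndarray] = {}
    alab = col("_atom_site_aniso_label")
    if alab:
        comps = {
            t: col(f"_atom_site_aniso_U_{t}") for t in ("11", "22", "33", "12", "13", "23")
        }
        for i, al in enumerate(alab):
            u = np.zeros((3, 3))
            u[0, 0] = _cif_num(comps["11"][i])
            u[1, 1] = _cif_num(comps["22"][i])
            u[2, 2] = _cif_num(comps["33"][i])
            u[0, 1] = u[1, 0] = _cif_num(comps["12"][i])
            u[0, 2] = u[2, 0] = _cif_num(comps["13"][i])
            u[1, 2] = u[2, 1] = _cif_num(comps["23"][i])
            aniso[al] = u

    sites = []
    for i in range(len(lab)):
        element = "".join(ch for ch in typ[i] if ch.isalpha())
        element = element[:1].upper() + element[1:].lower()
        sites.append(
            AtomSite(
                label=lab[i],
                element=element,
                xyz=(_cif_num(fx[i]), _cif_num(fy[i]), _cif_num(fz[i])),
                occupancy=_cif_num(occ[i]),
                u_iso=None if lab[i] in aniso else _cif_num(uiso[i]),
                u_aniso=aniso.get(lab[i]),
            )
        )
    return CrystalModel(cell=cell, symops=symops, sites=sites)


def write_cif_minimal(model: CrystalModel, name: str = "model") -> str:
    """Serialize the CIF subset read by :func:`read_cif_minimal`."""
    import gemmi

    c = model.cell
    lines = [
        f"data_{name}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    for r, t in model.symops:
        op = gemmi.Op()
        op.rot = [[int(v) * op.DEN for v in row] for row in r]
        op.tran = [int(round(v * op.DEN)) for v in t]
        lines.append(f"'{op.triplet()}'")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_U_iso_or_equiv",
    ]
    for site in model.sites:
        u_eq = site.u_iso if site.u_iso is not None else float(np.trace(site.u_aniso) / 3.0)
        x, y, z = site.xyz
        lines.append(
            f"{site.label} {site.element} {x:.6f} {y:.6f} {z:.6f} "
            f"{site.occupancy:.6f} {u_eq:.6f}"
        )
    aniso_sites = [s for s in model.sites if s.u_aniso is not None]
    if aniso_sites:
        lines += [
            "loop_",
            "_atom_site_aniso_label",
            "_atom_site_aniso_U_11",
            "_atom_site_aniso_U_22",
            "_atom_site_aniso_U_33",
            "_atom_site_aniso_U_12",
            "_atom_site_aniso_U_13",
            "_atom_site_aniso_U_23",
        ]
        for s in aniso_sites:
            u = s.u_aniso
            lines.append(
                f"{s.label} {u[0,0]:.6f} {u[1,1]:.6f} {u[2,2]:.6f} "
                f"{u[0,1]:.6f} {u[0,2]:.6f} {u[1,2]:.6f}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SHELX HKLF 4 reflection files (3I4, 2F8.2)
# ---------------------------------------------------------------------------

def read_shelx_hkl(text: str) -> list[tuple[tuple[int, int, int], float, float]]:
    """Parse HKLF 4 fixed-format lines; the 0 0 0 terminator ends the data.

    Negative Fo^2 are preserved; clamping happens only inside the weighting
    scheme's P term.
    """
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        if len(raw) < 28:
            raise HklParseError(f"record shorter than 28 columns: {raw!r}", lineno)
        try:
            h = int(raw[0:4])
            k = int(raw[4:8])
            l = int(raw[8:12])
            fo2 = float(raw[12:20])
            sig = float(raw[20:28])
        except ValueError as exc:
            raise HklParseError(f"column misalignment in {raw!r}", lineno) from exc
        if h == k == l == 0:
            break
        out.append(((h, k, l), fo2, sig))
    return out


def write_shelx_hkl(records: Iterable[tuple[tuple[int, int, int], float, float]]) -> str:
    lines = [
        f"{h:4d}{k:4d}{l:4d}{fo2:8.2f}{sig:8.2f}"
        for (h, k, l), fo2, sig in records
    ]
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Provider helpers
# ---------------------------------------------------------------------------

def slater_xray_provider(table) -> FormFactorProvider:
    """X-ray provider over a :class:`~slaterff.wavefunctions.WavefunctionTable`."""
    from .xray import xray_form_factor

    def provider(element: str, charge: int, s: float) -> float:
        return float(xray_form_factor(table.lookup(element, charge), s))

    return provider


def slater_ed_provider(table) -> FormFactorProvider:
    """Electron-diffraction provider (Mott-Bethe transformed)."""
    from .electron import ed_form_factor

    def provider(element: str, charge: int, s: float) -> float:
        return float(ed_form_factor(table.lookup(element, charge), s))

    return provider


def gaussian_provider(models: dict[str, "GaussianFFModel"]) -> FormFactorProvider:
    """Provider over Gaussian models keyed by element symbol (charge ignored
    unless an explicit '<El>+'/'<El>-' entry exists)."""
    from .xray import gaussian_form_factor

    def provider(element: str, charge: int, s: float) -> float:
        key = element if charge == 0 else f"{element}{'+' if charge > 0 else '-'}"
        model = models.get(key) or models[element]
        return float(gaussian_form_factor(model, s))

    return provider
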