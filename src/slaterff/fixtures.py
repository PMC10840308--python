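"""Synthetic fixtures: wavefunctions, Gaussian models, toy crystals, noisy data.

Everything every other module needs for testing is generated here with no
downloads.  Three families:

* **Wavefunctions.**  Hydrogen is exact (single 1s Slater).  The default
  bonded-hydrogen exponent is zeta = 1.15 bohr^-1, matching the contracted
  density of an H atom bound to a heavier partner (the convention of standard
  refinement engines); the free-atom zeta = 1.0 variant is available through
  :func:`make_hydrogen`.  Heavier elements use minimal-basis single-zeta
  wavefunctions built from Slater's screening rules
  (:func:`slater_rules_wavefunction`) — synthetic stand-ins for the published
  large-basis Hartree-Fock tables, adequate for every structural identity
  tested here though not of literature quality near the nucleus.  Fully
  random multi-primitive species come from :func:`make_synthetic_species`.

* **Gaussian models.**  The conventional 4G+c X-ray coefficients for H, C, N,
  O and Ca (bundled CSV, transcribed from the standard reference tables) and
  a synthetic Peng-style 4G electron model fitted by least squares to this
  package's own Mott-Bethe curves (:func:`make_peng_like_4g`).

* **Toy crystals.**  :func:`make_toy_crystal` emits CIF + HKLF 4 text for a
  P1 or P2_1/c cell with 1-5 sites and simulated noisy intensities
  ``Fo^2 = |Fc|^2 (1 + eps)``, ``eps ~ N(0, noise_fraction)``; byte-identical
  under a fixed seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .crystal import (
    AtomSite,
    CrystalModel,
    Identity,
    UnitCell,
    hkl_sphere,
    slater_xray_provider,
    structure_factor,
    write_cif_minimal,
    write_shelx_hkl,
)
from .wavefunctions import (
    ATOMIC_NUMBER,
    ELEMENTS,
    AtomicOrbital,
    SlaterPrimitive,
    SlaterWavefunction,
    WavefunctionTable,
    parse_wavefunction_table,
    shell_l,
)
from .xray import GaussianFFModel

# ---------------------------------------------------------------------------
# Hydrogen and Slater's-rules minimal-basis wavefunctions
# ---------------------------------------------------------------------------

#: default bonded-hydrogen exponent (bohr^-1)
HYDROGEN_ZETA_BONDED = 1.15


def make_hydrogen(zeta: float = HYDROGEN_ZETA_BONDED) -> SlaterWavefunction:
    """Single-1s hydrogen; zeta = 1.15 (bonded default) or 1.0 (free atom)."""
    return SlaterWavefunction(
        element="H",
        z_nuclear=1,
        charge=0,
        orbitals=(
            AtomicOrbital("1s", 0, 1.0, (SlaterPrimitive(1, zeta, 1.0),)),
        ),
        source=f"exact single-zeta hydrogen, zeta={zeta:g}",
    )


_AUFBAU = (
    "1s", "2s", "2p", "3s", "3p", "4s", "3d", "4p", "5s", "4d", "5p",
    "6s", "4f", "5d", "6p", "7s", "5f", "6d", "7p",
)

_N_STAR = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7, 5: 4.0, 6: 4.2, 7: 4.2}


def _configuration(n_electrons: int) -> dict[str, float]:
    """Aufbau electron configuration (no d-block exceptions; synthetic)."""
    config: dict[str, float] = {}
    remaining = n_electrons
    for shell in _AUFBAU:
        if remaining <= 0:
            break
        cap = 2 * (2 * shell_l(shell) + 1)
        take = min(cap, remaining)
        config[shell] = float(take)
        remaining -= take
    return config


def _slater_group(shell: str) -> tuple[int, str]:
    """Slater screening group of a shell: s and p of the same n share one."""
    n = int(shell[:-1])
    kind = shell[-1]
    return (n, "sp" if kind in "sp" else kind)


def _slater_zeta(shell: str, config: dict[str, float], z: int) -> float:
    """Effective single-zeta exponent (Z - sigma)/n* by Slater's rules."""
    n = int(shell[:-1])
    kind = shell[-1]
    group = _slater_group(shell)
    sigma = 0.0
    for other, occ in config.items():
        if _slater_group(other) == group:
            sigma += (occ - 1.0) * (0.30 if shell == "1s" else 0.35)
            continue
        on = int(other[:-1])
        if kind in "sp":
            if on == n - 1:
                sigma += occ * 0.85
            elif on < n - 1:
                sigma += occ * 1.00
            # higher shells do not screen s/p electrons
        else:  # d or f electron: every earlier group screens fully
            if _AUFBAU.index(other) < _AUFBAU.index(shell):
                sigma += occ * 1.00
    zeta = (z - sigma) / _N_STAR[n]
    return max(zeta, 0.1)  # anion valence shells of light atoms can dip low


def slater_rules_wavefunction(element: str, charge: int = 0) -> SlaterWavefunction:
    """Minimal-basis single-zeta wavefunction from Slater's screening rules.

    A synthetic stand-in for tabulated Hartree-Fock Slater wavefunctions:
    each occupied shell becomes one primitive with n = principal quantum
    number and zeta = (Z - sigma)/n*.  Ions move electrons in or out of the
    outermost aufbau shell.
    """
    z = ATOMIC_NUMBER[element]
    n_elec = z - charge
    if n_elec < 1:
        raise ValueError(f"{element}{charge:+d} has no electrons")
    config = _configuration(n_elec)
    orbitals = []
    for shell, occ in config.items():
        zeta = _slater_zeta(shell, config, z)
        orbitals.append(
            AtomicOrbital(
                label=shell,
                l_ang=shell_l(shell),
                occupation=occ,
                primitives=(SlaterPrimitive(int(shell[:-1]), zeta, 1.0),),
            )
        )
    return SlaterWavefunction(
        element=element,
        z_nuclear=z,
        charge=charge,
        orbitals=tuple(orbitals),
        source="synthetic minimal-basis wavefunction (Slater screening rules)",
    )


_ORBITAL_SEQUENCE = ("1s", "2s", "2p", "3s", "3p", "3d", "4s", "4p", "4d", "4f")


def make_synthetic_species(
    n_orbitals: int, primitives_per_orbital: int, seed: int
) -> SlaterWavefunction:
    """Random multi-primitive wavefunction with unit-norm contracted orbitals.

    Exponents are drawn in [0.3, 40] bohr^-1 and contraction coefficients are
    rescaled with the closed-form Gram matrix so each orbital is exactly
    unit-normalized; occupations fill shells to capacity so that f(0) equals
    an integer electron count.  Deterministic under the seed.
    """
    if n_orbitals < 1 or primitives_per_orbital < 1:
        raise ValueError("orbital and primitive counts must be >= 1")
    if n_orbitals > len(_ORBITAL_SEQUENCE):
        raise ValueError(f"at most {len(_ORBITAL_SEQUENCE)} orbitals supported")
    rng = np.random.default_rng(seed)
    orbitals = []
    total = 0
    for i in range(n_orbitals):
        label = _ORBITAL_SEQUENCE[i]
        l_ang = shell_l(label)
        n_min = int(label[:-1])
        prims = []
        for _ in range(primitives_per_orbital):
            n = int(rng.integers(n_min, n_min + 3))
            zeta = float(rng.uniform(0.3, 40.0))
            coeff = float(rng.uniform(0.2, 1.0)) * (1 if rng.random() < 0.8 else -1)
            prims.append(SlaterPrimitive(n, zeta, coeff))
        raw = AtomicOrbital(label, l_ang, 0.0, tuple(prims))
        scale = 1.0 / math.sqrt(raw.norm_integral())
        prims = tuple(
            SlaterPrimitive(p.n, p.zeta, p.coeff * scale) for p in prims
        )
        occ = 2 * (2 * l_ang + 1)
        total += occ
        orbitals.append(AtomicOrbital(label, l_ang, float(occ), prims))
    return SlaterWavefunction(
        element=ELEMENTS[total - 1],
        z_nuclear=total,
        charge=0,
        orbitals=tuple(orbitals),
        source=f"synthetic random species (seed {seed})",
    )


def bundled_wavefunctions() -> WavefunctionTable:
    """The bundled light-atom table (synthetic minimal basis + exact H)."""
    text = resources.files("slaterff.data").joinpath("synthetic_light_atoms.wft").read_text()
    return parse_wavefunction_table(text)


def default_wavefunction_table(extra_elements: tuple[str, ...] = ()) -> WavefunctionTable:
    """Bundled table, extended on demand with Slater's-rules species."""
    table = bundled_wavefunctions()
    for element in extra_elements:
        if (element, 0) not in table:
            table.add(slater_rules_wavefunction(element))
    return table


# ---------------------------------------------------------------------------
# Gaussian coefficient fixtures
# ---------------------------------------------------------------------------

def load_gaussian_csv(text: str) -> dict[str, GaussianFFModel]:
    """Parse the CSV fixture format: species, a1..a5, b1..b5, c."""
    models = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("species"):
            continue
        fields = line.split(",")
        species = fields[0].strip()
        nums = [float(x) for x in fields[1:12]]
        a = tuple(x for x in nums[0:5])
        b = tuple(x for x in nums[5:10])
        c = nums[10]
        keep = [i for i in range(5) if not (a[i] == 0 and b[i] == 0)]
        models[species] = GaussianFFModel(
            species, tuple(a[i] for i in keep), tuple(b[i] for i in keep), c
        )
    return models


def gaussian_models_to_csv(models: dict[str, GaussianFFModel], comment: str = "") -> str:
    lines = []
    if comment:
        lines += [f"# {ln}" for ln in comment.splitlines()]
    lines.append("species,a1,a2,a3,a4,a5,b1,b2,b3,b4,b5,c")
    for species, m in sorted(models.items()):
        a = list(m.a) + [0.0] * (5 - len(m.a))
        b = list(m.b) + [0.0] * (5 - len(m.b))
        nums = ",".join(f"{x:.8g}" for x in a + b + [m.c])
        lines.append(f"{species},{nums}")
    return "\n".join(lines) + "\n"


def bundled_gaussian_4gc() -> dict[str, GaussianFFModel]:
    """4G+c X-ray coefficients for H, C, N, O, Ca (bundled transcription)."""
    text = resources.files("slaterff.data").joinpath("gaussian_4gc.csv").read_text()
    return load_gaussian_csv(text)


def make_peng_like_4g(
    wf: SlaterWavefunction, s_max: float = 2.0, n_points: int = 120
) -> GaussianFFModel:
    """Synthetic Peng-style 4G electron model fitted to this package's curves.

    Least-squares fit of ``sum_i a_i exp(-b_i s^2)`` (c = 0) to the
    Mott-Bethe-transformed form factor of ``wf`` on s in (0, s_max].
    Deterministic (fixed grid and starting point); a stand-in for published
    electron-scattering Gaussian tables.
    """
    from scipy.optimize import curve_fit

    from .electron import ed_form_factor

    s = np.linspace(s_max / n_points, s_max, n_points)
    f = ed_form_factor(wf, s)

    def model4g(s, a1, a2, a3, a4, b1, b2, b3, b4):
        s2 = s * s
        return (a1 * np.exp(-b1 * s2) + a2 * np.exp(-b2 * s2)
                + a3 * np.exp(-b3 * s2) + a4 * np.exp(-b4 * s2))

    f0 = float(f[0])
    p0 = [f0 / 4] * 4 + [0.5, 2.0, 8.0, 30.0]
    bounds = ([-np.inf] * 4 + [0.0] * 4, [np.inf] * 8)
    popt, _ = curve_fit(model4g, s, f, p0=p0, bounds=bounds, maxfev=20000)
    return GaussianFFModel(
        species=wf.species, a=tuple(popt[:4]), b=tuple(popt[4:]), c=0.0
    )


# ---------------------------------------------------------------------------
# Toy crystals with simulated noisy intensities
# ---------------------------------------------------------------------------

#: P2_1/c symmetry operations (unique axis b)
P21C_SYMOPS = (
    (np.eye(3, dtype=int), np.zeros(3)),
    (np.diag((-1, 1, -1)), np.array([0.0, 0.5, 0.5])),
    (-np.eye(3, dtype=int), np.zeros(3)),
    (np.diag((1, -1, 1)), np.array([0.0, 0.5, 0.5])),
)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic toy-crystal data set."""

    seed: int = 0
    noise_fraction: float = 0.02
    species: tuple[str, ...] = ("C", "O")
    cell: tuple[float, float, float, float, float, float] = (8.0, 9.0, 10.0, 90.0, 90.0, 90.0)
    space_group: str = "P1"            # "P1" | "P21c"
    d_min: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.species) <= 5:
            raise ValueError("1-5 sites supported")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.space_group not in ("P1", "P21c"):
            raise ValueError("space_group must be 'P1' or 'P21c'")


#: absolute sigma(Fo^2) floor: keeps zero-noise fixtures compatible with the
#: sigma > 0 precondition of the weighting scheme and survives the two-decimal
#: HKLF 4 fixed format
SIGMA_FLOOR = 0.01


def make_toy_model(spec: FixtureSpec) -> CrystalModel:
    """The deterministic toy crystal model behind :func:`make_toy_crystal`."""
    rng = np.random.default_rng(spec.seed)
    cell = UnitCell(*spec.cell)
    symops = list(P21C_SYMOPS) if spec.space_group == "P21c" else [Identity]
    sites = []
    for i, element in enumerate(spec.species):
        xyz = tuple(float(x) for x in rng.uniform(0.05, 0.45, size=3))
        u_iso = float(rng.uniform(0.01, 0.04))
        sites.append(
            AtomSite(label=f"{element}{i + 1}", element=element, xyz=xyz, u_iso=u_iso)
        )
    return CrystalModel(cell=cell, symops=symops, sites=sites)


def make_toy_crystal(
    spec: FixtureSpec, table: WavefunctionTable | None = None
) -> tuple[str, str]:
    """Toy crystal as (CIF text, HKLF 4 text) with simulated intensities.

    ``Fo^2 = |Fc|^2 (1 + eps)`` with ``eps ~ Normal(0, noise_fraction)`` and
    ``sigma(Fo^2) = noise_fraction |Fc|^2`` (floored, see ``SIGMA_FLOOR``),
    computed from the generating Slater X-ray provider.  Byte-identical for a
    fixed seed.
    """
    model = make_toy_model(spec)
    if table is None:
        table = default_wavefunction_table(tuple(spec.species))
    provider = slater_xray_provider(table)
    rng = np.random.default_rng(spec.seed + 1)

    from .crystal import expand_to_p1

    expanded = expand_to_p1(model)
    records = []
    for hkl in hkl_sphere(model.cell, spec.d_min):
        fc = structure_factor(model, hkl, provider, expanded)
        fc2 = abs(fc) ** 2
        eps = float(rng.normal(0.0, spec.noise_fraction)) if spec.noise_fraction else 0.0
        fo2 = fc2 * (1.0 + eps)
        sig = max(spec.noise_fraction * fc2, SIGMA_FLOOR)
        records.append((hkl, fo2, sig))
    max_fo2 = max(abs(r[1]) for r in records)
    if max_fo2 >= 1e5:
        raise ValueError("toy intensities overflow the HKLF 4 fixed format")
    return write_cif_minimal(model, name="toy"), write_shelx_hkl(records)


def write_fixture_bundle(outdir, seed: int = 0) -> list[str]:
    """Emit the full fixture bundle into a directory; returns file names."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    wft = resources.files("slaterff.data").joinpath("synthetic_light_atoms.wft").read_text()
    (out / "wavefunctions.wft").write_text(wft)
    written.append("wavefunctions.wft")

    g4 = resources.files("slaterff.data").joinpath("gaussian_4gc.csv").read_text()
    (out / "gaussian_4gc.csv").write_text(g4)
    written.append("gaussian_4gc.csv")

    spec = FixtureSpec(seed=seed)
    cif, hkl = make_toy_crystal(spec)
    (out / "toy.cif").write_text(cif)
    (out / "toy.hkl").write_text(hkl)
    written += ["toy.cif", "toy.hkl"]

    from .electron import ed_form_factor

    table = default_wavefunction_table()
    peng_like = {}
    curves = ["species,s,f"]
    for element in ("H", "C", "O"):
        wf = table.lookup(element)
        model = make_peng_like_4g(wf)
        peng_like[model.species] = model
        for s in np.linspace(0.05, 2.0, 40):
            curves.append(f"{element},{s:.6f},{float(ed_form_factor(wf, s)):.8g}")
    (out / "peng_like_4g.csv").write_text(
        gaussian_models_to_csv(
            peng_like,
            comment="synthetic Peng-style 4G electron models fitted to "
                    "slaterff Mott-Bethe curves",
        )
    )
    (out / "ed_reference_curves.csv").write_text("\n".join(curves) + "\n")
    written += ["peng_like_4g.csv", "ed_reference_curves.csv"]
    return written
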