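"""The .tsc scattering-factor interchange format: build, write, read, merge.

A .tsc file tabulates, for every reflection of a structure, one (complex)
scattering factor per atom label.  It decouples the origin of the scattering
factors from the refinement engine that consumes them.  Dialect::

    TITLE: <free text>
    SYMM: expanded
    SCATTERERS: <label> <label> ...
    DATA:
    h k l re,im re,im ...

Unknown header keys are skipped on read (the official field set is larger
than what is written here).  Spherical factors have exactly zero imaginary
parts; the complex slot exists so merged tables can carry non-spherical
columns from other sources.

Scattering factors are evaluated exactly at each reflection's own
sin(theta)/lambda from the cell — tailor-made per scattering vector, never
interpolated from a precomputed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .crystal import CrystalModel, hkl_sphere, stol
from .wavefunctions import WavefunctionTable

logger = logging.getLogger(__name__)


class TscParseError(ValueError):
    """Malformed .tsc content."""


@dataclass
class TscTable:
    """Per-reflection, per-atom-label complex scattering factors."""

    title: str = ""
    symm: str = "expanded"
    scatterer_labels: list[str] = field(default_factory=list)
    rows: dict[tuple[int, int, int], tuple[complex, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hkl, values in self.rows.items():
            if len(values) != len(self.scatterer_labels):
                raise TscParseError(
                    f"row {hkl}: {len(values)} values for "
                    f"{len(self.scatterer_labels)} scatterers"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TscTable)
            and self.title == other.title
            and self.symm == other.symm
            and self.scatterer_labels == other.scatterer_labels
            and self.rows == other.rows
        )


def build_tsc(
    model: CrystalModel,
    table: WavefunctionTable,
    d_min: float,
    radiation: str = "xray",
    ion_overrides: dict[str, int] | None = None,
    title: str = "slaterff scattering factors",
) -> TscTable:
    """Tabulate analytic scattering factors for every reflection to d_min.

    ``ion_overrides`` maps atom labels to net charges (+1/-1); a label whose
    ionic wavefunction is missing falls back to the neutral atom with a logged
    warning.  Electron-diffraction mode never requests s = 0 (000 is excluded
    from the sphere), so the ion divergence at s = 0 cannot trigger here.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if radiation not in ("xray", "electron"):
        raise ValueError(f"radiation must be 'xray' or 'electron', got {radiation!r}")
    ion_overrides = ion_overrides or {}

    if radiation == "xray":
        from .xray import xray_form_factor as evaluate
    else:
        from .electron import ed_form_factor as evaluate

    labels = [site.label for site in model.sites]
    species = {}
    for site in model.sites:
        charge = ion_overrides.get(site.label, site.charge)
        species[site.label] = table.lookup(site.element, charge)

    rows: dict[tuple[int, int, int], tuple[complex, ...]] = {}
    # one evaluation per distinct species per reflection; symmetry-equivalent
    # reflections at identical s reuse nothing but agree to machine precision
    for hkl in hkl_sphere(model.cell, d_min):
        s = stol(model.cell, hkl)
        cache: dict[int, complex] = {}
        values = []
        for label in labels:
            wf = species[label]
            key = id(wf)
            if key not in cache:
                # quantize to the written 8-significant-digit precision so the
                # table round-trips through write_tsc/read_tsc exactly
                cache[key] = complex(float(f"{float(evaluate(wf, s)):.8g}"), 0.0)
            values.append(cache[key])
        rows[hkl] = tuple(values)
    return TscTable(title=title, symm="expanded", scatterer_labels=labels, rows=rows)


def write_tsc(table: TscTable) -> str:
    """Serialize with 8 significant digits; read(write(t)) == t."""
    lines = [
        f"TITLE: {table.title}",
        f"SYMM: {table.symm}",
        "SCATTERERS: " + " ".join(table.scatterer_labels),
        "DATA:",
    ]
    for (h, k, l), values in sorted(table.rows.items()):
        pairs = " ".join(f"{v.real:.8g},{v.imag:.8g}" for v in values)
        lines.append(f"{h} {k} {l} {pairs}".rstrip())
    return "\n".join(lines) + "\n"


def read_tsc(text: str) -> TscTable:
    """Parse the dialect above, skipping unknown header keys."""
    title = ""
    symm = "expanded"
    labels: list[str] | None = None
    rows: dict[tuple[int, int, int], tuple[complex, ...]] = {}
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if not in_data:
            if ":" not in line:
                raise TscParseError(f"line {lineno}: expected 'KEY:' header, got {line!r}")
            key, _, rest = line.partition(":")
            key = key.strip().upper()
            rest = rest.strip()
            if key == "TITLE":
                title = rest
            elif key == "SYMM":
                symm = rest
            elif key == "SCATTERERS":
                labels = rest.split()
            elif key == "DATA":
                in_data = True
            else:
                logger.debug("skipping unknown .tsc header key %r", key)
            continue
        fields = line.split()
        if labels is None:
            raise TscParseError(f"line {lineno}: DATA before SCATTERERS header")
        if len(fields) != 3 + len(labels):
            raise TscParseError(
                f"line {lineno}: expected {3 + len(labels)} fields, got {len(fields)}"
            )
        try:
            hkl = (int(fields[0]), int(fields[1]), int(fields[2]))
            values = tuple(
                complex(float(re), float(im))
                for re, im in (pair.split(",") for pair in fields[3:])
            )
        except ValueError as exc:
            raise TscParseError(f"line {lineno}: bad data row {line!r}") from exc
        if hkl in rows:
            raise TscParseError(f"line {lineno}: duplicate reflection {hkl}")
        rows[hkl] = values
    if labels is None:
        raise TscParseError("missing SCATTERERS header")
    return TscTable(title=title, symm=symm, scatterer_labels=labels, rows=rows)


def merge_tsc(tables: list[TscTable]) -> TscTable:
    """Column-wise union of tables over an identical reflection set.

    Later tables win on duplicate labels (warning logged).  Tables whose hkl
    sets differ raise, reporting the symmetric difference.
    """
    if not tables:
        raise ValueError("nothing to merge")
    base = tables[0]
    hkls = set(base.rows)
    for t in tables[1:]:
        if set(t.rows) != hkls:
            diff = sorted(set(t.rows) ^ hkls)
            raise ValueError(f"hkl sets differ; symmetric difference: {diff[:20]}"
                             + (" ..." if len(diff) > 20 else ""))

    labels: list[str] = []
    col_of: dict[str, tuple[int, int]] = {}  # label -> (table index, column)
    for ti, t in enumerate(tables):
        for ci, label in enumerate(t.scatterer_labels):
            if label in col_of:
                logger.warning("merge: duplicate scatterer %r, later table wins", label)
            else:
                labels.append(label)
            col_of[label] = (ti, ci)

    rows = {
        hkl: tuple(tables[col_of[lab][0]].rows[hkl][col_of[lab][1]] for lab in labels)
        for hkl in hkls
    }
    return TscTable(
        title=base.title, symm=base.symm, scatterer_labels=labels, rows=rows
    )
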