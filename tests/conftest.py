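import numpy as np
import pytest

from slaterff.fixtures import (
    FixtureSpec,
    default_wavefunction_table,
    make_hydrogen,
    make_synthetic_species,
    make_toy_model,
)


@pytest.fixture(scope="session")
def hydrogen_free():
    """Exact free-atom hydrogen, zeta = 1.0 bohr^-1."""
    return make_hydrogen(1.0)


@pytest.fixture(scope="session")
def hydrogen_bonded():
    """Bonded-atom hydrogen, zeta = 1.15 bohr^-1 (bundled default)."""
    return make_hydrogen(1.15)


@pytest.fixture(scope="session")
def wf_table():
    return default_wavefunction_table()


@pytest.fixture(scope="session")
def species_set(wf_table):
    """A spread of species: exact H, minimal-basis atoms/ions, random synthetics."""
    return [
        make_hydrogen(1.0),
        make_hydrogen(1.15),
        wf_table.lookup("C"),
        wf_table.lookup("O"),
        wf_table.lookup("O", -1),
        wf_table.lookup("Ca"),
        make_synthetic_species(1, 1, seed=11),
        make_synthetic_species(2, 3, seed=12),
        make_synthetic_species(3, 4, seed=13),
    ]


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=5, noise_fraction=0.0, species=("C", "O"),
                       space_group="P21c", d_min=1.0)


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


def quadrature_form_factor(wf, s):
    """Independent oracle: adaptive quadrature of 4 pi r^2 rho(r) sinc(kr)."""
    import math

    from scipy.integrate import quad

    from slaterff.wavefunctions import BOHR_ANGSTROM, radial_density

    k = 4.0 * math.pi * s * BOHR_ANGSTROM
    if k == 0:
        integrand = lambda r: 4.0 * math.pi * r * r * radial_density(wf, r)
    else:
        integrand = lambda r: (
            4.0 * math.pi * r * r * radial_density(wf, r) * math.sin(k * r) / (k * r)
        )
    total = 0.0
    for lo, hi in ((0.0, 1.0), (1.0, 5.0), (5.0, 20.0), (20.0, 80.0)):
        val, _ = quad(integrand, lo, hi, limit=400, epsabs=1e-12, epsrel=1e-12)
        total += val
    return total
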