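"""Reflection geometry, Debye-Waller, structure factors, weights, file I/O."""

import math

import numpy as np
import pytest

from slaterff.crystal import (
    AtomSite,
    CifParseError,
    CrystalModel,
    HklParseError,
    Identity,
    ReflectionRecord,
    SpeciesError,
    UnitCell,
    debye_waller,
    expand_to_p1,
    hkl_sphere,
    read_cif_minimal,
    read_shelx_hkl,
    slater_xray_provider,
    stol,
    structure_factor,
    weights_and_rstats,
    write_cif_minimal,
    write_shelx_hkl,
)
from slaterff.fixtures import P21C_SYMOPS


@pytest.fixture(scope="module")
def cubic10():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="module")
def const_provider():
    return lambda element, charge, s: 6.0


class TestGeometry:
    def test_stol_cubic(self, cubic10):
        assert stol(cubic10, (2, 0, 0)) == pytest.approx(0.1)     # d = 5 A
        assert stol(cubic10, (0, 0, 0)) == 0.0

    def test_stol_permutation_symmetry(self, cubic10):
        vals = {stol(cubic10, h) for h in ((2, 0, 0), (0, 2, 0), (0, 0, 2))}
        assert len(vals) == 1

    def test_stol_triclinic_vs_gemmi(self):
        import gemmi

        cell = UnitCell(7.1, 8.3, 9.7, 82.0, 95.0, 103.0)
        g = gemmi.UnitCell(7.1, 8.3, 9.7, 82.0, 95.0, 103.0)
        for hkl in ((1, 2, 3), (-2, 0, 1), (4, -1, -3)):
            assert stol(cell, hkl) == pytest.approx(
                0.5 / g.calculate_d(hkl), rel=1e-10
            )
        assert cell.volume == pytest.approx(g.volume, rel=1e-10)

    def test_hkl_sphere_brute_force(self, cubic10):
        got = set(hkl_sphere(cubic10, 5.0))
        brute = {
            (h, k, l)
            for h in range(-4, 5) for k in range(-4, 5) for l in range(-4, 5)
            if (h, k, l) != (0, 0, 0) and h * h + k * k + l * l <= 4
        }
        assert got == brute

    def test_hkl_sphere_friedel_even_count(self, cubic10):
        refl = hkl_sphere(cubic10, 1.3)
        assert len(refl) % 2 == 0
        assert all((-h, -k, -l) in set(refl) for h, k, l in refl)

    def test_hkl_sphere_empty_and_invalid(self, cubic10):
        assert hkl_sphere(cubic10, 11.0) == []
        with pytest.raises(ValueError):
            hkl_sphere(cubic10, 0.0)


class TestDebyeWaller:
    def test_u_zero(self, cubic10):
        site = AtomSite("C1", "C", (0, 0, 0), u_iso=0.0)
        assert debye_waller(site, cubic10, (3, 1, 2)) == 1.0

    def test_isotropic_value(self, cubic10):
        # s = 0.5 at hkl (10,0,0): exp(-8 pi^2 * 0.015 * 0.25)
        site = AtomSite("C1", "C", (0, 0, 0), u_iso=0.015)
        assert debye_waller(site, cubic10, (10, 0, 0)) == pytest.approx(
            math.exp(-8.0 * math.pi ** 2 * 0.015 * 0.25), rel=1e-12
        )

    def test_isotropic_matrix_equals_u_iso_in_cubic(self, cubic10):
        u = 0.02
        iso = AtomSite("C1", "C", (0, 0, 0), u_iso=u)
        mat = AtomSite("C2", "C", (0, 0, 0), u_aniso=u * np.eye(3))
        for hkl in ((1, 0, 0), (2, 3, 1), (5, 5, 5)):
            assert debye_waller(mat, cubic10, hkl) == pytest.approx(
                debye_waller(iso, cubic10, hkl), rel=1e-12
            )

    def test_attenuation_bounded(self, cubic10):
        site = AtomSite("C1", "C", (0, 0, 0), u_aniso=np.diag((0.01, 0.02, 0.05)))
        for hkl in ((1, 2, 3), (9, 0, 0), (0, 0, 7)):
            assert 0.0 < debye_waller(site, cubic10, hkl) <= 1.0


class TestStructureFactor:
    def test_single_atom_at_origin(self, cubic10, const_provider):
        model = CrystalModel(cell=cubic10, sites=[AtomSite("C1", "C", (0, 0, 0), u_iso=0.0)])
        f = structure_factor(model, (3, 1, 2), const_provider)
        assert f == pytest.approx(6.0 + 0j, abs=1e-12)

    def test_half_shift_phase(self, cubic10, const_provider):
        model = CrystalModel(cell=cubic10, sites=[AtomSite("C1", "C", (0.5, 0, 0), u_iso=0.0)])
        for h in range(-3, 4):
            f = structure_factor(model, (h, 0, 0), const_provider)
            assert f.real == pytest.approx(6.0 * (-1) ** h, abs=1e-10)

    def test_paired_half_occupancy_cosine(self, cubic10, const_provider):
        x = 0.137
        model = CrystalModel(
            cell=cubic10,
            sites=[
                AtomSite("C1", "C", (x, 0, 0), occupancy=0.5, u_iso=0.0),
                AtomSite("C2", "C", (-x % 1.0, 0, 0), occupancy=0.5, u_iso=0.0),
            ],
        )
        for h in (1, 2, 5):
            f = structure_factor(model, (h, 0, 0), const_provider)
            assert f == pytest.approx(6.0 * math.cos(2 * math.pi * h * x), abs=1e-10)

    def test_friedel_symmetry(self, toy_model, wf_table):
        provider = slater_xray_provider(wf_table)
        for hkl in ((1, 2, 3), (0, 4, -1), (-2, 1, 5)):
            f = structure_factor(toy_model, hkl, provider)
            f_bar = structure_factor(toy_model, tuple(-i for i in hkl), provider)
            assert f_bar == pytest.approx(f.conjugate(), rel=1e-10)

    def test_f000_counts_electrons(self, cubic10, wf_table):
        provider = slater_xray_provider(wf_table)
        model = CrystalModel(
            cell=cubic10,
            sites=[
                AtomSite("C1", "C", (0.1, 0.2, 0.3), u_iso=0.0),
                AtomSite("O1", "O", (0.6, 0.1, 0.8), occupancy=0.5, u_iso=0.0),
            ],
        )
        f = structure_factor(model, (0, 0, 0), provider)
        assert f.real == pytest.approx(6.0 + 0.5 * 8.0, rel=1e-10)

    def test_symmetry_expansion_vs_explicit_p1(self, cubic10, const_provider):
        """P2_1/c symop expansion equals listing all equivalents in P1."""
        x = (0.11, 0.23, 0.31)
        sym_model = CrystalModel(
            cell=cubic10, symops=list(P21C_SYMOPS),
            sites=[AtomSite("C1", "C", x, u_iso=0.01)],
        )
        images = [
            x,
            (-x[0] % 1, (x[1] + 0.5) % 1, (-x[2] + 0.5) % 1),
            (-x[0] % 1, -x[1] % 1, -x[2] % 1),
            (x[0] % 1, (-x[1] + 0.5) % 1, (x[2] + 0.5) % 1),
        ]
        p1_model = CrystalModel(
            cell=cubic10,
            sites=[AtomSite(f"C{i}", "C", im, u_iso=0.01) for i, im in enumerate(images)],
        )
        for hkl in ((1, 2, 3), (2, 0, 1), (-3, 1, -2)):
            assert structure_factor(sym_model, hkl, const_provider) == pytest.approx(
                structure_factor(p1_model, hkl, const_provider), abs=1e-9
            )

    def test_special_position_dedup(self, cubic10, const_provider):
        """An atom on an inversion centre is not double counted."""
        model = CrystalModel(
            cell=cubic10,
            symops=[Identity, (-np.eye(3, dtype=int), np.zeros(3))],
            sites=[AtomSite("C1", "C", (0, 0, 0), u_iso=0.0)],
        )
        assert len(expand_to_p1(model)) == 1

    def test_missing_species_named(self, cubic10, wf_table):
        provider = slater_xray_provider(wf_table)
        model = CrystalModel(cell=cubic10, sites=[AtomSite("Os1", "Os", (0, 0, 0), u_iso=0.0)])
        with pytest.raises(SpeciesError, match="Os"):
            structure_factor(model, (1, 0, 0), provider)

    def test_identity_required(self, cubic10):
        with pytest.raises(ValueError):
            CrystalModel(cell=cubic10,
                         symops=[(-np.eye(3, dtype=int), np.zeros(3))],
                         sites=[])


class TestWeightsAndRStats:
    def _records(self, fo2, sig, fc):
        return [
            ReflectionRecord((i, 0, 0), f, s, Fc=c)
            for i, (f, s, c) in enumerate(zip(fo2, sig, fc), start=1)
        ]

    def test_perfect_agreement(self):
        fc = [3.0 + 0j, 1.5 + 2j, -0.5 + 0.1j]
        fo2 = [abs(c) ** 2 for c in fc]
        recs = self._records(fo2, [0.1] * 3, fc)
        r1, wr2, w = weights_and_rstats(recs, a=0.05, b=0.3)
        assert r1 == 0.0 and wr2 == 0.0

    def test_pure_sigma_weights(self):
        recs = self._records([4.0, 9.0], [0.5, 2.0], [2.1 + 0j, 2.8 + 0j])
        _, _, w = weights_and_rstats(recs, a=0.0, b=0.0)
        assert np.allclose(w, [1 / 0.25, 1 / 4.0])

    def test_against_spreadsheet_recomputation(self):
        fo2 = np.array([104.0, 46.0, -1.2, 8.9])
        sig = np.array([2.0, 1.5, 0.8, 1.1])
        fc = np.array([10.1 + 0.5j, 6.6 - 1.0j, 0.4 + 0.4j, 3.1 + 0j])
        a_w, b_w = 0.1, 0.2
        recs = self._records(fo2, sig, fc)
        r1, wr2, w = weights_and_rstats(recs, a=a_w, b=b_w)

        fc2 = np.abs(fc) ** 2
        p = (np.maximum(fo2, 0) + 2 * fc2) / 3
        w_ref = 1.0 / (sig ** 2 + (a_w * p) ** 2 + b_w * p)
        wr2_ref = math.sqrt(np.sum(w_ref * (fo2 - fc2) ** 2) / np.sum(w_ref * fo2 ** 2))
        strong = fo2 > 2 * sig
        fo = np.sqrt(np.maximum(fo2[strong], 0))
        r1_ref = np.sum(np.abs(fo - np.abs(fc[strong]))) / np.sum(fo)
        assert np.allclose(w, w_ref)
        assert wr2 == pytest.approx(wr2_ref, rel=1e-12)
        assert r1 == pytest.approx(r1_ref, rel=1e-12)

    def test_empty_and_bad_sigma(self):
        with pytest.raises(ValueError):
            weights_and_rstats([], a=0.1)
        with pytest.raises(ValueError):
            weights_and_rstats(
                [ReflectionRecord((1, 0, 0), 1.0, 0.0, Fc=1.0 + 0j)], a=0.1
            )


class TestCifIO:
    def test_round_trip(self, toy_model):
        text = write_cif_minimal(toy_model)
        back = read_cif_minimal(text)
        assert len(back.sites) == len(toy_model.sites)
        assert len(back.symops) == len(toy_model.symops)
        for s1, s2 in zip(toy_model.sites, back.sites):
            assert np.allclose(s1.xyz, s2.xyz, atol=1e-6)
            assert s2.u_iso == pytest.approx(s1.u_iso, abs=1e-6)

    def test_aniso_loop(self, toy_model):
        model = CrystalModel(
            cell=toy_model.cell,
            sites=[AtomSite("O1", "O", (0.1, 0.2, 0.3),
                            u_aniso=np.array([[0.02, 0.001, 0.0],
                                              [0.001, 0.03, -0.002],
                                              [0.0, -0.002, 0.01]]))],
        )
        back = read_cif_minimal(write_cif_minimal(model))
        assert back.sites[0].u_aniso is not None
        assert np.allclose(back.sites[0].u_aniso, model.sites[0].u_aniso, atol=1e-6)

    def test_missing_cell_and_sites(self):
        with pytest.raises(CifParseError):
            read_cif_minimal("data_x\n_cell_length_a 10\n")
        with pytest.raises(CifParseError, match="atom_site"):
            read_cif_minimal(
                "data_x\n_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
                "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
            )


class TestHklIO:
    def test_single_record(self):
        line = "   1   0   0  100.00    2.00\n   0   0   0    0.00    0.00\n"
        assert read_shelx_hkl(line) == [((1, 0, 0), 100.0, 2.0)]

    def test_terminator_stops_parsing(self):
        text = (
            "   1   0   0  100.00    2.00\n"
            "   0   0   0    0.00    0.00\n"
            "   2   0   0   50.00    1.00\n"
        )
        assert len(read_shelx_hkl(text)) == 1

    def test_negative_fo2_preserved(self):
        text = "  -1   2  -3   -4.50    1.25\n   0   0   0    0.00    0.00\n"
        ((hkl, fo2, sig),) = read_shelx_hkl(text)
        assert hkl == (-1, 2, -3) and fo2 == -4.5 and sig == 1.25

    def test_misaligned_column_errors_with_line(self):
        with pytest.raises(HklParseError) as err:
            read_shelx_hkl("  1  0  0  100.00    2.00\n")
        assert err.value.line == 1

    def test_write_read_round_trip(self):
        recs = [((1, 2, 3), 12.25, 0.5), ((-4, 0, 2), -0.75, 1.0)]
        assert read_shelx_hkl(write_shelx_hkl(recs)) == recs
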