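"""Energy function: closed forms, oracles, NEA/FDB consistency, matrix."""

import numpy as np
import pytest
from scipy import integrate

from pdzdesign import (
    FDB,
    NEA,
    BornRadiiSet,
    folded_energy,
    gb_polarization_energy,
    lj_energy,
    precompute_energy_matrix,
    realize,
    sasa,
)
from pdzdesign.constants import AA1_TO_AA3
from pdzdesign.energetics import (
    _hct_radii,
    born_radii,
    hct_inverse_radius_terms,
)
from pdzdesign.errors import DegenerateGeometryError, UnsupportedModeError
from pdzdesign.params import ForceFieldParams, load_forcefield
from pdzdesign.sidechain import SystemState, native_state
from pdzdesign.synthetic import SyntheticScaffoldConfig, make_scaffold


class TestLennardJones:
    def test_root_at_sigma(self):
        assert lj_energy(3.4, 0.1, 3.4, 0.1, 3.4) == 0.0

    def test_minimum_at_r_min(self):
        r_min = 2 ** (1 / 6) * 3.4
        assert lj_energy(3.4, 0.1, 3.4, 0.1, r_min) == pytest.approx(
            -0.1, abs=1e-12
        )

    def test_against_independent_formula(self):
        # independently coded evaluation with explicit combining rules
        si, ei, sj, ej, r = 3.4, 0.1, 3.0, 0.2, 4.0
        sig = (si + sj) / 2
        eps = (ei * ej) ** 0.5
        expected = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert lj_energy(si, ei, sj, ej, r) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_distance_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            lj_energy(3.4, 0.1, 3.4, 0.1, 0.0)


class TestBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        b = _hct_radii(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.7]),
            np.array([[0.0, 0.0, 0.0]]), np.array([1.36]),
            skip_self=True,
        )
        assert b[0] == pytest.approx(1.7, abs=1e-12)

    def test_two_atom_against_numeric_integration(self):
        """Analytic HCT term vs numeric shell integration of 1/s^4."""

        def numeric(d, rho, a):
            def frac(s):
                if s >= d + a:
                    return 0.0
                if s <= abs(d - a):
                    return 1.0 if (d < a and s < a - d) else 0.0
                return (1 - (s * s + d * d - a * a) / (2 * d * s)) / 2

            val, _ = integrate.quad(
                lambda s: frac(s) / s**2, rho, d + a, limit=200
            )
            return val

        for d, rho, a in [(4.0, 1.7, 1.36), (2.5, 1.5, 1.6), (1.0, 1.2, 1.9)]:
            h = hct_inverse_radius_terms(np.array([d]), rho, np.array([a]))[0]
            assert h == pytest.approx(numeric(d, rho, a), rel=0.02)
        # full two-atom system at 4 A
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        rho = np.array([1.7, 1.7])
        b = _hct_radii(coords, rho, coords, 0.8 * rho, skip_self=True)
        inv_expected = 1 / 1.7 - numeric(4.0, 1.7, 0.8 * 1.7)
        assert b[0] == pytest.approx(1 / inv_expected, rel=0.02)

    def test_radii_never_below_intrinsic(self, helix6, ff, library):
        r = realize(native_state(helix6), ff, library)
        b = born_radii(r, ff, FDB)
        assert np.all(b.radii >= r.pset.rho - 1e-12)

    def test_nea_environment_is_frozen(self, helix6, ff, library, toy_spec):
        """Changing one residue leaves every other residue's radii fixed."""
        nat = realize(native_state(helix6), ff, library)
        s1 = SystemState(helix6, "ASAAAA", (0, 1, 0, 0, 0, 0))
        s2 = SystemState(helix6, "ALAAAA", (0, 4, 0, 0, 0, 0))
        b1 = born_radii(realize(s1, ff, library), ff, NEA, native=nat)
        b2 = born_radii(realize(s2, ff, library), ff, NEA, native=nat)
        r1, r2 = realize(s1, ff, library), realize(s2, ff, library)
        for i in range(len(r1.atoms)):
            if r1.atoms.res_index[i] == 1:
                continue
            j = [
                k
                for k in range(len(r2.atoms))
                if r2.atoms.res_index[k] == r1.atoms.res_index[i]
                and r2.atoms.names[k] == r1.atoms.names[i]
            ][0]
            assert b1.radii[i] == pytest.approx(b2.radii[j], abs=1e-12)

    def test_coincident_atoms_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        rho = np.array([1.7, 1.7])
        with pytest.raises(DegenerateGeometryError):
            _hct_radii(coords, rho, coords, 0.8 * rho, skip_self=True)


class TestGBPolarization:
    def test_born_ion_closed_form(self, ff):
        q, B = 1.0, 2.0
        born = BornRadiiSet(np.array([B]), "FDB-current")
        e = gb_polarization_energy(
            np.array([q]), np.zeros((1, 3)), born, ff
        )
        expected = (
            -0.5
            * ff.coulomb_k
            * (1 / ff.eps_protein - 1 / ff.eps_water)
            * q**2
            / B
        )
        assert e == pytest.approx(expected, abs=1e-12)

    def test_zero_charges_give_zero(self, ff):
        born = BornRadiiSet(np.ones(4) * 1.5, "FDB-current")
        coords = np.random.default_rng(0).normal(size=(4, 3)) * 5
        assert gb_polarization_energy(np.zeros(4), coords, born, ff) == 0.0

    def test_two_charge_cross_term(self, ff):
        """Screened cross term against an independent formula coding."""
        r, B = 20.0, 2.0
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        born = BornRadiiSet(np.array([B, B]), "FDB-current")
        e = gb_polarization_energy(np.array([1.0, 1.0]), coords, born, ff)
        fgb = np.sqrt(r**2 + B * B * np.exp(-(r**2) / (4 * B * B)))
        tau = 1 / ff.eps_protein - 1 / ff.eps_water
        expected = -ff.coulomb_k * tau * (1.0 / fgb) - ff.coulomb_k * tau * (
            1.0 / B
        )  # cross + two self terms (q=1 each)
        assert e == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, ff):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(6, 3)) * 4
        q = rng.normal(size=6)
        born = BornRadiiSet(rng.uniform(1.2, 2.5, 6), "FDB-current")
        e0 = gb_polarization_energy(q, coords, born, ff)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        e1 = gb_polarization_energy(q, moved, born, ff)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestSasa:
    def test_isolated_atom_sphere_area(self):
        a = sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert a[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.005)

    def test_coincident_atoms_count_once(self):
        coords = np.zeros((2, 3))
        a = sasa(coords, np.array([1.7, 1.7]), probe=1.4)
        assert a.sum() == pytest.approx(4 * np.pi * 3.1**2, rel=0.005)

    def test_three_atom_toy_against_grid_oracle(self):
        """Per-atom areas vs a dense surface-sampling oracle."""
        coords = np.array(
            [[0.0, 0.0, 0.0], [2.5, 0.0, 0.0], [1.2, 2.0, 0.5]]
        )
        radii = np.array([1.7, 1.5, 1.9])
        probe = 1.4
        areas = sasa(coords, radii, probe)
        # oracle: very dense independent spherical sampling per atom
        rng = np.random.default_rng(7)
        ext = radii + probe
        for i in range(3):
            v = rng.normal(size=(40000, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = coords[i] + ext[i] * v
            outside = np.ones(len(pts), dtype=bool)
            for j in range(3):
                if j != i:
                    outside &= (
                        np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
                    )
            oracle = 4 * np.pi * ext[i] ** 2 * outside.mean()
            assert areas[i] == pytest.approx(oracle, rel=0.02, abs=0.5)

    def test_against_independent_library_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on the same radii."""
        import biotite.structure as struc

        coords = np.array(
            [[0.0, 0.0, 0.0], [2.5, 0.0, 0.0], [1.2, 2.0, 0.5]]
        )
        radii = np.array([1.7, 1.5, 1.9])
        arr = struc.AtomArray(3)
        arr.coord[:] = coords
        arr.atom_name[:] = ["C1", "C2", "C3"]
        arr.element[:] = "C"
        arr.res_id[:] = 1
        arr.res_name[:] = "LIG"
        arr.chain_id[:] = "A"
        ref = struc.sasa(
            arr, probe_radius=1.4, vdw_radii=radii, point_number=2000
        )
        mine = sasa(coords, radii, 1.4)
        assert np.allclose(mine, ref, rtol=0.02, atol=0.5)


class TestFoldedEnergy:
    @pytest.mark.parametrize(
        "n,topology,seq",
        [
            (5, "helix", None),
            (8, "hairpin", None),
            (12, "helix-hairpin", None),
            (6, "helix", "ASLKDE"),
        ],
    )
    def test_nea_equals_fdb_on_native(self, ff, library, n, topology, seq):
        sc = make_scaffold(
            SyntheticScaffoldConfig(n, topology, seq or "poly-ALA")
        )
        st = native_state(sc)
        e_nea = folded_energy(st, ff, NEA, library)
        e_fdb = folded_energy(st, ff, FDB, library)
        assert abs(e_nea.total - e_fdb.total) < 1e-6

    def test_no_solvent_contrast_kills_gb(self, helix6, library):
        ff = ForceFieldParams(
            classes=load_forcefield().classes,
            eps_protein=4.0,
            eps_water=4.0 + 1e-9,
        )
        e = folded_energy(native_state(helix6), ff, FDB, library)
        assert abs(e.gb_polarization) < 1e-6

    def test_components_sum_to_total(self, ff, library):
        sc = make_scaffold(SyntheticScaffoldConfig(3, "helix", "ALS"))
        e = folded_energy(native_state(sc), ff, FDB, library)
        assert e.total == pytest.approx(
            e.lj + e.coulomb + e.gb_polarization + e.nonpolar_surface,
            abs=1e-12,
        )

    def test_fdb_differs_from_nea_off_native(self, helix6, ff, library):
        """The many-body solvation effect NEA discards."""
        st = SystemState(helix6, "AKLAEA", (0, 3, 4, 0, 1, 0))
        e_nea = folded_energy(st, ff, NEA, library)
        e_fdb = folded_energy(st, ff, FDB, library)
        assert abs(e_nea.total - e_fdb.total) > 1e-3


class TestEnergyMatrix:
    def test_reconstruction_on_random_states(
        self, helix6, toy_spec, ff, library
    ):
        """Matrix reconstruction equals direct NEA evaluation."""
        mat = precompute_energy_matrix(helix6, toy_spec, library, ff)
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = list(helix6.sequence)
            rots = [0] * len(helix6)
            for pos in mat.positions:
                if toy_spec.classes[pos] == "mutable":
                    seq[pos] = rng.choice(sorted(toy_spec.allowed[pos]))
                rots[pos] = int(
                    rng.integers(
                        library.n_rotamers(AA1_TO_AA3[seq[pos]])
                    )
                )
            st = SystemState(helix6, "".join(seq), tuple(rots))
            direct = folded_energy(st, ff, NEA, library).total
            assert mat.energy(st) == pytest.approx(direct, abs=1e-6)

    def test_native_reconstruction(self, helix6, toy_spec, ff, library):
        mat = precompute_energy_matrix(helix6, toy_spec, library, ff)
        st = native_state(helix6)
        direct = folded_energy(st, ff, NEA, library).total
        assert mat.energy(st) == pytest.approx(direct, abs=1e-6)

    def test_fdb_decomposition_rejected(self, helix6, toy_spec, ff, library):
        with pytest.raises(UnsupportedModeError):
            precompute_energy_matrix(
                helix6, toy_spec, library, ff, mode=FDB
            )

    def test_pair_access_symmetric(self, helix6, toy_spec, ff, library):
        mat = precompute_energy_matrix(helix6, toy_spec, library, ff)
        assert np.array_equal(mat.pair(0, 1), mat.pair(1, 0).T)
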