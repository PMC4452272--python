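"""Energy engine: pairwise terms, GB limits, SASA, decomposition, ensembles.

Every nontrivial expectation is checked against an independently coded
oracle: plain-Python O(N²) loops for the pairwise sums, analytic closed
forms for the Born ion and the two-sphere SASA lens, and Monte-Carlo
quadrature for the GB descreening integral.
"""

import math

import numpy as np
import pytest

from mtring import (
    born_radii,
    coulomb_pair,
    ensemble_average,
    gb_energy,
    interaction_energy,
    lj_pair,
    make_subsystem,
    nonpolar_energy,
    sasa,
)
from mtring.energy import GB_OFFSET, K_COULOMB, SingularityError, _hct_integral
from mtring.lattice import Atoms, Subsystem


def make_atoms(coords, charge=None, rmin2=1.9, eps=0.11, gb_r=1.5, screen=0.8,
               res_num=None, subunit="alpha"):
    n = len(coords)
    return Atoms(
        coords=np.asarray(coords, float),
        atom_name=["CA"] * n,
        element=["C"] * n,
        res_name=["ALA"] * n,
        res_num=res_num if res_num is not None else np.arange(1, n + 1),
        subunit=[subunit] * n,
        dimer_index=np.ones(n, int),
        charge=np.full(n, 0.0) if charge is None else np.asarray(charge, float),
        rmin2=np.full(n, rmin2),
        epsilon=np.full(n, eps),
        gb_radius=np.full(n, gb_r),
        gb_screen=np.full(n, screen),
        mass=np.full(n, 12.0),
    )


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------


class TestCoulomb:
    def test_unit_charges_at_3A(self):
        # 332.0636 / 3 by hand
        assert coulomb_pair(1.0, 1.0, 3.0, 1.0) == pytest.approx(110.688, abs=5e-4)

    def test_zero_charge_and_antisymmetry(self):
        assert coulomb_pair(0.0, 0.7, 2.2) == 0.0
        assert coulomb_pair(0.5, -0.5, 2.0) == -coulomb_pair(0.5, 0.5, 2.0)

    def test_dielectric_scaling(self):
        assert coulomb_pair(1.0, 1.0, 2.0, 4.0) == pytest.approx(
            coulomb_pair(1.0, 1.0, 2.0, 1.0) / 4.0
        )

    def test_singularity(self):
        with pytest.raises(SingularityError):
            coulomb_pair(1.0, 1.0, 0.0)


class TestLennardJones:
    def test_minimum_at_rmin(self):
        # at r = r_min,ij the 12-6 potential equals exactly −ε_ij
        assert lj_pair(1.9, 0.1, 2.1, 0.2, 4.0) == pytest.approx(
            -math.sqrt(0.1 * 0.2)
        )

    def test_zero_epsilon(self):
        assert lj_pair(1.9, 0.0, 1.9, 0.11, 3.3) == 0.0

    def test_against_brute_formula(self):
        # independent evaluation of ε[(rmin/r)^12 − 2(rmin/r)^6]
        rmin2, eps, r = 1.9080, 0.1094, 4.5
        rmin = 2 * rmin2
        expected = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_pair(rmin2, eps, rmin2, eps, r) == pytest.approx(
            expected, rel=1e-12
        )


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------


def mc_descreening_integral(r, s, rho_i, n=400_000, seed=7):
    """(1/4π)∫ dV/x⁴ over the ball of radius s at distance r, excluding x<ρ_i."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    radii = s * rng.random(n) ** (1 / 3)
    pts = pts * radii[:, None]
    pts[:, 0] += r
    x = np.linalg.norm(pts, axis=1)
    vals = np.where(x > rho_i, 1.0 / x**4, 0.0)
    return (4 / 3 * np.pi * s**3) * vals.mean() / (4 * np.pi)


class TestBornRadii:
    def test_isolated_atom(self):
        atoms = make_atoms([[0, 0, 0]], gb_r=1.5)
        assert born_radii(atoms)[0] == pytest.approx(1.5 - GB_OFFSET, abs=1e-12)

    def test_distant_atoms_are_isolated(self):
        atoms = make_atoms([[0, 0, 0], [500.0, 0, 0]], gb_r=1.5)
        assert np.allclose(born_radii(atoms), 1.5 - GB_OFFSET, atol=1e-6)

    def test_hct_integral_matches_quadrature(self):
        # closed-form pairwise descreening vs Monte-Carlo volume integral
        for r, s, rho in [(4.0, 1.3, 1.4), (2.5, 1.2, 1.4), (1.6, 1.3, 1.2)]:
            closed = float(_hct_integral(np.array(r), np.array(s), np.array(rho)))
            mc = mc_descreening_integral(r, s, rho)
            assert closed == pytest.approx(mc, rel=0.02)

    def test_burial_grows_radii(self):
        # a compact cluster descreens every atom: effective > isolated radius
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1.5, size=(10, 3))
        atoms = make_atoms(coords, gb_r=1.6)
        radii = born_radii(atoms)
        assert (radii > 1.6 - GB_OFFSET).all()

    def test_coincident_atoms_error(self):
        atoms = make_atoms([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(SingularityError):
            born_radii(atoms)


class TestGBEnergy:
    def test_born_ion_closed_form(self):
        # single ion, q=+1, effective radius 2 Å, ε 1→80:
        # −(1/2)(1 − 1/80)·332.0636/2 = −81.978 kcal/mol
        atoms = make_atoms([[0, 0, 0]], charge=[1.0])
        total, per_atom = gb_energy(atoms, radii=np.array([2.0]))
        expected = -0.5 * (1 - 1 / 80) * K_COULOMB / 2.0
        assert total == pytest.approx(expected, abs=1e-9)
        assert total == pytest.approx(-81.978, abs=5e-4)
        assert per_atom[0] == pytest.approx(total)

    def test_vacuum_limit_is_zero(self):
        rng = np.random.default_rng(0)
        atoms = make_atoms(rng.normal(0, 3, (8, 3)), charge=rng.normal(0, 0.5, 8))
        total, _ = gb_energy(atoms, eps_in=1.0, eps_out=1.0)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_far_separation_additivity(self):
        # two distant ions → sum of two Born self energies within 0.1%
        atoms = make_atoms([[0, 0, 0], [4000.0, 0, 0]], charge=[1.0, -1.0], gb_r=1.8)
        total, _ = gb_energy(atoms)
        single = make_atoms([[0, 0, 0]], charge=[1.0], gb_r=1.8)
        e1, _ = gb_energy(single)
        assert total == pytest.approx(2 * e1, rel=1e-3)

    def test_invalid_dielectrics(self):
        atoms = make_atoms([[0, 0, 0]], charge=[1.0])
        with pytest.raises(ValueError):
            gb_energy(atoms, eps_in=0.0)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


class TestSASA:
    def test_isolated_sphere(self):
        atoms = make_atoms([[0, 0, 0]], gb_r=1.7)
        areas = sasa(atoms, probe_radius=1.4, n_points=960)
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_buried_atom_zero_area(self):
        # central atom enclosed by a dense shell of large spheres
        shell = []
        for phi in np.linspace(0.3, np.pi - 0.3, 6):
            for theta in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                shell.append(
                    3.0
                    * np.array(
                        [
                            np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi),
                        ]
                    )
                )
        coords = [[0.0, 0.0, 0.0], [0, 0, 3.0], [0, 0, -3.0]] + shell
        atoms = make_atoms(coords, gb_r=2.5)
        areas = sasa(atoms, probe_radius=1.4, n_points=240)
        assert areas[0] == 0.0

    def test_two_sphere_lens_analytic(self):
        # exposed area of overlapping spheres vs the spherical-cap formula
        r1, r2, w, d = 1.9, 1.6, 1.4, 3.0
        a, b = r1 + w, r2 + w
        atoms = make_atoms([[0, 0, 0], [d, 0, 0]], gb_r=[0, 0])
        atoms.gb_radius[:] = [r1, r2]
        areas = sasa(atoms, probe_radius=w, n_points=960)
        h1 = a - (d**2 + a**2 - b**2) / (2 * d)
        h2 = b - (d**2 + b**2 - a**2) / (2 * d)
        exp1 = 4 * np.pi * a**2 - 2 * np.pi * a * h1
        exp2 = 4 * np.pi * b**2 - 2 * np.pi * b * h2
        assert areas[0] == pytest.approx(exp1, rel=0.02)
        assert areas[1] == pytest.approx(exp2, rel=0.02)

    def test_nonpolar_energy_scaling(self):
        areas = np.array([100.0, 50.0])
        assert nonpolar_energy(areas, gamma=0.0072, beta=0.0) == pytest.approx(1.08)

    def test_negative_probe_rejected(self):
        atoms = make_atoms([[0, 0, 0]])
        with pytest.raises(ValueError):
            sasa(atoms, probe_radius=-0.1)


# ---------------------------------------------------------------------------
# Interaction energy decomposition
# ---------------------------------------------------------------------------


def two_body_subsystem(r=4.2, q1=0.6, q2=-0.4):
    rec = make_atoms([[0, 0, 0]], charge=[q1], gb_r=1.6)
    lig = make_atoms([[r, 0, 0]], charge=[q2], gb_r=1.5, subunit="beta")
    return Subsystem(receptor=rec, ligand=lig, kind="lateral", index=1)


class TestInteractionEnergy:
    def test_all_zero_parameters_give_zero(self):
        rec = make_atoms([[0, 0, 0], [1.8, 0, 0]], res_num=[1, 2])
        lig = make_atoms([[5.0, 0, 0], [6.8, 0, 0]], res_num=[1, 2], subunit="beta")
        for a in (rec, lig):
            a.charge[:] = 0.0
            a.epsilon[:] = 0.0
        sub = Subsystem(receptor=rec, ligand=lig, kind="lateral", index=1)
        t = interaction_energy(sub, sa_gamma=0.0)
        assert abs(t.df[["E_vdW", "E_ele", "E_GB", "E_SA"]]).to_numpy().max() == 0.0

    def test_two_body_closed_form(self):
        # every component against independently coded formulas
        r, q1, q2 = 4.2, 0.6, -0.4
        sub = two_body_subsystem(r, q1, q2)
        t = interaction_energy(sub, sa_gamma=0.0)
        tot = t.totals()
        assert tot.E_vdW == pytest.approx(
            lj_pair(1.9, 0.11, 1.9, 0.11, r), rel=1e-12
        )
        assert tot.E_ele == pytest.approx(K_COULOMB * q1 * q2 / r, rel=1e-12)
        # GB oracle: Still equation with two-atom OBC radii, hand-coded
        def obc_radius(rho_self, rho_other, screen, R_self):
            s = screen * rho_other
            L = max(abs(r - s), rho_self)
            U = r + s
            H = 0.5 * (
                1 / L - 1 / U
                + 0.25 * (r - s**2 / r) * (1 / U**2 - 1 / L**2)
                + 0.5 / r * math.log(L / U)
            )
            psi = H * rho_self
            return 1.0 / (
                1 / rho_self - math.tanh(1.0 * psi - 0.8 * psi**2 + 4.85 * psi**3) / R_self
            )

        rho1, rho2 = 1.6 - GB_OFFSET, 1.5 - GB_OFFSET
        B1 = obc_radius(rho1, rho2, 0.8, 1.6)
        B2 = obc_radius(rho2, rho1, 0.8, 1.5)
        pref = -0.5 * (1 - 1 / 80) * K_COULOMB
        def still(q_a, q_b, Ba, Bb, rr):
            f = math.sqrt(rr**2 + Ba * Bb * math.exp(-(rr**2) / (4 * Ba * Bb)))
            return pref * q_a * q_b / f

        e_complex = (
            still(q1, q1, B1, B1, 0) + still(q2, q2, B2, B2, 0)
            + 2 * still(q1, q2, B1, B2, r)
        )
        e_isolated = still(q1, q1, rho1, rho1, 0) + still(q2, q2, rho2, rho2, 0)
        assert tot.E_GB == pytest.approx(e_complex - e_isolated, rel=1e-9)

    def test_brute_force_oracle_on_toy_subsystem(self, toy_subsystems):
        # cross-molecular vdW+ele pair sums vs plain-Python O(N²) loops
        sub = toy_subsystems[0]
        t = interaction_energy(sub, sa_gamma=0.0)
        rec, lig = sub.receptor, sub.ligand
        e_vdw = e_ele = 0.0
        for i in range(len(rec)):
            for j in range(len(lig)):
                rij = float(np.linalg.norm(rec.coords[i] - lig.coords[j]))
                e_vdw += lj_pair(
                    rec.rmin2[i], rec.epsilon[i], lig.rmin2[j], lig.epsilon[j], rij
                )
                e_ele += K_COULOMB * rec.charge[i] * lig.charge[j] / rij
        assert t.totals().E_vdW == pytest.approx(e_vdw, rel=1e-9)
        assert t.totals().E_ele == pytest.approx(e_ele, rel=1e-9)

    def test_per_residue_additivity(self, toy_subsystems):
        # Σ residues = subsystem total, every component, every subsystem kind
        for sub in (toy_subsystems[0], toy_subsystems[12], toy_subsystems[13]):
            t = interaction_energy(sub)
            totals = t.totals().as_dict()
            for comp, tot in totals.items():
                assert t.df[comp].sum() == pytest.approx(tot, rel=1e-6, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_subsystems):
        sub = toy_subsystems[13]
        t0 = interaction_energy(sub, sasa_points=120)
        ang = 0.7
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        rec = sub.receptor.transformed(rot, (5.0, -3.0, 11.0))
        lig = sub.ligand.transformed(rot, (5.0, -3.0, 11.0))
        moved = Subsystem(receptor=rec, ligand=lig, kind=sub.kind, index=sub.index)
        t1 = interaction_energy(moved, sasa_points=120)
        assert t1.total == pytest.approx(t0.total, abs=1e-6)

    def test_role_swap_preserves_total_and_pair_shares(self, toy_subsystems):
        sub = toy_subsystems[0]
        swapped = Subsystem(
            receptor=sub.ligand, ligand=sub.receptor, kind=sub.kind, index=sub.index
        )
        t0 = interaction_energy(sub, sasa_points=120)
        t1 = interaction_energy(swapped, sasa_points=120)
        assert t1.total == pytest.approx(t0.total, abs=1e-9)
        # vdW/ele shares are symmetric under the half-split: the receptor
        # share of the original equals the ligand share of the swapped system
        for comp in ("E_vdW", "E_ele"):
            orig_r = t0.df.xs("R", level="role")[comp]
            swap_l = t1.df.xs("L", level="role")[comp]
            assert np.allclose(orig_r.to_numpy(), swap_l.to_numpy(), atol=1e-9)

    def test_unparameterized_atoms_error(self, toy_subsystems):
        from mtring.energy import ParameterizationError

        sub = toy_subsystems[0]
        bad_rec = sub.receptor.copy()
        bad_rec.charge[0] = np.nan
        bad = Subsystem(receptor=bad_rec, ligand=sub.ligand, kind="lateral", index=1)
        with pytest.raises(ParameterizationError):
            interaction_energy(bad)


# ---------------------------------------------------------------------------
# Ensemble averaging
# ---------------------------------------------------------------------------


class TestEnsembleAverage:
    def _frame_tables(self, toy_subsystems, scales):
        base = interaction_energy(toy_subsystems[0], sasa_points=120)
        return [base.scaled(s) for s in scales]

    def test_identical_frames(self, toy_subsystems):
        tables = self._frame_tables(toy_subsystems, [1.0, 1.0, 1.0])
        ens = ensemble_average(tables)
        assert ens.total_sd.E_vdW == pytest.approx(0.0, abs=1e-12)
        assert ens.total_mean.E_vdW == pytest.approx(tables[0].totals().E_vdW)

    def test_two_frame_mean(self, toy_subsystems):
        base = interaction_energy(toy_subsystems[0], sasa_points=120)
        t_tot = base.total
        tables = [base.scaled(-10.0 / t_tot), base.scaled(-20.0 / t_tot)]
        ens = ensemble_average(tables)
        mean_total = sum(ens.total_mean.as_dict()[c] for c in
                         ("E_vdW", "E_ele", "E_GB", "E_SA"))
        assert mean_total == pytest.approx(-15.0, rel=1e-9)

    def test_gaussian_sd_recovery(self, toy_subsystems):
        # 200 frames with Gaussian-scaled totals: sample SD within 15% of σ
        rng = np.random.default_rng(11)
        base = interaction_energy(toy_subsystems[0], sasa_points=120)
        t_tot = base.total
        sigma, mu = 4.0, -50.0
        draws = rng.normal(mu, sigma, 200)
        tables = [base.scaled(d / t_tot) for d in draws]
        ens = ensemble_average(tables)
        assert ens.grand_total_mean == pytest.approx(draws.mean(), rel=1e-9)
        assert ens.grand_total_sd == pytest.approx(np.std(draws, ddof=0), rel=1e-9)
        assert ens.grand_total_sd == pytest.approx(sigma, rel=0.15)

    def test_inconsistent_residue_sets_rejected(self, toy_subsystems):
        t1 = interaction_energy(toy_subsystems[0], sasa_points=120)
        t2 = interaction_energy(toy_subsystems[13], sasa_points=120)
        t2b = t2
        t2b.df = t2.df.iloc[:-1]
        with pytest.raises(ValueError):
            ensemble_average([t1, t2b])
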