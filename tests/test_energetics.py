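"""Energetics: MM terms, GB/SASA solvation, NMA entropy, affinity tables."""

import numpy as np
import pytest

from switchscope._constants import (
    GB_PREFACTOR,
    EPS_SOLVENT,
    H_PLANCK,
    KB_J,
    OMEGA2_PER_EIGVAL,
    R_KCAL,
)
from switchscope import refdata
from switchscope.energetics import (
    ElasticNetworkModel,
    EnergeticsError,
    EnergyReport,
    assemble_affinity_table,
    covalent_energy,
    dg_from_ic50,
    gb_polar_energy,
    harmonic_entropy,
    mm_interaction_energy,
    mmgbsa_binding,
    nma_entropy,
    numerical_hessian,
    per_residue_decomposition,
    r_squared,
    shrake_rupley_sasa,
    solvation_energy,
    vibrational_entropy,
)
from switchscope.system import Trajectory

from .conftest import make_structure
from .oracles import mc_sasa


class TestMMInteraction:
    def test_unit_charges_give_exact_coulomb(self):
        s = make_structure(2, charges=[1.0, 1.0])
        frame = np.array([[0.0, 0, 0], [3.320637, 0, 0]])
        elec, _ = mm_interaction_energy(frame, s, [0], [1])
        assert elec == pytest.approx(100.0, abs=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        s = make_structure(2, rmin2=[1.5, 1.5], epsilon=[0.25, 0.25])
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        _, vdw = mm_interaction_energy(frame, s, [0], [1])
        assert vdw == pytest.approx(-0.25, abs=1e-12)

    def test_neutral_distant_atoms_vanish(self):
        s = make_structure(2)
        frame = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        elec, vdw = mm_interaction_energy(frame, s, [0], [1])
        assert elec == 0.0
        assert vdw == pytest.approx(0.0, abs=1e-3)
        assert vdw < 0  # attractive tail

    def test_overlapping_atoms_named(self):
        s = make_structure(2)
        frame = np.zeros((2, 3))
        with pytest.raises(EnergeticsError, match="0 and 1"):
            mm_interaction_energy(frame, s, [0], [1])

    def test_disjoint_groups_required(self):
        s = make_structure(3)
        with pytest.raises(EnergeticsError, match="disjoint"):
            mm_interaction_energy(np.eye(3), s, [0, 1], [1, 2])

    def test_bonded_pairs_excluded(self):
        """A covalent cross-link pair contributes no nonbonded clash."""
        s = make_structure(2, charges=[1.0, 1.0], bonds=[(0, 1)])
        frame = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        elec, vdw = mm_interaction_energy(frame, s, [0], [1])
        assert elec == 0.0 and vdw == 0.0

    def test_covalent_strain_energy(self):
        s = make_structure(2, bonds=[(0, 1)])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert covalent_energy(frame, s, [0], [1], k_bond=100.0,
                               r0={(0, 1): 1.5}) == pytest.approx(25.0)
        # no shared bonds -> zero
        s2 = make_structure(2)
        assert covalent_energy(frame, s2, [0], [1]) == 0.0


class TestSolvation:
    def test_born_ion_closed_form(self):
        e = gb_polar_energy(np.zeros((1, 3)), [1.0], [1.5])
        expected = -GB_PREFACTOR * (1 - 1 / EPS_SOLVENT) / 1.5
        assert e == pytest.approx(expected, abs=1e-9)
        assert e == pytest.approx(-109.28, abs=0.01)

    def test_gb_reaches_born_limit_at_large_separation(self):
        """f_GB -> r, so GB = self terms + screened cross Coulomb."""
        r = 1e6
        e = gb_polar_energy(np.array([[0.0, 0, 0], [r, 0, 0]]), [1.0, 1.0], [1.5, 1.5])
        self_terms = 2 * gb_polar_energy(np.zeros((1, 3)), [1.0], [1.5])
        cross = -2 * GB_PREFACTOR * (1 - 1 / EPS_SOLVENT) / r
        assert abs(e - (self_terms + cross)) < 1e-6

    def test_nonpositive_born_radius_rejected(self):
        with pytest.raises(EnergeticsError, match="Born"):
            gb_polar_energy(np.zeros((1, 3)), [1.0], [0.0])

    def test_isolated_sphere_sasa(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), [1.6], probe=1.4, n_points=960)
        assert sasa[0] == pytest.approx(4 * np.pi * 3.0**2, abs=1e-9)

    def test_buried_atom_has_zero_sasa(self):
        # central atom caged by 14 overlapping large neighbors
        shell = []
        for d in (-2.0, 2.0):
            shell += [[d, 0, 0], [0, d, 0], [0, 0, d]]
        for sx in (-1.6, 1.6):
            for sy in (-1.6, 1.6):
                for sz in (-1.6, 1.6):
                    shell.append([sx, sy, sz])
        coords = np.vstack([[0.0, 0, 0], shell])
        radii = np.full(len(coords), 2.0)
        sasa = shrake_rupley_sasa(coords, radii, probe=1.4, n_points=960)
        assert sasa[0] == 0.0

    def test_matches_monte_carlo_oracle_on_random_clusters(self):
        rng = np.random.default_rng(12)
        for trial in range(3):
            coords = rng.uniform(-2, 2, size=(5, 3))
            radii = rng.uniform(1.2, 2.0, size=5)
            fast = shrake_rupley_sasa(coords, radii, n_points=10000).sum()
            slow = mc_sasa(coords, radii, n_samples=40000, seed=trial)
            assert fast == pytest.approx(slow, rel=0.005)

    def test_solvation_energy_composes_terms(self):
        s = make_structure(1, charges=[1.0], rmin2=[1.6], born=[1.5])
        polar, nonpolar, sasa = solvation_energy(np.zeros((1, 3)), s, [0])
        assert polar == pytest.approx(-109.28, abs=0.01)
        assert sasa == pytest.approx(113.097, abs=0.5)
        assert nonpolar == pytest.approx(0.0072 * sasa)


class TestEntropy:
    def test_single_mode_closed_form(self):
        """A mode with h nu / kT = 1 has S = R(1/(e-1) - ln(1-1/e))."""
        t = 300.0
        nu = KB_J * t / H_PLANCK
        s = harmonic_entropy(np.array([nu]), t)
        expected = R_KCAL * (1 / (np.e - 1) - np.log(1 - np.exp(-1)))
        assert s == pytest.approx(expected, rel=1e-12)
        assert s * 1000 == pytest.approx(2.068, abs=0.001)

    def test_free_rigid_body_has_six_zero_modes_and_zero_entropy(self):
        s = make_structure(4)
        coords = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        model = ElasticNetworkModel(coords, cutoff=10.0, k=1.0)
        assert vibrational_entropy(s, model, coords, T=310.0) > 0  # 6 vib modes remain
        # a single atom has only rigid modes -> zero entropy
        s1 = make_structure(1)
        m1 = ElasticNetworkModel(np.zeros((1, 3)), cutoff=10.0)
        assert vibrational_entropy(s1, m1, np.zeros((1, 3)), T=310.0) == 0.0

    def test_diatomic_frequency_matches_reduced_mass_formula(self):
        k, r0, mass = 100.0, 1.5, 12.011

        class Spring:
            def energy(self, x):
                x = np.asarray(x).reshape(2, 3)
                return 0.5 * k * (np.linalg.norm(x[0] - x[1]) - r0) ** 2

        coords = np.array([[0.0, 0, 0], [r0, 0, 0]])
        hess = numerical_hessian(Spring().energy, coords)
        mw = hess / mass
        evals = np.linalg.eigvalsh(mw)
        vib = evals[np.abs(evals) > 1e-6 * np.abs(evals).max()]
        assert len(vib) == 1
        nu = np.sqrt(vib[0] * OMEGA2_PER_EIGVAL) / (2 * np.pi)
        mu = mass / 2
        nu_expected = np.sqrt(k / mu * OMEGA2_PER_EIGVAL) / (2 * np.pi)
        assert nu == pytest.approx(nu_expected, rel=1e-3)

    def test_analytic_enm_hessian_matches_numerical(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-2, 2, (5, 3))
        model = ElasticNetworkModel(coords, cutoff=10.0, k=2.0)
        num = numerical_hessian(model.energy, coords)
        assert np.allclose(model.hessian(), num, atol=1e-4)

    def test_binding_entropy_penalty_is_positive(self, toy_structure, toy_run):
        traj, _ = toy_run
        receptor = np.flatnonzero(toy_structure.roles != "ligand")
        ligand = toy_structure.atoms_by_role("ligand")
        val = nma_entropy(toy_structure, traj.coords[0], receptor, ligand)
        assert val > 0  # binding restricts motion


class TestMmgbsa:
    def test_noninteracting_limit(self):
        s = make_structure(4, charges=[0.3, -0.3, 0.2, -0.2],
                           roles=["protein", "protein", "ligand", "ligand"])
        frame = np.array([[0.0, 0, 0], [3, 0, 0], [100.0, 0, 0], [103.0, 0, 0]])
        traj = Trajectory(frame[None])
        rep = mmgbsa_binding(traj, s, [0, 1], [2, 3], stride=1)
        assert abs(rep.e_elec) < 1e-3
        assert abs(rep.e_vdw) < 1e-6
        assert abs(rep.g_solv) < 0.1  # small GB/SASA closure remnant

    def test_one_frame_recomposes_from_suboperations(self, toy_structure, toy_run):
        traj, _ = toy_run
        one = Trajectory(traj.coords[:1])
        receptor = np.flatnonzero(toy_structure.roles != "ligand")
        ligand = toy_structure.atoms_by_role("ligand")
        rep = mmgbsa_binding(one, toy_structure, receptor, ligand, stride=1)
        elec, vdw = mm_interaction_energy(one.coords[0], toy_structure, receptor, ligand)
        assert rep.e_elec == pytest.approx(elec, abs=1e-9)
        assert rep.e_vdw == pytest.approx(vdw, abs=1e-9)
        both = np.concatenate([receptor, ligand])
        pol = {}
        for name, grp in (("c", both), ("r", receptor), ("l", ligand)):
            p, npol, _ = solvation_energy(one.coords[0], toy_structure, grp, n_points=480)
            pol[name] = (p, npol)
        dsolv = sum(pol["c"]) - sum(pol["r"]) - sum(pol["l"])
        assert rep.g_solv == pytest.approx(dsolv, abs=1e-9)

    def test_report_invariants_hold_by_construction(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            vals = rng.normal(size=5) * 50
            rep = EnergyReport(
                e_elec=vals[0], e_vdw=vals[1], e_covalent=vals[2],
                g_solv=vals[3] + vals[4], g_solv_polar=vals[3],
                g_solv_nonpolar=vals[4], minus_t_ds=rng.normal() * 10,
            )
            assert rep.e_bind == pytest.approx(
                rep.e_elec + rep.e_vdw + rep.e_covalent + rep.g_solv, abs=1e-6
            )
            assert rep.g_cal == pytest.approx(rep.e_bind + rep.minus_t_ds, abs=1e-6)

    def test_terms_independent_of_frame_order(self, toy_structure, toy_run):
        traj, _ = toy_run
        receptor = np.flatnonzero(toy_structure.roles != "ligand")
        ligand = toy_structure.atoms_by_role("ligand")
        sub = Trajectory(traj.coords[:6])
        rev = Trajectory(traj.coords[:6][::-1].copy())
        a = mmgbsa_binding(sub, toy_structure, receptor, ligand, stride=1, sasa_points=240)
        b = mmgbsa_binding(rev, toy_structure, receptor, ligand, stride=1, sasa_points=240)
        assert a.e_elec == pytest.approx(b.e_elec, abs=1e-9)
        assert a.e_vdw == pytest.approx(b.e_vdw, abs=1e-9)
        assert a.g_solv == pytest.approx(b.g_solv, abs=1e-9)

    def test_zero_frames_rejected(self, toy_structure, toy_run):
        traj, _ = toy_run
        receptor = np.flatnonzero(toy_structure.roles != "ligand")
        ligand = toy_structure.atoms_by_role("ligand")
        with pytest.raises(EnergeticsError, match="stride"):
            mmgbsa_binding(Trajectory(traj.coords[:1]), toy_structure,
                           receptor, ligand, stride=0)


class TestDecomposition:
    def _system(self):
        # 3 protein residues + 2-atom ligand; only residue 2 is charged
        s = make_structure(
            5,
            charges=[0.0, 1.0, 0.0, -1.0, 0.0],
            roles=["protein"] * 3 + ["ligand"] * 2,
        )
        frame = np.array(
            [[0.0, 8, 0], [0, 0, 0], [0, -8, 0], [4.0, 0, 0], [7.0, 0, 0]]
        )
        return s, Trajectory(frame[None])

    def test_charged_residue_dominates_electrostatics(self):
        s, traj = self._system()
        dec = per_residue_decomposition(traj, s, [3, 4], sasa_points=240)
        elec = dec["elec"].abs()
        assert elec.loc[2] / elec.sum() >= 0.99

    def test_residue_totals_close_on_cross_terms(self, toy_structure, toy_run):
        traj, _ = toy_run
        one = Trajectory(traj.coords[:1])
        ligand = toy_structure.atoms_by_role("ligand")
        dec = per_residue_decomposition(one, toy_structure, ligand, sasa_points=240)
        protein = np.flatnonzero(toy_structure.roles == "protein")
        elec, vdw = mm_interaction_energy(one.coords[0], toy_structure, protein, ligand)
        assert dec["elec"].sum() == pytest.approx(elec, abs=1e-6)
        assert dec["vdW"].sum() == pytest.approx(vdw, abs=1e-6)
        assert dec["total"].sum() == pytest.approx(
            dec[["vdW", "elec", "polar", "nonpolar"]].values.sum(), abs=1e-6
        )

    def test_planted_mutation_only_moves_its_own_residue(self):
        s, traj = self._system()
        base = per_residue_decomposition(traj, s, [3, 4], sasa_points=240)
        s.charges[0] += 0.5  # "mutation" on residue 1, geometry frozen
        mut = per_residue_decomposition(traj, s, [3, 4], sasa_points=240)
        diff = (mut["total"] - base["total"]).abs()
        assert diff.loc[1] > 1e-3
        assert diff.loc[2] < 1e-9 and diff.loc[3] < 1e-9


class TestAffinity:
    def test_ic50_conversion_reference_values(self):
        assert dg_from_ic50(1e9) == pytest.approx(0.0, abs=1e-9)
        assert dg_from_ic50(19.81, T=310.0) == pytest.approx(-10.91, abs=0.03)
        assert dg_from_ic50(1.01, T=310.0) == pytest.approx(-12.75, abs=0.02)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(EnergeticsError):
            dg_from_ic50(0.0)

    @staticmethod
    def _reports(table):
        out = {}
        for name, row in table.items():
            out[name] = EnergyReport(
                e_elec=row["dE_elec"], e_vdw=row["dE_vdW"],
                e_covalent=row["dE_covalent"], g_solv=row["dG_solv"],
                g_solv_polar=row["dG_solv"], g_solv_nonpolar=0.0,
                minus_t_ds=row["-TdS"],
            )
        return out

    def test_published_sotorasib_table_assembles(self):
        reports = self._reports(refdata.AMG510)
        ic50s = {k: v["IC50_nM"] for k, v in refdata.AMG510.items()}
        records = {r.system: r for r in assemble_affinity_table(reports, ic50s, "G12C")}
        # the reported ledger: dG_cal from the printed dE_bind + (-TdS)
        assert refdata.dg_cal(refdata.AMG510, "G12C") == pytest.approx(-31.43, abs=1e-9)
        assert records["G12C"].ddg_cal is None
        ddg = refdata.dg_cal(refdata.AMG510, "G12C-Y96D") - refdata.dg_cal(
            refdata.AMG510, "G12C"
        )
        assert ddg == pytest.approx(10.03, abs=1e-9)

    def test_published_adagrasib_table_assembles(self):
        assert refdata.dg_cal(refdata.MRTX849, "G12C") == pytest.approx(-38.81, abs=1e-9)
        ddg = refdata.dg_cal(refdata.MRTX849, "G12C-Y96D") - refdata.dg_cal(
            refdata.MRTX849, "G12C"
        )
        assert ddg == pytest.approx(10.63, abs=1e-9)

    def test_missing_ic50_rejected(self):
        reports = self._reports(refdata.AMG510)
        with pytest.raises(EnergeticsError, match="IC50"):
            assemble_affinity_table(reports, {}, "G12C")

    def test_all_zero_inputs_give_zero_records(self):
        rep = EnergyReport(0, 0, 0, 0, 0, 0, 0)
        records = assemble_affinity_table({"a": rep, "b": rep}, {"a": 1e9, "b": 1e9}, "a")
        for r in records:
            assert r.dg_cal == 0.0
            assert r.dg_exp == pytest.approx(0.0, abs=1e-9)


class TestRSquared:
    def test_perfect_line_is_one(self):
        x = np.array([1.0, 2, 3, 4])
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_published_correlations(self):
        """Squared Pearson of calculated vs experimental binding free
        energies reproduces the reported 0.70 / 0.95 to printed precision."""
        for table, expected in ((refdata.AMG510, 0.70), (refdata.MRTX849, 0.95)):
            cal = [refdata.dg_cal(table, s) for s in refdata.SYSTEMS]
            exp = [dg_from_ic50(table[s]["IC50_nM"]) for s in refdata.SYSTEMS]
            assert r_squared(cal, exp) == pytest.approx(expected, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EnergeticsError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(EnergeticsError):
            r_squared([1.0, 2.0], [1.0, 2.0])
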