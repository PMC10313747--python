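"""Pair energies, the SIE combiner, GB surrogate, and decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from siefel import (
    GateModelParams,
    SIECoefficients,
    SIEComponents,
    Trajectory,
    born_reaction_field,
    cavity_term,
    coulomb_energy,
    delta_sasa,
    intermolecular_terms,
    key_residues,
    lj_energy,
    make_toy_complex,
    per_residue_decomposition,
    reaction_field_binding,
    sie_combine,
    sie_from_trajectory,
    simulate_gate_trajectory,
)
from siefel.benchmarks import sie_benchmark_frame
from siefel.structure_io import AnalysisError
from toyutil import make_atom, topology_from_atoms


class TestLennardJones:
    def test_well_depth_at_rmin(self):
        assert lj_energy(1.9, 0.1, 1.7, 0.4, r=3.6) == pytest.approx(
            -np.sqrt(0.1 * 0.4))

    def test_zero_crossing(self):
        r0 = 3.6 / 2 ** (1 / 6)
        assert lj_energy(1.9, 0.1, 1.7, 0.4, r=r0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            ri, rj = rng.uniform(1.0, 2.2, 2)
            ei, ej = rng.uniform(0.01, 0.5, 2)
            r = rng.uniform(2.0, 8.0)
            rmin, eps = ri + rj, np.sqrt(ei * ej)
            expected = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            assert lj_energy(ri, ei, rj, ej, r) == pytest.approx(expected)

    def test_singularity(self):
        with pytest.raises(AnalysisError):
            lj_energy(1.9, 0.1, 1.7, 0.4, r=0.0)


class TestCoulomb:
    def test_closed_forms(self):
        assert coulomb_energy(1.0, 1.0, 3.320636, 1.0) == pytest.approx(100.0)
        assert coulomb_energy(0.0, 1.0, 2.0) == 0.0
        assert coulomb_energy(1.0, -1.0, 1.0) == pytest.approx(-332.0636)

    def test_singularity(self):
        with pytest.raises(AnalysisError):
            coulomb_energy(1.0, 1.0, 0.0)


def _pair_system(r, q1=0.3, q2=-0.2):
    atoms = [make_atom(1, (0, 0, 0), charge=q1, rmin_half=1.9, epsilon=0.11),
             make_atom(2, (r, 0, 0), res_seq=2, res_name="LIG",
                       charge=q2, rmin_half=1.7, epsilon=0.21)]
    return topology_from_atoms(atoms, ligand=(1,))


class TestIntermolecularTerms:
    def test_vanishes_at_large_separation(self):
        # net-neutral groups 500 A apart: dipole-dipole decay ~ 1/r^3
        atoms = [
            make_atom(1, (0, 0, 0), charge=0.3),
            make_atom(2, (1.5, 0, 0), res_seq=2, charge=-0.3),
            make_atom(3, (500, 0, 0), res_seq=3, res_name="LIG", charge=0.2),
            make_atom(4, (501.5, 0, 0), res_seq=3, res_name="LIG", charge=-0.2),
        ]
        top = topology_from_atoms(atoms, ligand=(2, 3))
        e_vdw, e_ele = intermolecular_terms(top.coords(), top)
        assert abs(e_vdw) < 1e-3
        assert abs(e_ele) < 1e-3

    def test_single_pair_reduces_to_scalar_ops(self):
        top = _pair_system(3.1)
        e_vdw, e_ele = intermolecular_terms(top.coords(), top)
        assert e_vdw == pytest.approx(lj_energy(1.9, 0.11, 1.7, 0.21, 3.1))
        assert e_ele == pytest.approx(coulomb_energy(0.3, -0.2, 3.1))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        n_rec, n_lig = 10, 5
        coords = rng.uniform(0, 10, size=(n_rec + n_lig, 3))
        charges = rng.uniform(-0.5, 0.5, n_rec + n_lig)
        atoms = [make_atom(i + 1, coords[i], res_seq=i + 1, charge=charges[i],
                           rmin_half=1.8, epsilon=0.15)
                 for i in range(n_rec + n_lig)]
        top = topology_from_atoms(atoms, ligand=tuple(range(n_rec, n_rec + n_lig)))
        e_vdw, e_ele = intermolecular_terms(coords, top)
        exp_vdw = exp_ele = 0.0
        for i in range(n_rec):
            for j in range(n_rec, n_rec + n_lig):
                r = float(np.linalg.norm(coords[i] - coords[j]))
                exp_vdw += lj_energy(1.8, 0.15, 1.8, 0.15, r)
                exp_ele += coulomb_energy(charges[i], charges[j], r)
        assert e_vdw == pytest.approx(exp_vdw, rel=1e-12)
        assert e_ele == pytest.approx(exp_ele, rel=1e-12)


class TestGeneralizedBorn:
    def test_single_ion_born_formula(self):
        val = born_reaction_field([1.0], [2.0], [[0, 0, 0]],
                                  eps_in=1.0, eps_out=78.5)
        expected = -166.0318 * (1 - 1 / 78.5) / 2.0
        assert val == pytest.approx(expected, abs=1e-6)

    def test_zero_charges(self):
        rng = np.random.default_rng(0)
        val = born_reaction_field(np.zeros(5), np.full(5, 1.5),
                                  rng.uniform(0, 8, (5, 3)))
        assert val == 0.0

    def test_two_charge_still_oracle(self):
        q = np.array([0.4, -0.7])
        a = np.array([1.6, 2.1])
        pos = np.array([[0.0, 0, 0], [3.3, 0, 0]])
        tau = 1 / 2.25 - 1 / 78.5
        r2 = 3.3 ** 2
        fgb = np.sqrt(r2 + a[0] * a[1] * np.exp(-r2 / (4 * a[0] * a[1])))
        expected = -166.0318 * tau * (q[0] ** 2 / a[0] + q[1] ** 2 / a[1]
                                      + 2 * q[0] * q[1] / fgb)
        assert born_reaction_field(q, a, pos) == pytest.approx(expected, rel=1e-12)

    def test_charge_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(-0.5, 0.5, 6)
        a = rng.uniform(1.2, 2.2, 6)
        pos = rng.uniform(0, 9, (6, 3))
        assert born_reaction_field(q, a, pos) == pytest.approx(
            born_reaction_field(-q, a, pos), rel=1e-12)

    def test_binding_term_equals_complex_minus_parts(self, toy):
        """Cross-term route agrees with three full GB evaluations."""
        top = toy.topology
        rec = top.group_indices("receptor")
        lig = top.group_indices("ligand")
        X = top.coords()
        q, a = top.charges, top.born_radii
        g_all = born_reaction_field(q, a, X)
        g_rec = born_reaction_field(q[rec], a[rec], X[rec])
        g_lig = born_reaction_field(q[lig], a[lig], X[lig])
        direct = reaction_field_binding(X, top)
        assert direct == pytest.approx(g_all - g_rec - g_lig, abs=1e-8)

    def test_invalid_dielectrics(self):
        with pytest.raises(AnalysisError):
            born_reaction_field([1.0], [2.0], [[0, 0, 0]],
                                eps_in=80.0, eps_out=78.5)


class TestCavityTerm:
    def test_closed_forms(self):
        assert cavity_term(-1000.0, 0.013) == pytest.approx(-13.0)
        assert cavity_term(0.0) == 0.0

    def test_burial_gives_negative_cavity(self, toy):
        dsa = delta_sasa(toy.topology.coords(), toy.topology)
        assert dsa < 0
        assert cavity_term(dsa) < 0


class TestSIECombine:
    def test_published_component_rows(self):
        """Worked examples: component means recombine to the reported totals."""
        df = sie_benchmark_frame()
        dmpc1 = df[(df.ligand == "dmpc") & (df.run == 1)].iloc[0]
        val = sie_combine(SIEComponents(dmpc1.e_vdw, dmpc1.e_ele,
                                        dmpc1.g_rf, dmpc1.cavity))
        assert val == pytest.approx(-9.505, abs=1e-9)
        assert val == pytest.approx(dmpc1.dg_reported, abs=0.03)
        atov1 = df[(df.ligand == "atovaquone") & (df.run == 1)].iloc[0]
        val = sie_combine(SIEComponents(atov1.e_vdw, atov1.e_ele,
                                        atov1.g_rf, atov1.cavity))
        assert val == pytest.approx(-5.89, abs=0.01)

    def test_zero_components_return_constant(self):
        assert sie_combine(SIEComponents(0, 0, 0, 0)) == pytest.approx(-2.89)

    @given(scale=st.floats(0.1, 10.0),
           e=st.floats(-50, 50), g=st.floats(-50, 50))
    def test_affine_in_components(self, scale, e, g):
        coeffs = SIECoefficients()
        base = sie_combine(SIEComponents(e, g, -g / 2, e / 3), coeffs)
        scaled = sie_combine(
            SIEComponents(scale * e, scale * g, -scale * g / 2, scale * e / 3),
            coeffs)
        assert scaled - coeffs.constant == pytest.approx(
            scale * (base - coeffs.constant), rel=1e-9, abs=1e-9)


@pytest.fixture(scope="module")
def short_traj():
    toy = make_toy_complex(n_residues=60, seed=41)
    traj = simulate_gate_trajectory(toy, GateModelParams(n_frames=60, seed=42))
    return toy, traj


class TestSIEFromTrajectory:
    def test_static_trajectory_zero_sd(self, toy):
        frames = np.repeat(toy.topology.coords()[None], 12, axis=0)
        traj = Trajectory(topology=toy.topology, frames=frames,
                          times=np.arange(12.0))
        res = sie_from_trajectory(traj, window=range(12), n_snapshots=5)
        assert res.sd == pytest.approx(0.0, abs=1e-9)
        assert res.per_snapshot["dg_bind"].nunique() == 1

    def test_mean_commutes_with_combine(self, short_traj):
        """Linearity: mean of per-snapshot dG equals dG of mean components."""
        _, traj = short_traj
        res = sie_from_trajectory(traj, window=range(40, 60), n_snapshots=5)
        df = res.per_snapshot
        combined = sie_combine(SIEComponents(
            df.e_vdw.mean(), df.e_ele.mean(), df.g_rf.mean(), df.cavity.mean()))
        assert res.mean == pytest.approx(combined, abs=1e-9)

    def test_window_too_short(self, short_traj):
        _, traj = short_traj
        with pytest.raises(AnalysisError):
            sie_from_trajectory(traj, window=range(0, 5), n_snapshots=100)

    def test_sd_propagates_component_noise(self):
        """Gaussian component noise maps to alpha * sigma_sum in the dG SD."""
        rng = np.random.default_rng(55)
        sig = np.array([2.0, 1.0, 1.5, 0.3])
        n = 20000
        comps = rng.normal(0, 1, size=(n, 4)) * sig
        dg = np.array([sie_combine(SIEComponents(*c)) for c in comps[:2000]])
        expected_sd = 0.105 * np.sqrt((sig ** 2).sum())
        assert dg.std(ddof=1) == pytest.approx(expected_sd, rel=0.10)


class TestDecomposition:
    def test_distant_ligand_near_zero(self, toy):
        coords = toy.topology.coords().copy()
        lig = toy.topology.group_indices("ligand")
        coords[lig] += np.array([200.0, 0, 0])
        traj = Trajectory(topology=toy.topology, frames=coords[None],
                          times=np.array([0.0]))
        df = per_residue_decomposition(traj, window=range(1), n_snapshots=1,
                                       include_solvation=False)
        assert (df["total"].abs() < 1e-3).all()

    def test_pairwise_sums_conserved(self, short_traj):
        """Residue-summed pair terms equal the intermolecular totals."""
        _, traj = short_traj
        window = range(50, 60)
        df = per_residue_decomposition(traj, window=window, n_snapshots=3,
                                       include_solvation=False)
        from siefel.energetics import _snapshot_indices
        snaps = _snapshot_indices(window, 3)
        exp_vdw = np.mean([intermolecular_terms(traj.frames[f], traj.topology)[0]
                           for f in snaps])
        exp_ele = np.mean([intermolecular_terms(traj.frames[f], traj.topology)[1]
                           for f in snaps])
        assert df["vdw_pair"].sum() == pytest.approx(exp_vdw, abs=1e-6)
        assert df["ele_pair"].sum() == pytest.approx(exp_ele, abs=1e-6)

    def test_charged_residue_dominates_electrostatics(self):
        atoms = [
            make_atom(1, (0, 0, 0), charge=1.0),
            make_atom(2, (0, 8, 0), res_seq=2, charge=0.0),
            make_atom(3, (0, 4, 0), res_seq=3, charge=0.0),
            make_atom(4, (3.2, 0, 0), res_seq=9, res_name="LIG", charge=-1.0),
        ]
        top = topology_from_atoms(atoms, ligand=(3,))
        traj = Trajectory(topology=top, frames=top.coords()[None],
                          times=np.array([0.0]))
        df = per_residue_decomposition(traj, window=range(1), n_snapshots=1,
                                       include_solvation=False)
        by_res = df.set_index("residue_seq")
        assert by_res.loc[1, "ele_term"] < -50.0
        assert abs(by_res.loc[2, "ele_term"]) < 1e-9
        # hand check: single charge pair at 3.2 A
        assert by_res.loc[1, "ele_pair"] == pytest.approx(
            coulomb_energy(1.0, -1.0, 3.2))


class TestKeyResidues:
    def _frame(self, totals):
        return pd.DataFrame({
            "residue_seq": range(1, len(totals) + 1),
            "residue_name": ["ALA"] * len(totals),
            "total": totals,
        })

    def test_threshold_selection_and_ordering(self):
        df = self._frame([-1.2, -0.8, -3.0])
        out = key_residues(df)
        assert out["total"].tolist() == [-3.0, -1.2]

    def test_exact_threshold_excluded(self):
        out = key_residues(self._frame([-1.0, -1.0000001]))
        assert out["total"].tolist() == [-1.0000001]

    def test_all_nonnegative_empty(self):
        assert key_residues(self._frame([0.0, 0.5, 2.0])).empty
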