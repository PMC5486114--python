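import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from nmrbind.corcema import (
    CorcemaConditions,
    SpinSystem,
    build_relaxation_matrix,
    cross_relaxation_rate,
    methyl_spectral_density,
    noe_r_factor,
    predict_std,
    spectral_density,
)
from nmrbind.corcema.rates import auto_relaxation_rate
from nmrbind.corcema.simulate import assemble_exchange_system
from nmrbind.std_buildup import BuildupCurve, fit_buildup
from nmrbind.synthetic import gen_toy_complex

OMEGA_600 = 2.0 * math.pi * 600e6


class TestSpectralDensity:
    def test_zero_frequency(self):
        assert spectral_density(0.0, 22e-9) == 22e-9

    def test_omega_tau_unity(self):
        tau = 1e-9
        assert spectral_density(1.0 / tau, tau) == pytest.approx(tau / 2.0)

    def test_monotone_decreasing(self):
        omegas = np.linspace(0.0, 1e10, 50)
        vals = [spectral_density(w, 5e-9) for w in omegas]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            spectral_density(1.0, 0.0)


class TestCrossRelaxationRate:
    def test_zero_crossing_at_sqrt5_over_2(self):
        # sigma changes sign where 6 J(2w) = J(0), i.e. w*tau = sqrt(5)/2
        def sigma_of_tau(tau):
            return cross_relaxation_rate(2.5, tau, OMEGA_600)

        root = brentq(sigma_of_tau, 1e-11, 1e-8, xtol=1e-22, rtol=1e-15)
        assert root * OMEGA_600 == pytest.approx(math.sqrt(5.0) / 2.0, rel=1e-9)

    def test_sign_protein_regime(self):
        # long correlation time at 600 MHz: spin-diffusion limit, sigma < 0
        assert cross_relaxation_rate(2.5, 22e-9, OMEGA_600) < 0.0

    def test_sign_free_ligand_regime(self):
        # 0.4 ns sits just past the null (w*tau ~ 1.5): weakly negative
        s_04 = cross_relaxation_rate(2.5, 0.4e-9, OMEGA_600)
        assert s_04 < 0.0
        assert abs(s_04) < abs(cross_relaxation_rate(2.5, 22e-9, OMEGA_600)) / 50
        # genuinely fast tumbling is positive
        assert cross_relaxation_rate(2.5, 0.1e-9, OMEGA_600) > 0.0

    def test_unphysical_distance_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            cross_relaxation_rate(0.3, 1e-9, OMEGA_600)


class TestMethylSpectralDensity:
    def test_order_param_one_is_rigid(self):
        for w in (0.0, OMEGA_600):
            assert methyl_spectral_density(w, 22e-9, 10e-12, 1.0) == pytest.approx(
                spectral_density(w, 22e-9), rel=1e-12
            )

    def test_vanishing_internal_time_limit(self):
        j = methyl_spectral_density(0.0, 22e-9, 1e-16, 0.25)
        assert j == pytest.approx(0.25 * 22e-9, rel=1e-6)

    def test_arithmetic_example(self):
        tau_e = 1.0 / (1.0 / 22e-9 + 1.0 / 10e-12)
        expected = 0.25 * 22e-9 + 0.75 * tau_e
        got = methyl_spectral_density(0.0, 22e-9, 10e-12, 0.25)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.5075e-9, rel=1e-3)

    def test_internal_slower_than_overall_rejected(self):
        with pytest.raises(ValueError):
            methyl_spectral_density(0.0, 1e-9, 2e-9, 0.25)


class TestBuildRelaxationMatrix:
    def test_two_proton_matrix(self, toy_conditions):
        sys2 = SpinSystem(
            labels=["L1", "P1"],
            owners=["ligand", "protein"],
            coords_bound=np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]]),
        )
        R, idx = build_relaxation_matrix(sys2, "bound", toy_conditions)
        assert R.shape == (2, 2)
        assert R[0, 1] == pytest.approx(R[1, 0], rel=1e-15)
        tau = toy_conditions.tau_c_bound_ns * 1e-9
        assert R[0, 1] == pytest.approx(
            cross_relaxation_rate(2.5, tau, toy_conditions.omega0), rel=1e-12
        )
        assert R[0, 0] == pytest.approx(
            auto_relaxation_rate(2.5, tau, toy_conditions.omega0), rel=1e-12
        )

    def test_r6_distance_scaling(self, toy_conditions, four_spin_system):
        R1, _ = build_relaxation_matrix(four_spin_system, "bound", toy_conditions)
        doubled = SpinSystem(
            labels=four_spin_system.labels,
            owners=four_spin_system.owners,
            coords_bound=2.0 * four_spin_system.coords_bound,
            saturated=four_spin_system.saturated,
        )
        R2, _ = build_relaxation_matrix(doubled, "bound", toy_conditions)
        assert np.allclose(R2, R1 / 64.0, rtol=1e-12)

    def test_three_spin_chain_hand_computed(self):
        # independent scalar recomputation, constants from scratch
        gamma, hbar, mu4pi = 2.6752218744e8, 1.054571817e-34, 1e-7
        q = 0.1 * gamma**4 * hbar**2 * mu4pi**2
        tau, w0 = 5e-9, OMEGA_600

        def jj(w):
            return tau / (1 + (w * tau) ** 2)

        def sig(r_m):
            return q / r_m**6 * (6 * jj(2 * w0) - jj(0))

        def rho(r_m):
            return q / r_m**6 * (jj(0) + 3 * jj(w0) + 6 * jj(2 * w0))

        conds = CorcemaConditions(tau_c_bound_ns=5.0)
        chain = SpinSystem(
            labels=["L1", "L2", "P1"],
            owners=["ligand", "ligand", "protein"],
            coords_bound=np.array(
                [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [4.0, 0.0, 0.0]]
            ),
        )
        R, _ = build_relaxation_matrix(chain, "bound", conds)
        assert R[0, 1] == pytest.approx(sig(2.0e-10), rel=1e-10)
        assert R[0, 2] == pytest.approx(sig(4.0e-10), rel=1e-10)
        assert R[1, 2] == pytest.approx(sig(2.0e-10), rel=1e-10)
        assert R[0, 0] == pytest.approx(rho(2.0e-10) + rho(4.0e-10), rel=1e-10)
        assert R[1, 1] == pytest.approx(2 * rho(2.0e-10), rel=1e-10)

    def test_cutoff_excludes_remote_protein_protons(self, toy_conditions):
        sys3 = SpinSystem(
            labels=["L1", "L2", "Pnear", "Pfar"],
            owners=["ligand", "ligand", "protein", "protein"],
            coords_bound=np.array(
                [[0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 50.0, 0]]
            ),
        )
        R, idx = build_relaxation_matrix(sys3, "bound", toy_conditions)
        assert R.shape == (3, 3)
        assert list(idx) == [0, 1, 2]

    def test_no_neighbors_error(self, toy_conditions):
        lonely = SpinSystem(
            labels=["L1", "L2", "P1"],
            owners=["ligand", "ligand", "protein"],
            coords_bound=np.array([[0, 0, 0], [2, 0, 0], [0, 100.0, 0]]),
        )
        with pytest.raises(ValueError, match="no protein protons within"):
            build_relaxation_matrix(lonely, "bound", toy_conditions)

    def test_unknown_state(self, toy_conditions, four_spin_system):
        with pytest.raises(ValueError, match="unknown state"):
            build_relaxation_matrix(four_spin_system, "complexed", toy_conditions)

    def test_relaxation_eigenvalues_positive_real(self, toy_conditions):
        for seed in range(10):
            system = gen_toy_complex(3, 3, seed=seed)
            R, _ = build_relaxation_matrix(system, "bound", toy_conditions)
            assert np.all(np.linalg.eigvals(R).real > 0)


class TestAssembleExchange:
    def test_exchange_block_conserves_magnetization(self, four_spin_system):
        # difference of two assemblies that differ only in kon isolates the
        # kinetic block, whose columns must each sum to zero
        c1 = CorcemaConditions(kon_per_M_s=1e8)
        c2 = CorcemaConditions(kon_per_M_s=3e8)
        D1 = assemble_exchange_system(four_spin_system, c1)["D"]
        D2 = assemble_exchange_system(four_spin_system, c2)["D"]
        K_diff = D1 - D2
        assert np.allclose(K_diff.sum(axis=0), 0.0, atol=1e-9)

    def test_equilibrium_pools(self, four_spin_system, toy_conditions):
        sysd = assemble_exchange_system(four_spin_system, toy_conditions)
        kin = sysd["kinetics"]
        m = sysd["m_eq"]
        assert m[0] == pytest.approx(kin.free_ligand_M)
        assert m[2] == pytest.approx(kin.complex_conc_M)
        assert kin.free_ligand_M + kin.complex_conc_M == pytest.approx(1.5e-3)


class TestPredictStd:
    TSAT = np.array([0.5, 1.0, 2.0, 3.0, 4.0])

    def test_empty_saturated_set_gives_zero(self, toy_conditions, four_spin_system):
        unsat = four_spin_system.saturate([])
        res = predict_std(unsat, toy_conditions, self.TSAT)
        assert np.all(res.std_fractions == 0.0)

    def test_no_binding_gives_zero(self, four_spin_system):
        conds = CorcemaConditions(kd_uM=1e12)
        res = predict_std(four_spin_system, conds, self.TSAT)
        assert np.all(np.abs(res.std_fractions) < 1e-9)

    def test_ode_oracle(self, toy_conditions, four_spin_system):
        res = predict_std(four_spin_system, toy_conditions, self.TSAT, method="eig")

        sysd = assemble_exchange_system(four_spin_system, toy_conditions)
        D, m_eq, clamped = sysd["D"], sysd["m_eq"], sysd["clamped"]
        n_lig = sysd["n_ligand"]
        free_ix = np.flatnonzero(~clamped)
        sat_ix = np.flatnonzero(clamped)
        D_ff = D[np.ix_(free_ix, free_ix)]
        D_fs = D[np.ix_(free_ix, sat_ix)]
        drive = D_fs @ m_eq[sat_ix]

        def rhs(_t, y):
            return -D_ff @ y + drive

        sol = solve_ivp(
            rhs,
            (0.0, float(self.TSAT[-1])),
            np.zeros(free_ix.size),
            t_eval=self.TSAT,
            rtol=1e-11,
            atol=1e-16,
            method="LSODA",
        )
        assert sol.success
        l_total = m_eq[0] + m_eq[n_lig]
        for k in range(self.TSAT.size):
            full = np.zeros(D.shape[0])
            full[free_ix] = sol.y[:, k]
            std = -(full[:n_lig] + full[n_lig : 2 * n_lig]) / l_total
            assert np.allclose(res.std_fractions[:, k], std, atol=1e-8)

    def test_method_independence(self, toy_conditions, four_spin_system):
        r_eig = predict_std(four_spin_system, toy_conditions, self.TSAT, method="eig")
        r_expm = predict_std(four_spin_system, toy_conditions, self.TSAT, method="expm")
        assert np.allclose(r_eig.std_fractions, r_expm.std_fractions, atol=1e-8)

    def test_buildup_monotone_and_fittable(self, toy_conditions):
        system = gen_toy_complex(2, 3, seed=5)
        times = np.concatenate([np.linspace(0.25, 20.0, 40), [2000.0, 4000.0]])
        res = predict_std(system, toy_conditions, times)
        for row in res.std_fractions:
            assert np.all(np.diff(row) > -1e-12)  # monotone non-decreasing
            # asymptote: the curve has flattened out at long saturation times
            assert row[-1] - row[-2] < 1e-3 * row[-1]
        # cross-module consistency: the 0.5-4 s window fits the
        # mono-exponential build-up model with well-conditioned parameters
        res5 = predict_std(system, toy_conditions, self.TSAT)
        row = res5.std_fractions[0]
        scale = row.max()
        curve = BuildupCurve("L1", "toy", self.TSAT, row / (scale * 1.05))
        fit = fit_buildup(curve)
        assert fit.std_max > 0 and fit.k_sat > 0
        assert np.isfinite(fit.std0)

    def test_relabel_symmetry(self):
        # mirror-symmetric 4 spins, stoichiometric binding (no free pool):
        # swapping ligand/protein roles must leave the observed STD unchanged
        coords = np.array(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.8, 0.0], [2.0, 2.8, 0.0]]
        )
        conds = CorcemaConditions(p0_uM=30.0, l0_mM=30.0e-3, kd_uM=0.0)

        def build(owners, sat):
            return SpinSystem(
                labels=["A", "B", "C", "D"],
                owners=owners,
                coords_bound=coords,
                saturated=np.array(sat),
            )

        sys_a = build(["ligand", "ligand", "protein", "protein"],
                      [False, False, True, True])
        sys_b = build(["protein", "protein", "ligand", "ligand"],
                      [True, True, False, False])
        res_a = predict_std(sys_a, conds, self.TSAT)
        res_b = predict_std(sys_b, conds, self.TSAT)
        assert np.allclose(res_a.std_fractions, res_b.std_fractions, atol=1e-12)

    def test_result_frame(self, toy_conditions, four_spin_system):
        res = predict_std(four_spin_system, toy_conditions, self.TSAT)
        frame = res.to_frame()
        assert list(frame.index) == ["L1", "L2"]
        assert frame.shape == (2, 5)
        assert np.all(np.abs(frame.to_numpy()) <= 1.0)


class TestNoeRFactor:
    def test_perfect_agreement(self):
        assert noe_r_factor([0.1, 0.2], [0.1, 0.2]) == 0.0

    def test_zero_prediction(self):
        assert noe_r_factor([0.0, 0.0], [0.1, 0.2]) == pytest.approx(1.0)

    def test_hand_example(self):
        r = noe_r_factor([0.12, 0.18], [0.1, 0.2])
        assert r == pytest.approx(math.sqrt(0.0008 / 0.05), rel=1e-12)
        assert r == pytest.approx(0.1265, abs=1e-4)

    def test_all_zero_experimental_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            noe_r_factor([0.1], [0.0])


class TestSpinSystemIO:
    def test_json_round_trip(self, tmp_path, four_spin_system):
        path = tmp_path / "sys.json"
        four_spin_system.to_json(path)
        back = SpinSystem.from_json(path)
        assert back.labels == four_spin_system.labels
        assert back.owners == four_spin_system.owners
        assert np.allclose(back.coords_bound, four_spin_system.coords_bound)
        assert np.array_equal(back.saturated, four_spin_system.saturated)

    def test_saturate_selector(self, four_spin_system):
        sel = four_spin_system.saturate(["P1"])
        assert list(sel.saturated) == [False, False, True, False]
        with pytest.raises(ValueError, match="unknown proton"):
            four_spin_system.saturate(["Q9"])

    def test_saturated_must_be_protein(self):
        with pytest.raises(ValueError, match="subset of protein"):
            SpinSystem(
                labels=["L1", "P1"],
                owners=["ligand", "protein"],
                coords_bound=np.zeros((2, 3)),
                saturated=np.array([True, False]),
            )


PDB_WITH_H = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  HB1 ALA A   1       1.650   1.950   0.880  1.00  0.00           H
ATOM      5  HB2 ALA A   1       1.650   1.950  -0.880  1.00  0.00           H
ATOM      6  HB3 ALA A   1       3.090   1.420   0.000  1.00  0.00           H
HETATM    7  C1  LIG A   2       4.500   1.500   0.000  1.00  0.00           C
HETATM    8  H1  LIG A   2       5.100   2.300   0.400  1.00  0.00           H
HETATM    9  H2  LIG A   2       5.100   0.700  -0.400  1.00  0.00           H
END
"""

PDB_NO_H = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
HETATM    3  C1  LIG A   2       4.500   1.500   0.000  1.00  0.00           C
END
"""


class TestFromPdb:
    def test_reads_protons_and_methyls(self, tmp_path):
        path = tmp_path / "complex.pdb"
        path.write_text(PDB_WITH_H)
        system = SpinSystem.from_pdb(path)
        assert system.n_protons == 5
        assert system.owners.count("ligand") == 2
        # the three ALA HB protons form one saturated methyl group
        methyl = system.methyl_ids[system.methyl_ids >= 0]
        assert len(methyl) == 3 and len(set(methyl)) == 1
        assert int(system.saturated.sum()) == 3

    def test_no_hydrogens_rejected(self, tmp_path):
        path = tmp_path / "bare.pdb"
        path.write_text(PDB_NO_H)
        with pytest.raises(ValueError, match="no explicit hydrogens"):
            SpinSystem.from_pdb(path)
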