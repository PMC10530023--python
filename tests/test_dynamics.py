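"""Batch integration, serial transfers, and design-grid behaviour."""

import numpy as np
import pytest

from phagevolve import (ExperimentDesign, ModelParams, PopulationState,
                        TransferProtocol, Treatment, apply_transfer,
                        bundled_design, integrate_batch, run_design_grid,
                        run_protocol)
from phagevolve.errors import ConfigError, DomainError
from phagevolve.model import rhs


def logistic(t, S0, r, K):
    return K * S0 * np.exp(r * t) / (K + S0 * (np.exp(r * t) - 1.0))


class TestIntegrateBatch:
    def test_all_zero_state_is_absorbing(self, params):
        traj = integrate_batch(PopulationState(), params, 20.0)
        assert np.all(traj.y == 0.0)

    def test_matches_closed_form_logistic(self, params):
        # no phage, no mutation, no acquisition: pure logistic growth of S
        p = params.replace(mu=0.0, A=0.0)
        S0 = p.K / 100
        traj = integrate_batch(PopulationState(S=S0), p, 20.0, n_samples=5)
        for t_chk in (5.0, 10.0, 20.0):
            idx = np.argmin(np.abs(traj.t - t_chk))
            expected = logistic(traj.t[idx], S0, p.r, p.K)
            assert traj.y[idx, 0] == pytest.approx(expected, rel=1e-6)

    def test_solution_converged_in_tolerance(self, params):
        state0 = PopulationState(S=1e6, V=1e4)
        base = integrate_batch(state0, params, 20.0)
        tight = integrate_batch(state0, params, 20.0, rtol=1e-9, atol=1e-13)
        f0, f1 = base.y[-1], tight.y[-1]
        scale = np.maximum(np.abs(f1), 1.0)
        assert np.all(np.abs(f0 - f1) / scale < 1e-6)

    def test_invalid_duration(self, params):
        with pytest.raises(DomainError):
            integrate_batch(PopulationState(S=1.0), params, 0.0)


class TestTransfer:
    def test_identity_dilution(self, s4_state):
        protocol = TransferProtocol(dilution=1.0, phage_dilution=1.0)
        assert apply_transfer(s4_state, protocol) == s4_state

    def test_scalar_dilution(self):
        state = PopulationState(S=1e8, V=1e7)
        out = apply_transfer(state, TransferProtocol())
        assert out.S == pytest.approx(1e6) and out.V == pytest.approx(1e5)

    def test_frequencies_invariant_under_transfer(self, rng):
        from phagevolve import genotype_frequencies
        for _ in range(20):
            dens = rng.uniform(1.0, 1e8, size=5)
            state = PopulationState(S=dens[0], R=dens[1], C=dens[2],
                                    D=dens[3], V=dens[4])
            d = rng.uniform(0.001, 1.0)
            out = apply_transfer(state, TransferProtocol(dilution=d,
                                                         phage_dilution=d / 2))
            f0, f1 = genotype_frequencies(state), genotype_frequencies(out)
            assert np.allclose(f0.as_tuple(), f1.as_tuple(), rtol=1e-12)

    def test_invalid_protocol(self):
        with pytest.raises(ConfigError):
            TransferProtocol(dilution=0.0)


class TestRunProtocol:
    def test_single_transfer_reduces_to_batch(self, params, s4_state):
        single = run_protocol(s4_state, params, TransferProtocol(n_transfers=1))
        batch = integrate_batch(s4_state, params, 20.0)
        assert np.allclose(single.y[-1], batch.y[-1], rtol=1e-12)

    def test_phage_drops_hundredfold_at_boundaries(self, params, s4_state):
        traj = run_protocol(s4_state, params, TransferProtocol())
        assert len(traj.boundaries) == 2
        for b in traj.boundaries:
            assert traj.t[b] == traj.t[b - 1]  # duplicate-time boundary pair
            assert traj.y[b, 4] == pytest.approx(0.01 * traj.y[b - 1, 4], rel=1e-12)
            assert np.allclose(traj.y[b, :4], 0.01 * traj.y[b - 1, :4], rtol=1e-12)

    def test_final_frequencies_match_fixed_step_euler(self, params, s4_state):
        traj = run_protocol(s4_state, params, TransferProtocol())
        # independent fixed-step Euler re-implementation
        dt = 1e-3
        y = s4_state.to_array()
        for _ in range(3):
            for _ in range(int(20.0 / dt)):
                y = np.maximum(y + dt * rhs(0.0, y, params), 0.0)
            euler_final = y.copy()
            y = y * np.array([0.01] * 4 + [0.01])
        hosts = traj.y[-1, :4]
        f_solver = hosts / hosts.sum()
        f_euler = euler_final[:4] / euler_final[:4].sum()
        assert np.allclose(f_solver, f_euler, atol=1e-3)


class TestDesignGrid:
    def test_no_phage_means_no_crispr(self, params):
        tr = Treatment(label="v0_zero", V0=0.0, K=1e8, inoculum_fraction=0.01)
        res = run_design_grid(ExperimentDesign("null_dose", (tr,)), params)
        assert (res["f_C"] == 0.0).all() and (res["f_D"] == 0.0).all()

    def test_results_deterministic(self, params):
        design = bundled_design("inoculum_sweep")
        a = run_design_grid(design, params)
        b = run_design_grid(design, params)
        assert a.equals(b)

    def test_empty_design_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentDesign("empty", ())

    def test_double_resistance_stays_rare(self, params, s4_state):
        traj = run_protocol(s4_state, params, TransferProtocol())
        hosts = traj.y[:, :4]
        total = hosts.sum(axis=1)
        f_D = hosts[:, 3] / np.where(total > 0, total, 1.0)
        assert f_D.max() < 0.01

    def test_moi_matched_sweep_differs_only_through_dose(self, params):
        fixed = run_design_grid(bundled_design("inoculum_sweep"), params)
        moi = run_design_grid(bundled_design("inoculum_sweep_moi"), params)
        # same inocula; the only channel is V0, which matches at S0/K = 0.1
        assert np.allclose(sorted(fixed["inoculum_fraction"]),
                           sorted(moi["inoculum_fraction"]))
        top_fixed = fixed[fixed.inoculum_fraction == 0.1].iloc[0]
        top_moi = moi[moi.inoculum_fraction == 0.1].iloc[0]
        assert top_moi["V0"] == pytest.approx(top_fixed["V0"])
        assert top_moi["f_C"] == pytest.approx(top_fixed["f_C"], rel=1e-9)
        low_fixed = fixed[fixed.inoculum_fraction == 0.0001].iloc[0]
        low_moi = moi[moi.inoculum_fraction == 0.0001].iloc[0]
        assert low_moi["V0"] < low_fixed["V0"]
        assert not np.isclose(low_moi["f_C"], low_fixed["f_C"], rtol=1e-3)
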