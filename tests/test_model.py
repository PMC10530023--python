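"""Unit and property tests for the five-compartment model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagevolve import (ModelParams, PopulationState, derivatives,
                        genotype_growth_rates, integrate_batch)
from phagevolve.errors import ConfigError, DomainError


class TestParams:
    def test_default_parameter_profile(self, params):
        assert (params.r, params.m, params.m_v) == (1.0, 0.0, 0.0)
        assert (params.a, params.B) == (1e-8, 100.0)
        assert (params.c_R, params.tau) == (0.01, 0.01)
        assert (params.mu, params.A, params.L, params.K) == (1e-4, 5e-4, 1e-3, 1e8)
        assert params.mutation_model == "per_replication"

    @pytest.mark.parametrize("bad", [{"mu": -1.0}, {"K": 0.0}, {"B": 0.5},
                                     {"r": float("nan")},
                                     {"mutation_model": "per_generation"}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ConfigError):
            ModelParams(**bad)

    def test_negative_density_rejected(self):
        with pytest.raises(DomainError):
            PopulationState(S=-1.0)


class TestGrowthRates:
    def test_surface_cost_is_constitutive(self, params):
        for V in (0.0, 1e4, 1e9):
            r_S, r_R, r_C, r_D = genotype_growth_rates(params, V)
            assert r_R == pytest.approx(math.exp(-0.01), rel=1e-12)
            assert r_D == r_R
            assert r_S == 1.0

    def test_crispr_cost_is_induced_by_exposure(self, params):
        # tau*a*V = 0.01 * 1e-8 * 1e8 = 0.01: same realized cost as c_R
        _, r_R, r_C, _ = genotype_growth_rates(params, 1e8)
        assert r_C == pytest.approx(math.exp(-0.01), rel=1e-12)
        assert r_C == pytest.approx(r_R, rel=1e-12)
        # no toxicity without phage or without tau
        assert genotype_growth_rates(params, 0.0)[2] == params.r
        assert genotype_growth_rates(params.replace(tau=0.0), 1e9)[2] == params.r

    def test_cost_ordering_and_crossover(self, params):
        # V = 0: CRISPR free, surface resistance costly
        r_S, r_R, r_C, r_D = genotype_growth_rates(params, 0.0)
        assert r_C == r_S and r_R == r_D < r_S
        # a*V*tau > c_R: CRISPR toxicity exceeds the constitutive cost
        r_S, r_R, r_C, _ = genotype_growth_rates(params, 1e10)
        assert r_C < r_R

    def test_negative_phage_density_rejected(self, params):
        with pytest.raises(DomainError):
            genotype_growth_rates(params, -1.0)


class TestDerivatives:
    def test_logistic_equilibrium_without_mutation(self, params):
        p = params.replace(mu=0.0)
        state = PopulationState(S=p.K)
        dy, _ = derivatives(state, p)
        assert np.all(dy == 0.0)

    def test_no_spacer_uptake_without_phage(self, params):
        state = PopulationState(S=1e6, C=1e5, V=0.0)
        dy, br = derivatives(state, params)
        assert br.acquisition_S == 0.0
        g = 1.0 - state.N / params.K
        expected_dC = (params.r * g - params.mu * params.r * g - params.L) * state.C
        assert dy[2] == pytest.approx(expected_dC, rel=1e-12)

    def test_phage_sink(self, params):
        # CRISPR hosts adsorb phage without producing progeny
        state = PopulationState(S=0.0, C=1e6, V=1e5)
        dy, br = derivatives(state, params)
        assert br.phage_production == 0.0
        assert dy[4] == pytest.approx(-params.a * state.V * state.C, rel=1e-12)
        assert dy[4] < 0

    def test_derivative_matches_finite_difference_of_trajectory(self, params):
        state = PopulationState(S=1e6, V=1e4)
        h = 1e-4
        traj = integrate_batch(state, params, 2 * h, n_samples=3,
                               rtol=1e-11, atol=1e-14)
        # central difference is centred on the middle sample
        mid = PopulationState.from_array(traj.t[1], traj.y[1])
        dy, _ = derivatives(mid, params)
        fd = (traj.y[2] - traj.y[0]) / (2 * h)
        nonzero = dy != 0
        assert np.allclose(fd[nonzero], dy[nonzero], rtol=1e-6)

    def test_rescue_reduces_lysis_and_burst(self, params):
        state = PopulationState(S=1e6, V=1e6)
        _, plain = derivatives(state, params)
        _, rescued = derivatives(state, params.replace(rescue_on_acquisition=True))
        aVS = params.a * state.V * state.S
        assert plain.lysis == pytest.approx(aVS)
        assert rescued.lysis == pytest.approx((1 - params.A) * aVS)
        assert rescued.phage_production == pytest.approx(params.B * rescued.lysis)

    def test_acquisition_from_R_routes_to_double_resistance(self, params):
        state = PopulationState(S=1e5, R=1e6, V=1e6)
        _, br = derivatives(state, params.replace(acquisition_from_R=True))
        assert br.acquisition_R == pytest.approx(params.A * params.a * state.V * state.R)


densities = st.floats(min_value=0.0, max_value=1e8)


class TestBookkeeping:
    @given(S=densities, R=densities, C=densities, D=densities,
           V=st.floats(min_value=0.0, max_value=1e11),
           per_repl=st.booleans(), acq_R=st.booleans(), rescue=st.booleans())
    @settings(max_examples=150, deadline=None)
    def test_derivatives_equal_signed_flux_sums(self, S, R, C, D, V,
                                                per_repl, acq_R, rescue):
        p = ModelParams(
            K=1e9,  # keeps N <= K so all fluxes are nonnegative
            m=0.01, m_v=0.1,
            mutation_model="per_replication" if per_repl else "per_capita",
            acquisition_from_R=acq_R, rescue_on_acquisition=rescue)
        state = PopulationState(S=S, R=R, C=C, D=D, V=V)
        dy, br = derivatives(state, p)
        assert np.array_equal(dy, br.signed_sums())
        for name in ("growth_S", "growth_R", "growth_C", "growth_D", "lysis",
                     "acquisition_S", "acquisition_R", "mutation_S", "mutation_C",
                     "loss_C", "loss_D", "phage_production",
                     "phage_adsorption_S", "phage_adsorption_C", "phage_decay"):
            assert getattr(br, name) >= 0.0
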