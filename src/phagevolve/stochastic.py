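"""Finite-population, event-based counterpart of the deterministic model.

Events mirror the deterministic fluxes one-for-one: per-capita births
with logistic density dependence (surface mutation applied as a
per-birth probability under the default mutation model), mass-action
phage adsorption with instantaneous burst, spacer acquisition, CRISPR
loss, and background deaths.  Serial transfer is binomial thinning.

The exact (Gillespie) core is compiled with numba: at realistic
carrying capacities a single 20 h batch involves millions of events.
A tau-leaping approximation is provided for larger systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigError, DomainError
from .model import ModelParams, PopulationState

__all__ = ["StochasticRun", "simulate_stochastic", "simulate_protocol_stochastic"]


@dataclass
class StochasticRun:
    """One stochastic realisation, sampled on a time grid.

    ``counts`` are integer copy numbers (density x volume); ``n_events``
    totals executed reactions, ``n_rate_clips`` counts instants where the
    logistic factor overshot below zero and birth rates were clipped.
    """

    seed: int
    method: str
    volume: float
    t: np.ndarray
    counts: np.ndarray  # (n_times, 5) int64: S, R, C, D, V
    n_events: int
    n_rate_clips: int
    params: ModelParams = None

    def state(self, i: int) -> PopulationState:
        c = self.counts[i] / self.volume
        return PopulationState(t=float(self.t[i]), S=c[0], R=c[1], C=c[2],
                               D=c[3], V=c[4])

    @property
    def final_state(self) -> PopulationState:
        return self.state(len(self.t) - 1)


@njit(cache=True)
def _ssa_core(y0, t_grid, r, m, m_v, a, B, c_R, tau, mu, A, L, K,
              per_replication, acq_from_R, rescue, seed):  # pragma: no cover
    np.random.seed(seed)
    n_grid = t_grid.shape[0]
    out = np.zeros((n_grid, 5), dtype=np.int64)
    S, R, C, D, V = y0[0], y0[1], y0[2], y0[3], y0[4]
    t = 0.0
    idx = 0
    n_events = 0
    n_clips = 0
    er = math.exp(-c_R)
    while idx < n_grid:
        N = S + R + C + D
        g = 1.0 - N / K
        if g < 0.0:
            g = 0.0
            n_clips += 1
        rc = math.exp(-tau * a * V)
        b_s = r * g * S
        b_r = r * er * g * R
        b_c = r * rc * g * C
        b_d = r * er * g * D
        ads_s = a * V * S
        ads_c = a * V * C
        acq_s = 0.0 if rescue else A * a * V * S
        acq_r = A * a * V * R if acq_from_R else 0.0
        mut_s = 0.0 if per_replication else mu * S
        mut_c = 0.0 if per_replication else mu * C
        los_c = L * C
        los_d = L * D
        d_s = m * S
        d_r = m * R
        d_c = m * C
        d_d = m * D
        d_v = m_v * V
        total = (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                 + mut_s + mut_c + los_c + los_d + d_s + d_r + d_c + d_d + d_v)
        if total <= 0.0:
            while idx < n_grid:
                out[idx, 0], out[idx, 1], out[idx, 2] = S, R, C
                out[idx, 3], out[idx, 4] = D, V
                idx += 1
            break
        dt = -math.log(np.random.random()) / total
        while idx < n_grid and t + dt >= t_grid[idx]:
            out[idx, 0], out[idx, 1], out[idx, 2] = S, R, C
            out[idx, 3], out[idx, 4] = D, V
            idx += 1
        if idx >= n_grid:
            break
        t += dt
        u = np.random.random() * total
        n_events += 1
        if u < b_s:
            if (not per_replication) or np.random.random() >= mu:
                S += 1
            else:
                R += 1
        elif u < b_s + b_r:
            R += 1
        elif u < b_s + b_r + b_c:
            if (not per_replication) or np.random.random() >= mu:
                C += 1
            else:
                D += 1
        elif u < b_s + b_r + b_c + b_d:
            D += 1
        elif u < b_s + b_r + b_c + b_d + ads_s:
            if rescue and np.random.random() < A:
                S -= 1
                C += 1
                V -= 1
            else:
                S -= 1
                V += B - 1
        elif u < b_s + b_r + b_c + b_d + ads_s + ads_c:
            V -= 1
        elif u < b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s:
            S -= 1
            C += 1
        elif u < b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r:
            R -= 1
            D += 1
        elif u < b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r + mut_s:
            S -= 1
            R += 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c):
            C -= 1
            D += 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c):
            C -= 1
            S += 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c + los_d):
            D -= 1
            R += 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c + los_d + d_s):
            S -= 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c + los_d + d_s + d_r):
            R -= 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c + los_d + d_s + d_r + d_c):
            C -= 1
        elif u < (b_s + b_r + b_c + b_d + ads_s + ads_c + acq_s + acq_r
                  + mut_s + mut_c + los_c + los_d + d_s + d_r + d_c + d_d):
            D -= 1
        else:
            V -= 1
    return out, n_events, n_clips


# state-change vectors for the tau-leap channels, columns (S, R, C, D, V):
# birth_S, birth_S_mut, birth_R, birth_C, birth_C_mut, birth_D,
# lysis, rescue_acq, sink_C, acq_S, acq_R, mut_S, mut_C, loss_C, loss_D,
# death_S, death_R, death_C, death_D, decay_V
def _tau_leap(y0, t_grid, p: ModelParams, a_eff, B, rng, eps=0.03):
    n_grid = len(t_grid)
    out = np.zeros((n_grid, 5), dtype=np.int64)
    y = y0.astype(np.float64)
    t = 0.0
    idx = 0
    n_steps = 0
    n_clips = 0
    er = math.exp(-p.c_R)
    per_repl = p.mutation_model == "per_replication"
    nu = np.array([
        [1, 0, 0, 0, 0],      # birth S
        [0, 1, 0, 0, 0],      # birth S, mutated offspring
        [0, 1, 0, 0, 0],      # birth R
        [0, 0, 1, 0, 0],      # birth C
        [0, 0, 0, 1, 0],      # birth C, mutated offspring
        [0, 0, 0, 1, 0],      # birth D
        [-1, 0, 0, 0, B - 1],  # lysis of S
        [-1, 0, 1, 0, -1],    # rescue acquisition (adsorption -> C)
        [0, 0, 0, 0, -1],     # phage sink on C
        [-1, 0, 1, 0, 0],     # acquisition S -> C
        [0, -1, 0, 1, 0],     # acquisition R -> D
        [-1, 1, 0, 0, 0],     # per-capita mutation S -> R
        [0, 0, -1, 1, 0],     # per-capita mutation C -> D
        [1, 0, -1, 0, 0],     # loss C -> S
        [0, 1, 0, -1, 0],     # loss D -> R
        [-1, 0, 0, 0, 0], [0, -1, 0, 0, 0], [0, 0, -1, 0, 0],
        [0, 0, 0, -1, 0], [0, 0, 0, 0, -1],
    ], dtype=np.float64)

    def propensities(y):
        S, R, C, D, V = y
        N = S + R + C + D
        g = max(1.0 - N / (p.K), 0.0)
        rc = math.exp(-p.tau * a_eff * V)
        mu_b = p.mu if per_repl else 0.0
        rates = np.array([
            p.r * g * S * (1 - mu_b), p.r * g * S * mu_b,
            p.r * er * g * R,
            p.r * rc * g * C * (1 - mu_b), p.r * rc * g * C * mu_b,
            p.r * er * g * D,
            (1 - p.A) * a_eff * V * S if p.rescue_on_acquisition else a_eff * V * S,
            p.A * a_eff * V * S if p.rescue_on_acquisition else 0.0,
            a_eff * V * C,
            0.0 if p.rescue_on_acquisition else p.A * a_eff * V * S,
            p.A * a_eff * V * R if p.acquisition_from_R else 0.0,
            0.0 if per_repl else p.mu * S,
            0.0 if per_repl else p.mu * C,
            p.L * C, p.L * D,
            p.m * S, p.m * R, p.m * C, p.m * D, p.m_v * V,
        ])
        return rates, g

    t_end = t_grid[-1]
    while idx < n_grid:
        rates, g = propensities(y)
        if g == 0.0:
            n_clips += 1
        total = rates.sum()
        if total <= 0:
            out[idx:] = np.round(y).astype(np.int64)
            idx = n_grid
            break
        # Cao-style step: bound expected relative change of each species
        mu_i = nu.T @ rates
        sig_i = (nu.T ** 2) @ rates
        scale = np.maximum(eps * y, 1.0)
        with np.errstate(divide="ignore"):
            tau1 = np.where(np.abs(mu_i) > 0, scale / np.abs(mu_i), np.inf)
            tau2 = np.where(sig_i > 0, scale ** 2 / sig_i, np.inf)
        tau = min(tau1.min(), tau2.min(), t_end - t + 1e-9)
        tau = max(tau, 1e-7)
        k = rng.poisson(rates * tau)
        dy = nu.T @ k
        y_new = y + dy
        if (y_new < 0).any():
            # reject and halve: rerun this step at tau/2 via loop repeat
            k = rng.poisson(rates * (tau / 2))
            dy = nu.T @ k
            y_new = np.maximum(y + dy, 0.0)
            tau = tau / 2
        y = y_new
        t += tau
        n_steps += int(k.sum())
        while idx < n_grid and t >= t_grid[idx] - 1e-12:
            out[idx] = np.round(y).astype(np.int64)
            idx += 1
    return out, n_steps, n_clips


def _initial_counts(state0: PopulationState, volume: float) -> np.ndarray:
    dens = state0.to_array() * volume
    counts = np.rint(dens)
    if not np.allclose(dens, counts, atol=1e-6):
        raise DomainError(
            "initial densities x volume must be integer copy numbers; "
            f"got {dens.tolist()}")
    return counts.astype(np.int64)


def simulate_stochastic(
    state0: PopulationState,
    params: ModelParams,
    duration: float,
    seed: int,
    method: str = "exact",
    volume: float = 1.0,
    n_samples: int = 41,
) -> StochasticRun:
    """One stochastic realisation of the model over ``duration`` hours.

    ``volume`` (ml) converts densities to copy numbers; with the default
    1 ml, densities equal counts.  ``method`` is ``"exact"`` (Gillespie)
    or ``"tau_leap"``.
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    if method not in ("exact", "tau_leap"):
        raise ConfigError(f"unknown method {method!r}")
    y0 = _initial_counts(state0, volume)
    t_grid = np.linspace(0.0, duration, n_samples)
    a_eff = params.a / volume
    K_counts = params.K * volume
    if method == "exact":
        counts, n_events, n_clips = _ssa_core(
            y0, t_grid, params.r, params.m, params.m_v, a_eff, int(params.B),
            params.c_R, params.tau, params.mu, params.A, params.L, K_counts,
            params.mutation_model == "per_replication",
            params.acquisition_from_R, params.rescue_on_acquisition,
            int(seed) % (2 ** 31),
        )
    else:
        rng = np.random.default_rng(seed)
        p_counts = params.replace(K=K_counts)
        counts, n_events, n_clips = _tau_leap(
            y0, t_grid, p_counts, a_eff, int(params.B), rng)
    return StochasticRun(
        seed=int(seed), method=method, volume=volume,
        t=t_grid + state0.t, counts=counts,
        n_events=int(n_events), n_rate_clips=int(n_clips), params=params)


def simulate_protocol_stochastic(
    state0: PopulationState,
    params: ModelParams,
    protocol,
    seed: int,
    method: str = "exact",
    volume: float = 1.0,
    n_samples: int = 41,
) -> StochasticRun:
    """Stochastic serial-transfer run; transfer is binomial thinning.

    Each batch uses a sub-seed derived from ``seed``; the thinning RNG is
    seeded independently so runs are reproducible end to end.
    """
    rng = np.random.default_rng(seed)
    state = state0
    t_parts, c_parts = [], []
    n_events = n_clips = 0
    for k in range(protocol.n_transfers):
        sub = int(rng.integers(0, 2 ** 31))
        run = simulate_stochastic(state, params, protocol.hours_per_transfer,
                                  seed=sub, method=method, volume=volume,
                                  n_samples=n_samples)
        t_parts.append(run.t)
        c_parts.append(run.counts)
        n_events += run.n_events
        n_clips += run.n_rate_clips
        final = run.counts[-1]
        thinned = [rng.binomial(int(final[i]), protocol.dilution) for i in range(4)]
        v_thin = rng.binomial(int(final[4]), protocol.phage_dilution)
        state = PopulationState(
            t=float(run.t[-1]),
            S=thinned[0] / volume, R=thinned[1] / volume,
            C=thinned[2] / volume, D=thinned[3] / volume, V=v_thin / volume)
    return StochasticRun(
        seed=int(seed), method=method, volume=volume,
        t=np.concatenate(t_parts), counts=np.vstack(c_parts),
        n_events=n_events, n_rate_clips=n_clips, params=params)
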