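"""Batch-culture integration, serial transfers, and factorial design sweeps.

A "transfer" mimics daily 1:100 subculture into fresh media: hosts and
phage are diluted by their respective factors, the carrying capacity (a
media property) is unchanged, and growth resumes for another batch
period.  Designs are factorial grids over initial phage dose ``V0``,
carrying capacity ``K`` and inoculum fraction ``S0/K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, DomainError, IntegrationError
from .model import ModelParams, PopulationState, rhs

__all__ = [
    "TransferProtocol",
    "Trajectory",
    "Treatment",
    "ExperimentDesign",
    "integrate_batch",
    "apply_transfer",
    "run_protocol",
    "run_design_grid",
]

#: Densities below this (per ml) are snapped to zero after each batch,
#: avoiding denormal drift in a deterministic model with no true extinction.
EXTINCTION_FLOOR = 1e-30


@dataclass(frozen=True)
class TransferProtocol:
    """Serial-transfer schedule: daily 1:100 subculture for 3 days by default."""

    n_transfers: int = 3
    hours_per_transfer: float = 20.0
    dilution: float = 0.01
    phage_dilution: float = 0.01

    def __post_init__(self) -> None:
        if self.n_transfers < 1:
            raise ConfigError("n_transfers must be >= 1")
        if not (0.0 < self.dilution <= 1.0) or not (0.0 < self.phage_dilution <= 1.0):
            raise ConfigError("dilution factors must be in (0, 1]")
        if self.hours_per_transfer <= 0:
            raise ConfigError("hours_per_transfer must be > 0")


@dataclass
class Trajectory:
    """Time-ordered model states, with transfer boundaries marked.

    ``t`` is non-decreasing; at each transfer boundary the pre-dilution
    state and the post-dilution state share the same time stamp, and
    ``boundaries`` holds the index of each post-dilution sample.
    ``segment_ends`` holds the index of the last (pre-dilution) sample of
    each batch, i.e. the daily plating points.
    """

    t: np.ndarray
    y: np.ndarray  # (n, 5): S, R, C, D, V
    boundaries: list = field(default_factory=list)
    segment_ends: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def state(self, i: int) -> PopulationState:
        return PopulationState.from_array(self.t[i], self.y[i])

    @property
    def final_state(self) -> PopulationState:
        return self.state(len(self.t) - 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=["S", "R", "C", "D", "V"])
        df.insert(0, "t", self.t)
        return df


def integrate_batch(
    state0: PopulationState,
    params: ModelParams,
    duration: float,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_samples: int = 201,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one batch-growth period of ``duration`` hours.

    Uses a stiff-capable adaptive solver (phage density spans many orders
    of magnitude across treatments).  Densities are clipped at zero below
    the extinction floor.
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    t_eval = np.linspace(0.0, duration, n_samples) + state0.t
    y0 = state0.to_array()
    if not y0.any():
        # absorbing all-zero state: skip the solver
        y = np.zeros((n_samples, 5))
        return Trajectory(t=t_eval, y=y, segment_ends=[n_samples - 1],
                          meta={"solver": "trivial", "rtol": rtol, "atol": atol})
    sol = solve_ivp(
        rhs, (state0.t, state0.t + duration), y0, args=(params,),
        method=method, rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = sol.y.T.copy()
    y[y < EXTINCTION_FLOOR] = 0.0
    meta = {"solver": method, "rtol": rtol, "atol": atol,
            "n_steps": int(sol.t.size), "nfev": int(sol.nfev)}
    return Trajectory(t=sol.t.copy(), y=y, segment_ends=[len(sol.t) - 1], meta=meta)


def apply_transfer(state: PopulationState, protocol: TransferProtocol) -> PopulationState:
    """Dilute hosts and phage by the protocol factors; time is preserved.

    Genotype frequencies are invariant (dilution is genotype-blind); K is
    a media property and unchanged by transfer into fresh media.
    """
    d, dv = protocol.dilution, protocol.phage_dilution
    return PopulationState(t=state.t, S=state.S * d, R=state.R * d,
                           C=state.C * d, D=state.D * d, V=state.V * dv)


def run_protocol(
    state0: PopulationState,
    params: ModelParams,
    protocol: TransferProtocol,
    **solver_options,
) -> Trajectory:
    """Concatenated batch integrations separated by transfer dilutions."""
    segments = []
    state = state0
    for _ in range(protocol.n_transfers):
        seg = integrate_batch(state, params, protocol.hours_per_transfer, **solver_options)
        segments.append(seg)
        state = apply_transfer(seg.final_state, protocol)

    t_parts, y_parts, boundaries, segment_ends = [], [], [], []
    offset = 0
    dil = np.array([protocol.dilution] * 4 + [protocol.phage_dilution])
    for k, seg in enumerate(segments):
        t_parts.append(seg.t)
        y_parts.append(seg.y)
        offset += len(seg.t)
        segment_ends.append(offset - 1)
        if k < len(segments) - 1:
            # duplicate-time post-dilution sample starting the next segment
            boundaries.append(offset)
    t = np.concatenate(t_parts)
    y = np.vstack(y_parts)
    meta = {"protocol": protocol, "segments": [s.meta for s in segments]}
    return Trajectory(t=t, y=y, boundaries=boundaries,
                      segment_ends=segment_ends, meta=meta)


@dataclass(frozen=True)
class Treatment:
    """One fully specified culture condition."""

    label: str
    V0: float
    K: float
    inoculum_fraction: float
    protocol: TransferProtocol = TransferProtocol()
    sampling_days: tuple = None  # defaults to every transfer boundary
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if not (0.0 < self.inoculum_fraction <= 1.0):
            raise ConfigError("inoculum_fraction must be in (0, 1]")
        if self.V0 < 0 or self.K <= 0:
            raise ConfigError("V0 must be >= 0 and K > 0")
        if self.sampling_days is None:
            object.__setattr__(
                self, "sampling_days", tuple(range(1, self.protocol.n_transfers + 1)))

    def initial_state(self) -> PopulationState:
        return PopulationState(t=0.0, S=self.inoculum_fraction * self.K, V=self.V0)


@dataclass(frozen=True)
class ExperimentDesign:
    """A labelled factorial set of treatments."""

    label: str
    treatments: tuple

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ConfigError(f"design {self.label!r} has no treatments")
        object.__setattr__(self, "treatments", tuple(self.treatments))


def run_design_grid(
    design: ExperimentDesign, params: ModelParams, **solver_options
) -> pd.DataFrame:
    """Deterministic model predictions for every treatment x sampling day.

    Returns a tidy table with one row per treatment and day, holding the
    pre-dilution densities (the daily plating point at t = day x batch
    duration) and the host genotype frequencies ``f_S .. f_D``.
    Replicate variation enters only later, at synthetic sampling.
    """
    from .popgen import genotype_frequencies, linkage_disequilibrium

    rows = []
    for tr in design.treatments:
        p = params.replace(K=tr.K)
        traj = run_protocol(tr.initial_state(), p, tr.protocol, **solver_options)
        for day in tr.sampling_days:
            idx = traj.segment_ends[day - 1]
            st = traj.state(idx)
            freqs = genotype_frequencies(st)
            rows.append({
                "design": design.label, "treatment": tr.label,
                "V0": tr.V0, "K": tr.K,
                "inoculum_fraction": tr.inoculum_fraction,
                "day": day, "t": st.t,
                "S": st.S, "R": st.R, "C": st.C, "D": st.D, "V": st.V,
                "N": st.N,
                "f_S": freqs.f_S, "f_R": freqs.f_R,
                "f_C": freqs.f_C, "f_D": freqs.f_D,
                "LD": linkage_disequilibrium(freqs),
            })
    return pd.DataFrame(rows)
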