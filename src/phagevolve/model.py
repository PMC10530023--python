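"""Five-compartment eco-evolutionary model of phage defence evolution.

The model tracks a batch culture of initially phage-sensitive bacteria
(*S*) exposed to a virulent phage (free phage density *V*).  Hosts can
escape infection through two routes:

* **surface mutation** (*R* hosts) — constitutive resistance via receptor
  loss, acquired during replication at rate ``mu`` and paying a fixed
  growth cost ``exp(-c_R)``;
* **CRISPR-Cas immunity** (*C* hosts) — inducible resistance via spacer
  acquisition at rate ``A*a*V`` (proportional to phage exposure), paying
  an infection-induced toxicity cost ``exp(-tau*a*V)``.

*D* hosts carry both resistances but, being never infected, only express
the constitutive cost — the source of strong negative epistasis between
the two loci.  Host growth is logistic with carrying capacity ``K``
(density-dependence factor ``g = 1 - N/K`` shared by all genotypes);
phage infect *S* by mass action ``a*V*S`` with burst size ``B``, and are
adsorbed (without progeny) by *C* hosts, which therefore act as a phage
sink.  CRISPR resistance can be lost at rate ``L`` (C -> S, D -> R).

All rates are per hour; densities are per ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace as _dc_replace

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "ModelParams",
    "PopulationState",
    "RateBreakdown",
    "genotype_growth_rates",
    "derivatives",
    "rhs",
]

MUTATION_MODELS = ("per_replication", "per_capita")

#: Parameter names that appear in config files, in canonical order.
PARAM_NAMES = ("r", "m", "m_v", "a", "B", "c_R", "tau", "mu", "A", "L", "K")
SWITCH_NAMES = ("mutation_model", "acquisition_from_R", "rescue_on_acquisition")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and structural switches of the model.

    Defaults are the reference parameter set for the P. aeruginosa
    PA14 / phage DMS3vir system (per-hour rates, densities per ml).

    Parameters
    ----------
    r : maximal per-capita host growth rate (1/h); naive hosts grow at
        ``r_S = r``.
    m : host background mortality rate (1/h).
    m_v : free-phage decay rate (1/h).
    a : adsorption rate constant (ml/phage/h).
    B : burst size (phage released per lysed cell).
    c_R : constitutive cost of surface resistance; ``r_R = exp(-c_R) * r``.
    tau : CRISPR toxicity coefficient; ``r_C = exp(-tau*a*V) * r``.
    mu : surface-mutation rate.  Under the default ``per_replication``
        model this is a probability per replication (mutation flux
        ``mu * r_X * g * X``); under ``per_capita`` it is a plain rate
        (flux ``mu * X``).
    A : spacer-acquisition efficiency; acquisition rate is ``A * a * V``.
    L : CRISPR resistance-loss rate (1/h), applied as C -> S and D -> R.
    K : carrying capacity (cells/ml).
    mutation_model : ``"per_replication"`` (default) or ``"per_capita"``.
    acquisition_from_R : whether surface mutants can also acquire spacers
        (R -> D at ``A*a*V``).  Off by default: surface modification
        blocks the adsorption that acquisition requires.
    rescue_on_acquisition : whether spacer acquisition subtracts from the
        lysis flux, i.e. lysis becomes ``(1-A)*a*V*S``.  Off by default.
    """

    r: float = 1.0
    m: float = 0.0
    m_v: float = 0.0
    a: float = 1e-8
    B: float = 100.0
    c_R: float = 0.01
    tau: float = 0.01
    mu: float = 1e-4
    A: float = 5e-4
    L: float = 1e-3
    K: float = 1e8
    mutation_model: str = "per_replication"
    acquisition_from_R: bool = False
    rescue_on_acquisition: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ConfigError(f"parameter {name!r} must be a finite number, got {value!r}")
            if value < 0:
                raise ConfigError(f"parameter {name!r} must be >= 0, got {value!r}")
        if self.B < 1:
            raise ConfigError(f"burst size B must be >= 1, got {self.B!r}")
        if self.K <= 0:
            raise ConfigError("carrying capacity K must be > 0")
        if self.mutation_model not in MUTATION_MODELS:
            raise ConfigError(
                f"mutation_model must be one of {MUTATION_MODELS}, got {self.mutation_model!r}"
            )

    @classmethod
    def paper_defaults(cls) -> "ModelParams":
        """The bundled default parameter profile (the class defaults)."""
        return cls()

    def replace(self, **changes) -> "ModelParams":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PopulationState:
    """Densities of the four host genotypes and free phage at time ``t``.

    ``S`` sensitive, ``R`` surface mutant, ``C`` CRISPR immune, ``D``
    doubly resistant (cells/ml); ``V`` free phage (phage/ml).
    """

    t: float = 0.0
    S: float = 0.0
    R: float = 0.0
    C: float = 0.0
    D: float = 0.0
    V: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S", "R", "C", "D", "V"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise DomainError(f"density {name} must be finite and >= 0, got {value!r}")

    @property
    def N(self) -> float:
        """Total host density S + R + C + D."""
        return self.S + self.R + self.C + self.D

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.R, self.C, self.D, self.V], dtype=float)

    @classmethod
    def from_array(cls, t: float, y: np.ndarray) -> "PopulationState":
        S, R, C, D, V = (float(max(v, 0.0)) for v in y)
        return cls(t=float(t), S=S, R=R, C=C, D=D, V=V)


@dataclass(frozen=True)
class RateBreakdown:
    """Named nonnegative fluxes whose signed sums give the derivatives.

    A diagnostic decomposition: each compartment derivative equals the
    sum of its gain fluxes minus its loss fluxes (see :meth:`signed_sums`).
    """

    growth_S: float
    growth_R: float
    growth_C: float
    growth_D: float
    lysis: float              # death of S by productive infection
    acquisition_S: float      # S -> C spacer acquisition
    acquisition_R: float      # R -> D (only if acquisition_from_R)
    mutation_S: float         # S -> R surface mutation
    mutation_C: float         # C -> D surface mutation
    loss_C: float             # C -> S CRISPR loss
    loss_D: float             # D -> R CRISPR loss
    death_S: float
    death_R: float
    death_C: float
    death_D: float
    phage_production: float   # B * lysis
    phage_adsorption_S: float  # a*V*S phage removal on contact with S
    phage_adsorption_C: float  # a*V*C phage sink on CRISPR hosts
    phage_decay: float

    def signed_sums(self) -> np.ndarray:
        """Derivatives (dS, dR, dC, dD, dV) reassembled from the fluxes."""
        dS = (self.growth_S - self.lysis - self.acquisition_S - self.mutation_S
              + self.loss_C - self.death_S)
        dR = (self.growth_R + self.mutation_S + self.loss_D - self.death_R
              - self.acquisition_R)
        dC = (self.growth_C + self.acquisition_S - self.mutation_C - self.loss_C
              - self.death_C)
        dD = (self.growth_D + self.mutation_C + self.acquisition_R - self.loss_D
              - self.death_D)
        dV = (self.phage_production - self.phage_adsorption_S
              - self.phage_adsorption_C - self.phage_decay)
        return np.array([dS, dR, dC, dD, dV])


def genotype_growth_rates(params: ModelParams, V: float):
    """Per-capita intrinsic growth rates (r_S, r_R, r_C, r_D) at phage density V.

    These are the rates *before* the shared logistic factor ``g``:
    ``r_S = r``, ``r_R = r_D = exp(-c_R) * r`` (constitutive cost), and
    ``r_C = exp(-tau*a*V) * r`` (infection-induced toxicity).
    """
    if not math.isfinite(V) or V < 0:
        raise DomainError(f"phage density V must be finite and >= 0, got {V!r}")
    r_S = params.r
    r_R = math.exp(-params.c_R) * params.r
    r_C = math.exp(-params.tau * params.a * V) * params.r
    return r_S, r_R, r_C, r_R


def _flux_terms(S, R, C, D, V, p: ModelParams):
    """Raw flux arithmetic shared by `derivatives` and the solver `rhs`."""
    N = S + R + C + D
    g = 1.0 - N / p.K
    r_S = p.r
    r_R = math.exp(-p.c_R) * p.r
    r_C = math.exp(-p.tau * p.a * V) * p.r
    r_D = r_R

    growth = (r_S * g * S, r_R * g * R, r_C * g * C, r_D * g * D)

    aVS = p.a * V * S
    lysis = (1.0 - p.A) * aVS if p.rescue_on_acquisition else aVS
    acq_S = p.A * aVS
    acq_R = p.A * p.a * V * R if p.acquisition_from_R else 0.0

    if p.mutation_model == "per_replication":
        mut_S = p.mu * r_S * g * S
        mut_C = p.mu * r_C * g * C
    else:
        mut_S = p.mu * S
        mut_C = p.mu * C

    return (growth, lysis, acq_S, acq_R, mut_S, mut_C,
            p.L * C, p.L * D,
            p.m * S, p.m * R, p.m * C, p.m * D,
            p.B * lysis, aVS, p.a * V * C, p.m_v * V)


def derivatives(state: PopulationState, params: ModelParams):
    """Time-derivatives of (S, R, C, D, V) plus the flux breakdown.

    Implements the default system (``g = 1 - N/K``, ``M(X)`` the
    mutation flux)::

        dS = r_S g S - a V S - M(S) - A a V S + L C - m S
        dR = r_R g R + M(S) + L D - m R
        dC = r_C g C + A a V S - M(C) - L C - m C
        dD = r_D g D + M(C) - L D - m D
        dV = B a V S - a V (S + C) - m_v V

    modulated by the structural switches documented on
    :class:`ModelParams`.

    Returns
    -------
    (numpy.ndarray, RateBreakdown)
        The derivative vector and its flux decomposition; the vector
        equals ``breakdown.signed_sums()`` exactly.
    """
    terms = _flux_terms(state.S, state.R, state.C, state.D, state.V, params)
    (growth, lysis, acq_S, acq_R, mut_S, mut_C, loss_C, loss_D,
     dth_S, dth_R, dth_C, dth_D, prod, ads_S, ads_C, decay) = terms
    breakdown = RateBreakdown(
        growth_S=growth[0], growth_R=growth[1], growth_C=growth[2], growth_D=growth[3],
        lysis=lysis, acquisition_S=acq_S, acquisition_R=acq_R,
        mutation_S=mut_S, mutation_C=mut_C, loss_C=loss_C, loss_D=loss_D,
        death_S=dth_S, death_R=dth_R, death_C=dth_C, death_D=dth_D,
        phage_production=prod, phage_adsorption_S=ads_S,
        phage_adsorption_C=ads_C, phage_decay=decay,
    )
    return breakdown.signed_sums(), breakdown


def rhs(t, y, params: ModelParams) -> np.ndarray:
    """Right-hand side for the ODE solver (clamps tiny negative densities)."""
    S, R, C, D, V = (v if v > 0.0 else 0.0 for v in y)
    (growth, lysis, acq_S, acq_R, mut_S, mut_C, loss_C, loss_D,
     dth_S, dth_R, dth_C, dth_D, prod, ads_S, ads_C, decay) = _flux_terms(
        S, R, C, D, V, params)
    dS = growth[0] - lysis - acq_S - mut_S + loss_C - dth_S
    dR = growth[1] + mut_S + loss_D - dth_R - acq_R
    dC = growth[2] + acq_S - mut_C - loss_C - dth_C
    dD = growth[3] + mut_C + acq_R - loss_D - dth_D
    dV = prod - ads_S - ads_C - decay
    return np.array([dS, dR, dC, dD, dV])
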