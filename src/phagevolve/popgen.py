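"""Genotype frequencies, linkage disequilibrium and selection coefficients.

The two resistance loci (surface modification, CRISPR) define four
haplotypes S, R, C, D.  Because double resistance confers no extra
protection but pays the constitutive cost, epistasis is strongly
negative and the two single-resistance haplotypes come to be
over-represented: linkage disequilibrium ``LD = f_S f_D - f_R f_C``
turns negative as resistance spreads.

Selection coefficients here measure *selection only*: the difference in
flux-weighted per-capita birth/death rates between carriers and
non-carriers of a focal allele, excluding mutation, spacer acquisition
and resistance-loss fluxes (those are supply, not selection).  In the
limit of no supply the coefficient equals d/dt logit(carrier frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedCoefficientError, UndefinedFrequencyError
from .model import ModelParams, PopulationState, genotype_growth_rates

__all__ = [
    "GenotypeFrequencies",
    "SelectionReport",
    "genotype_frequencies",
    "linkage_disequilibrium",
    "selection_coefficient",
    "selection_coefficients",
    "selection_series",
    "integrated_selection",
    "interference_curve",
]


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Host genotype frequencies; always sum to 1."""

    f_S: float
    f_R: float
    f_C: float
    f_D: float

    def as_tuple(self):
        return (self.f_S, self.f_R, self.f_C, self.f_D)


def genotype_frequencies(state: PopulationState) -> GenotypeFrequencies:
    """Frequencies f_X = X / N among hosts; undefined for an empty population."""
    N = state.N
    if N <= 0:
        raise UndefinedFrequencyError("genotype frequencies undefined at N = 0")
    return GenotypeFrequencies(state.S / N, state.R / N, state.C / N, state.D / N)


def linkage_disequilibrium(freqs: GenotypeFrequencies) -> float:
    """Two-locus LD of the resistance loci: ``f_S f_D - f_R f_C``."""
    return freqs.f_S * freqs.f_D - freqs.f_R * freqs.f_C


@dataclass(frozen=True)
class SelectionReport:
    """Selection coefficients of both resistance alleles at one time point.

    ``components`` splits each coefficient into a growth-differential
    term (cost of resistance under density dependence) and a
    phage-protection term (lysis avoided by carriers); the two sum to
    the total.
    """

    time: float
    s_R: float
    s_C: float
    components: dict


def _per_capita_rates(state: PopulationState, params: ModelParams):
    g = 1.0 - state.N / params.K
    r_S, r_R, r_C, r_D = genotype_growth_rates(params, state.V)
    growth = {"S": r_S * g, "R": r_R * g, "C": r_C * g, "D": r_D * g}
    lysis = {"S": params.a * state.V, "R": 0.0, "C": 0.0, "D": 0.0}
    return growth, lysis


_CARRIERS = {"surface": ("R", "D"), "crispr": ("C", "D")}


def selection_coefficient(state: PopulationState, params: ModelParams, allele: str):
    """Selection coefficient (per hour) of one resistance allele.

    ``allele`` is ``"surface"`` (carriers R, D) or ``"crispr"`` (carriers
    C, D).  Returns ``(s, components)`` where components hold the growth
    and phage-protection terms.  Background mortality ``m`` is shared by
    every genotype and cancels.
    """
    if allele not in _CARRIERS:
        raise ValueError(f"allele must be 'surface' or 'crispr', got {allele!r}")
    carriers = _CARRIERS[allele]
    non_carriers = tuple(x for x in "SRCD" if x not in carriers)
    dens = {x: getattr(state, x) for x in "SRCD"}
    n_car = sum(dens[x] for x in carriers)
    n_non = sum(dens[x] for x in non_carriers)
    if n_car <= 0 or n_non <= 0:
        raise UndefinedCoefficientError(
            f"selection coefficient for {allele!r} undefined: "
            f"carriers={n_car:g}, non-carriers={n_non:g}")
    growth, lysis = _per_capita_rates(state, params)

    def avg(rates, group, total):
        return sum(rates[x] * dens[x] for x in group) / total

    growth_term = avg(growth, carriers, n_car) - avg(growth, non_carriers, n_non)
    protection_term = avg(lysis, non_carriers, n_non) - avg(lysis, carriers, n_car)
    return growth_term + protection_term, {
        "growth": growth_term, "phage_protection": protection_term}


def selection_coefficients(state: PopulationState, params: ModelParams) -> SelectionReport:
    """Selection coefficients of both alleles (each requires both classes present)."""
    s_R, comp_R = selection_coefficient(state, params, "surface")
    s_C, comp_C = selection_coefficient(state, params, "crispr")
    return SelectionReport(
        time=state.t, s_R=s_R, s_C=s_C,
        components={"surface": comp_R, "crispr": comp_C})


def selection_series(trajectory, params: ModelParams, allele: str):
    """(t, s) arrays along a trajectory, skipping points where s is undefined."""
    ts, ss = [], []
    for i in range(len(trajectory.t)):
        st = trajectory.state(i)
        try:
            s, _ = selection_coefficient(st, params, allele)
        except UndefinedCoefficientError:
            continue
        ts.append(trajectory.t[i])
        ss.append(s)
    return np.asarray(ts), np.asarray(ss)


def integrated_selection(trajectory, params: ModelParams, allele: str) -> float:
    """Time integral of the selection coefficient (trapezoid on solver output).

    Duplicate time stamps at transfer boundaries contribute zero width, so
    the jump in densities at dilution is handled naturally.
    """
    ts, ss = selection_series(trajectory, params, allele)
    if ts.size < 2:
        return 0.0
    return float(np.trapezoid(ss, ts))


def interference_curve(
    params: ModelParams,
    acquisition_values,
    state0: PopulationState | None = None,
    protocol=None,
    **solver_options,
) -> pd.DataFrame:
    """Interference of CRISPR on selection for surface resistance.

    For each spacer-acquisition efficiency ``A``, runs the 3-transfer
    default setup (K = 1e8, V0 = 1e4, S0 = K/100 unless overridden) and
    reports the time-integrated surface-allele selection coefficient and
    the final surface-mutant frequency.  Faster spacer acquisition
    raises early resistance and depresses phage density — both weaken
    selection for the alternative, constitutive resistance.
    """
    from .dynamics import TransferProtocol, run_protocol

    if protocol is None:
        protocol = TransferProtocol()
    if state0 is None:
        state0 = PopulationState(t=0.0, S=params.K / 100.0, V=1e4)
    rows = []
    for A in acquisition_values:
        if A <= 0:
            raise ValueError("acquisition values must be > 0")
        p = params.replace(A=A)
        traj = run_protocol(state0, p, protocol, **solver_options)
        final = genotype_frequencies(traj.final_state)
        rows.append({
            "A": A,
            "integrated_s_R": integrated_selection(traj, p, "surface"),
            "final_f_R": final.f_R,
            "final_f_C": final.f_C,
        })
    return pd.DataFrame(rows)
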