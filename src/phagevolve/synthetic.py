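"""Synthetic "experimental" datasets: clone typing tables and CFU/PFU counts.

Emulates the observation layer of a serial-transfer evolution
experiment.  Per replicate culture, 24 random clones are streaked
against the plain phage and an anti-CRISPR
(AcrIF1) carrying variant.  Phage-sensitive clones are susceptible to
both; surface mutants resist both; CRISPR clones resist the plain phage
only, because AcrIF1 disables CRISPR interference.  Doubly resistant
clones therefore score as surface mutants — the receptor is still
mutated — so the observed "sm" fraction estimates ``f_R + f_D``.

Clone counts are multinomial draws from the deterministic model
frequencies (optionally Dirichlet-compounded for between-replicate
overdispersion); plate counts get mean-preserving lognormal noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dynamics import ExperimentDesign, run_design_grid
from .errors import ConfigError, DomainError, InconsistentAssayError
from .model import ModelParams

__all__ = [
    "AssayResult",
    "CloneTable",
    "SyntheticDataset",
    "classify_phenotype",
    "genotype_to_assay",
    "sample_clone_table",
    "generate_dataset",
]

PHENOTYPES = ("sensitive", "sm", "crispr")
GENOTYPES = ("S", "R", "C", "D")


class AssayResult(NamedTuple):
    """Two-phage streak assay outcome for one clone."""

    resistant_to_dms3vir: bool
    resistant_to_dms3vir_acrif1: bool


def classify_phenotype(assay: AssayResult) -> str:
    """Map a streak-assay outcome to sensitive / sm / crispr.

    Resistance to the anti-CRISPR phage without resistance to the plain
    phage is physically inconsistent and raises.
    """
    plain, acr = bool(assay[0]), bool(assay[1])
    if not plain and not acr:
        return "sensitive"
    if plain and acr:
        return "sm"
    if plain and not acr:
        return "crispr"
    raise InconsistentAssayError(
        "clone resistant to the AcrIF1 phage but sensitive to the plain phage")


def genotype_to_assay(genotype: str) -> AssayResult:
    """Streak-assay outcome produced by each true genotype.

    D hosts resist both phages: AcrIF1 only disables CRISPR, and the
    mutated receptor still blocks adsorption — so D scores as sm.
    """
    if genotype == "S":
        return AssayResult(False, False)
    if genotype == "R" or genotype == "D":
        return AssayResult(True, True)
    if genotype == "C":
        return AssayResult(True, False)
    raise DomainError(f"unknown genotype {genotype!r}")


def observed_class_probabilities(row) -> np.ndarray:
    """(p_sensitive, p_sm, p_crispr) implied by model frequencies in a row."""
    p = np.array([row["f_S"], row["f_R"] + row["f_D"], row["f_C"]], dtype=float)
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise DomainError("invalid truth frequencies")
    return p / total


@dataclass
class CloneTable:
    """Per replicate x treatment x day clone classification counts."""

    data: pd.DataFrame  # treatment, replicate, day, n_sensitive, n_sm, n_crispr
    n_clones: int = 24
    n_replicates: int = 6
    seed: int | None = None
    overdispersion: float = 0.0

    COLUMNS = ("treatment", "replicate", "day", "n_sensitive", "n_sm", "n_crispr")


def _dirichlet_multinomial(rng, n, p, rho):
    """Multinomial with Dirichlet-compounded probabilities.

    ``rho`` in [0, 1) is the pairwise within-replicate correlation; the
    concentration is ``(1 - rho) / rho`` so each class count is
    beta-binomial with variance inflation ``1 + (n - 1) * rho``.
    """
    if rho == 0.0:
        return rng.multinomial(n, p)
    alpha0 = (1.0 - rho) / rho
    pos = p > 0
    q = np.zeros_like(p)
    q[pos] = rng.dirichlet(alpha0 * p[pos])
    return rng.multinomial(n, q)


def sample_clone_table(
    truth: pd.DataFrame,
    n_clones: int = 24,
    n_replicates: int = 6,
    seed: int | None = None,
    overdispersion: float = 0.0,
) -> CloneTable:
    """Draw clone-typing counts from deterministic truth frequencies.

    ``truth`` is a tidy design-grid table (one row per treatment x day
    with f_S..f_D).  Per replicate, ``n_clones`` clones are assigned true
    genotypes by a multinomial draw and pushed through the two-phage
    assay, yielding counts over {sensitive, sm, crispr} with class
    probabilities (f_S, f_R + f_D, f_C).
    """
    if n_clones <= 0:
        raise ConfigError("n_clones must be > 0")
    if not (0.0 <= overdispersion < 1.0):
        raise ConfigError("overdispersion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in truth.iterrows():
        p = observed_class_probabilities(row)
        for rep in range(1, n_replicates + 1):
            counts = _dirichlet_multinomial(rng, n_clones, p, overdispersion)
            rows.append({
                "treatment": row["treatment"], "replicate": rep,
                "day": int(row["day"]),
                "n_sensitive": int(counts[0]), "n_sm": int(counts[1]),
                "n_crispr": int(counts[2]),
            })
    return CloneTable(data=pd.DataFrame(rows, columns=list(CloneTable.COLUMNS)),
                      n_clones=n_clones, n_replicates=n_replicates,
                      seed=seed, overdispersion=overdispersion)


@dataclass
class SyntheticDataset:
    """A full synthetic experiment: truth, clone table, noisy plate counts."""

    truth: pd.DataFrame
    clones: CloneTable
    counts: pd.DataFrame  # treatment, replicate, day, cfu_per_ml, pfu_per_ml
    manifest: dict = field(default_factory=dict)


def _config_hash(design: ExperimentDesign, params: ModelParams, noise: dict) -> str:
    payload = json.dumps(
        {"design": design.label,
         "treatments": [(t.label, t.V0, t.K, t.inoculum_fraction) for t in design.treatments],
         "params": params.to_dict(), "noise": noise},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_dataset(
    design: ExperimentDesign,
    params: ModelParams,
    count_cv: float = 0.2,
    overdispersion: float = 0.0,
    n_clones: int = 24,
    seed: int | None = None,
) -> SyntheticDataset:
    """Deterministic truth plus per-replicate clone typing and plate counts.

    CFU/PFU noise is mean-preserving lognormal with coefficient of
    variation ``count_cv`` (0 disables it: counts equal the truth and
    only clone sampling is stochastic).  Reruns with the same seed are
    bit-identical.
    """
    if count_cv < 0:
        raise ConfigError("count_cv must be >= 0")
    truth = run_design_grid(design, params)
    rng = np.random.default_rng(seed)
    clone_seed = int(rng.integers(0, 2 ** 31))
    rows = []
    sigma = math.sqrt(math.log(1.0 + count_cv ** 2)) if count_cv > 0 else 0.0
    for _, row in truth.iterrows():
        n_reps = next(t.n_replicates for t in design.treatments
                      if t.label == row["treatment"])
        for rep in range(1, n_reps + 1):
            if sigma > 0:
                f_cfu = math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                f_pfu = math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
            else:
                f_cfu = f_pfu = 1.0
            rows.append({
                "treatment": row["treatment"], "replicate": rep,
                "day": int(row["day"]),
                "cfu_per_ml": row["N"] * f_cfu,
                "pfu_per_ml": row["V"] * f_pfu,
            })
    n_replicates = max(t.n_replicates for t in design.treatments)
    clones = sample_clone_table(truth, n_clones=n_clones,
                                n_replicates=n_replicates, seed=clone_seed,
                                overdispersion=overdispersion)
    noise = {"count_cv": count_cv, "overdispersion": overdispersion}
    manifest = {
        "seed": seed, "clone_seed": clone_seed,
        "config_hash": _config_hash(design, params, noise),
        "noise": noise, "n_clones": n_clones,
    }
    return SyntheticDataset(truth=truth, clones=clones,
                            counts=pd.DataFrame(rows), manifest=manifest)
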