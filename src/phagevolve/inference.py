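"""Maximum-likelihood parameter fitting from clone-typing tables.

The observation model is multinomial: each replicate's 24 clones fall
into {sensitive, sm, crispr} with probabilities (f_S, f_R + f_D, f_C)
given by the deterministic model at that treatment and day (a mean-field
approximation to the stochastic culture).  Free parameters are fitted in
log space by bounded multi-start optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .dynamics import ExperimentDesign, run_design_grid
from .errors import ConfigError, FitFailureError
from .model import ModelParams
from .synthetic import CloneTable, observed_class_probabilities

__all__ = ["FitResult", "clone_loglikelihood", "fit_parameters"]

FITTABLE = ("mu", "A", "c_R", "tau")
DEFAULT_BOUNDS = {"mu": (1e-8, 1e-1), "A": (1e-8, 1e-1),
                  "c_R": (1e-6, 1.0), "tau": (1e-6, 1.0)}
PROB_FLOOR = 1e-12

_COUNT_COLS = ["n_sensitive", "n_sm", "n_crispr"]


def _class_probability_table(params: ModelParams, design: ExperimentDesign,
                             cache: dict | None = None) -> dict:
    """(treatment, day) -> class probabilities from the deterministic model."""
    key = tuple(sorted(params.to_dict().items()))
    if cache is not None and key in cache:
        return cache[key]
    truth = run_design_grid(design, params)
    table = {
        (row["treatment"], int(row["day"])): observed_class_probabilities(row)
        for _, row in truth.iterrows()
    }
    if cache is not None:
        cache[key] = table
    return table


def clone_loglikelihood(
    params: ModelParams,
    design: ExperimentDesign,
    clone_table: CloneTable | pd.DataFrame,
    _cache: dict | None = None,
) -> float:
    """Multinomial log-likelihood of a clone table under the model.

    Sums the multinomial log-pmf over rows, with model class
    probabilities floored at 1e-12 before taking logs.  Invariant to row
    order; an empty table has log-likelihood 0.
    """
    df = clone_table.data if isinstance(clone_table, CloneTable) else clone_table
    if df.empty:
        return 0.0
    probs = _class_probability_table(params, design, _cache)
    missing = {(t, int(d)) for t, d in zip(df["treatment"], df["day"])} - set(probs)
    if missing:
        raise ConfigError(f"design does not cover table treatments/days: {sorted(missing)}")
    ll = 0.0
    counts = df[_COUNT_COLS].to_numpy(dtype=float)
    for (t, d), n in zip(zip(df["treatment"], df["day"]), counts):
        p = np.maximum(probs[(t, int(d))], PROB_FLOOR)
        tot = n.sum()
        ll += (gammaln(tot + 1) - gammaln(n + 1).sum() + (n * np.log(p)).sum())
    return float(ll)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: dict
    loglik: float
    fixed: dict
    free: tuple
    bounds: dict
    starts: list = field(default_factory=list)
    success: bool = True
    n_loglik_evals: int = 0
    bootstrap_intervals: dict | None = None
    seed: int | None = None

    def fitted_params(self) -> ModelParams:
        return ModelParams.from_dict({**self.fixed, **self.estimates})


def fit_parameters(
    clone_table: CloneTable | pd.DataFrame,
    design: ExperimentDesign,
    free=("mu", "A"),
    params: ModelParams | None = None,
    bounds: dict | None = None,
    seed: int | None = None,
    n_starts: int = 4,
    bootstrap: int = 0,
) -> FitResult:
    """Fit a subset of {mu, A, c_R, tau} by multi-start bounded MLE.

    Optimisation runs in log10-parameter space (rates span orders of
    magnitude and must stay positive).  One start is the centre of the
    log-bounds box; the rest are drawn uniformly in it from ``seed``.
    With ``free=()`` the function evaluates the likelihood of ``params``
    as given (evaluation mode).  ``bootstrap > 0`` adds nonparametric
    percentile intervals from resampling replicates.
    """
    free = tuple(free)
    unknown = set(free) - set(FITTABLE)
    if unknown:
        raise ConfigError(f"cannot fit parameters: {sorted(unknown)}")
    base = params if params is not None else ModelParams.paper_defaults()
    df = clone_table.data if isinstance(clone_table, CloneTable) else clone_table
    cache: dict = {}

    if not free:
        ll = clone_loglikelihood(base, design, df, _cache=cache)
        return FitResult(estimates={}, loglik=ll, fixed=base.to_dict(),
                         free=free, bounds={}, success=True, seed=seed)

    bnds = {k: DEFAULT_BOUNDS[k] for k in free}
    if bounds:
        bnds.update({k: tuple(v) for k, v in bounds.items() if k in free})
    log_bounds = [(math.log10(lo), math.log10(hi)) for lo, hi in (bnds[k] for k in free)]

    evals = [0]

    def negll(x):
        evals[0] += 1
        trial = base.replace(**{k: 10.0 ** xi for k, xi in zip(free, x)})
        return -clone_loglikelihood(trial, design, df, _cache=cache)

    rng = np.random.default_rng(seed)
    centre = np.array([(lo + hi) / 2 for lo, hi in log_bounds])
    starts_x = [centre] + [
        np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
        for _ in range(max(n_starts - 1, 0))
    ]

    results, starts_log = [], []
    for x0 in starts_x:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=log_bounds)
        starts_log.append({
            "x0": {k: 10.0 ** v for k, v in zip(free, x0)},
            "x": {k: 10.0 ** v for k, v in zip(free, res.x)},
            "loglik": -float(res.fun), "success": bool(res.success),
        })
        if res.success or np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise FitFailureError(f"all {len(starts_x)} optimiser starts failed: {starts_log}")
    best = min(results, key=lambda r: r.fun)
    estimates = {k: float(10.0 ** v) for k, v in zip(free, best.x)}
    fixed = {k: v for k, v in base.to_dict().items() if k not in free}

    boot_intervals = None
    if bootstrap > 0:
        boot = {k: [] for k in free}
        groups = df.groupby(["treatment", "day"], sort=False)
        for _ in range(bootstrap):
            parts = []
            for _, grp in groups:
                idx = rng.integers(0, len(grp), size=len(grp))
                parts.append(grp.iloc[idx])
            resampled = pd.concat(parts, ignore_index=True)
            sub = fit_parameters(resampled, design, free=free, params=base,
                                 bounds=bnds, seed=int(rng.integers(0, 2 ** 31)),
                                 n_starts=1)
            for k in free:
                boot[k].append(sub.estimates[k])
        boot_intervals = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in boot.items()
        }

    return FitResult(
        estimates=estimates, loglik=-float(best.fun), fixed=fixed, free=free,
        bounds=bnds, starts=starts_log, success=True,
        n_loglik_evals=evals[0], bootstrap_intervals=boot_intervals, seed=seed)
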