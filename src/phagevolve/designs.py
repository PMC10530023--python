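"""Bundled experiment designs for the standard serial-transfer protocols.

Each factory returns an :class:`~phagevolve.dynamics.ExperimentDesign`:

* ``inoculum_sweep`` — inoculum fraction S0/K in {10%, 1%, 0.1%, 0.01%}
  at a fixed phage dose V0 = 1e6/ml, K = 1e8, one 20 h growth period.
* ``inoculum_sweep_moi`` — same inocula with V0 scaled to keep the
  multiplicity of infection at 0.1.
* ``dose_capacity_grid`` — factorial V0 x K grid, S0 = K/100, 3 daily
  transfers.
* ``transfer_dynamics`` — the single default 3-transfer condition
  (K = 1e8, V0 = 1e4, S0 = K/100) used for the LD and selection
  diagnostics.
* ``clone_typing_factorial`` — the dose x capacity design used for synthetic
  clone-typing data and parameter-recovery studies (experimental phage
  doses, 6 replicates, 24 clones, days 1-3).
"""

from __future__ import annotations

from .dynamics import ExperimentDesign, TransferProtocol, Treatment
from .errors import ConfigError

__all__ = ["bundled_design", "BUNDLED_DESIGNS"]

_ONE_DAY = TransferProtocol(n_transfers=1)
_THREE_DAYS = TransferProtocol(n_transfers=3)

INOCULUM_FRACTIONS = (0.1, 0.01, 0.001, 0.0001)
DOSE_GRID_V0 = (1e2, 1e4, 1e6, 1e8, 1e10)
DOSE_GRID_K = (1e6, 1e7, 1e8, 1e9)
TYPING_V0 = (1e1, 1e2, 1e3, 1e5, 1e9)
TYPING_K = (1e6, 1e7, 1e8, 1e9)


def inoculum_sweep() -> ExperimentDesign:
    treatments = [
        Treatment(label=f"inoc_{frac:g}", V0=1e6, K=1e8,
                  inoculum_fraction=frac, protocol=_ONE_DAY)
        for frac in INOCULUM_FRACTIONS
    ]
    return ExperimentDesign("inoculum_sweep", treatments)


def inoculum_sweep_moi(moi: float = 0.1) -> ExperimentDesign:
    treatments = [
        Treatment(label=f"inoc_{frac:g}_moi{moi:g}", V0=moi * frac * 1e8, K=1e8,
                  inoculum_fraction=frac, protocol=_ONE_DAY)
        for frac in INOCULUM_FRACTIONS
    ]
    return ExperimentDesign("inoculum_sweep_moi", treatments)


def dose_capacity_grid(V0_levels=DOSE_GRID_V0, K_levels=DOSE_GRID_K) -> ExperimentDesign:
    treatments = [
        Treatment(label=f"V0_{V0:g}_K_{K:g}", V0=V0, K=K,
                  inoculum_fraction=0.01, protocol=_THREE_DAYS)
        for K in K_levels for V0 in V0_levels
    ]
    return ExperimentDesign("dose_capacity_grid", treatments)


def transfer_dynamics() -> ExperimentDesign:
    tr = Treatment(label="default", V0=1e4, K=1e8,
                   inoculum_fraction=0.01, protocol=_THREE_DAYS)
    return ExperimentDesign("transfer_dynamics", (tr,))


def clone_typing_factorial(V0_levels=TYPING_V0, K_levels=TYPING_K) -> ExperimentDesign:
    treatments = [
        Treatment(label=f"V0_{V0:g}_K_{K:g}", V0=V0, K=K,
                  inoculum_fraction=0.01, protocol=_THREE_DAYS, n_replicates=6)
        for K in K_levels for V0 in V0_levels
    ]
    return ExperimentDesign("clone_typing_factorial", treatments)


BUNDLED_DESIGNS = {
    "inoculum_sweep": inoculum_sweep,
    "inoculum_sweep_moi": inoculum_sweep_moi,
    "dose_capacity_grid": dose_capacity_grid,
    "transfer_dynamics": transfer_dynamics,
    "clone_typing_factorial": clone_typing_factorial,
}


def bundled_design(name: str) -> ExperimentDesign:
    """Look up a bundled design by name."""
    try:
        factory = BUNDLED_DESIGNS[name]
    except KeyError:
        raise ConfigError(
            f"unknown design {name!r}; bundled: {sorted(BUNDLED_DESIGNS)}") from None
    return factory()
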