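"""Pipeline experiments: dose sweeps, step responses and validation.

These are the computations behind the model's headline claims: the
dose-response of equilibrium peripheral insulin against observed human
clamp data, the decomposition of the intra-islet monomer pool into newly
secreted versus returned insulin, and the transient after a stepwise glucose
increase from the empty state.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    ZERO_STATE,
    IsletState,
    KineticParams,
    SimulationTrace,
    equilibrium,
    simulate_clamp,
    time_to_fraction,
)

__all__ = [
    "ValidationReport",
    "StepResponse",
    "dose_sweep",
    "step_response",
    "validate",
    "load_observed_dose_response",
]


def load_observed_dose_response() -> pd.DataFrame:
    """Observed peripheral insulin (pM) at clamped glucose levels, from human data."""
    ref = resources.files("isletins.data") / "observed_dose_response.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def dose_sweep(params: KineticParams, G_grid: Sequence[float]) -> pd.DataFrame:
    """Closed-form equilibria over a glucose grid, with source decomposition.

    Returns one row per glucose level with the equilibrium pools, the total
    monomer concentration and the new/peripheral fractions of that total
    (NaN where the total is zero).
    """
    grid = np.asarray(list(G_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("glucose grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("glucose values must be nonnegative")
    rows = []
    for G in grid:
        eq = equilibrium(params, float(G))
        total = eq.total_monomer
        if total > 0:
            new_frac, per_frac = eq.m / total, eq.ip / total
        else:
            new_frac = per_frac = np.nan
        rows.append(
            {
                "glucose_mM": float(G),
                "h_pM": eq.h,
                "d_pM": eq.d,
                "m_pM": eq.m,
                "Ip_pM": eq.ip,
                "total_monomer_pM": total,
                "new_fraction": new_frac,
                "peripheral_fraction": per_frac,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepResponse:
    """A step-response trace plus the time for returned insulin to near equilibrium."""

    trace: SimulationTrace
    equilibrium_state: IsletState
    #: First time (min) ip(t) is within 10% of ip*; None if not reached in the trace.
    time_to_90pct: float | None


def step_response(
    params: KineticParams,
    G: float,
    t_end: float,
    dt_out: float = 0.1,
    init: IsletState = ZERO_STATE,
) -> StepResponse:
    """Simulate a stepwise glucose increase from the empty islet state.

    The clamp steps from 0 to ``G`` mM at t = 0.  The reported timing is the
    first moment the returned peripheral pool comes within 10% of its
    equilibrium value (the trajectory approaches it monotonically, so this
    stands in for "reaching its maximum").
    """
    if not G > 0:
        raise ValueError("step glucose must be strictly positive")
    trace = simulate_clamp(params, G, t_end, dt_out=dt_out, init=init)
    eq = equilibrium(params, G)
    t90 = time_to_fraction(trace, "ip", 0.9, eq.ip)
    return StepResponse(trace=trace, equilibrium_state=eq, time_to_90pct=t90)


@dataclass(frozen=True)
class ValidationReport:
    """Predicted vs observed equilibrium peripheral insulin with relative errors."""

    table: pd.DataFrame
    max_abs_rel_error: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            self.table.to_string(index=False, float_format=lambda x: f"{x:.3f}")
            + f"\nmax |relative error| = {self.max_abs_rel_error:.3f}"
        )


def validate(
    params: KineticParams, observed: pd.DataFrame | None = None
) -> ValidationReport:
    """Compare predicted equilibrium peripheral insulin against observations.

    ``observed`` needs columns ``glucose_mM`` and ``insulin_pM``; by default
    the packaged human dose-response observations are used.  The prediction
    at each glucose level is the closed-form equilibrium ip*.
    """
    if observed is None:
        observed = load_observed_dose_response()
    if len(observed) == 0:
        raise ValueError("observed table must be nonempty")
    rows = []
    for _, rec in observed.iterrows():
        G = float(rec["glucose_mM"])
        obs = float(rec["insulin_pM"])
        pred = equilibrium(params, G).ip
        rel = (pred - obs) / obs if obs != 0 else np.nan
        rows.append(
            {
                "glucose_mM": G,
                "predicted_Ip_pM": pred,
                "observed_Ip_pM": obs,
                "rel_error": rel,
            }
        )
    table = pd.DataFrame(rows)
    return ValidationReport(
        table=table, max_abs_rel_error=float(table["rel_error"].abs().max())
    )
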