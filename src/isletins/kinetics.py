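"""Four-state kinetic model of the single-islet insulin microenvironment.

State variables (all in pM, i.e. pmol/L):

* ``h``  -- newly secreted insulin hexamers (counted as hexamer particles),
* ``d``  -- insulin dimers,
* ``m``  -- newly produced local insulin monomers,
* ``ip`` -- monomeric peripheral insulin returned to the islet by circulation.

Glucose-stimulated secretion delivers hexamers at rate ``s(G)/6`` (the Hill
secretion rate counts monomer equivalents; one hexamer carries six).  Each
hexamer dissolves into three dimers at rate ``p`` with a mass-action
re-aggregation correction ``q*d**3``; each dimer dissolves into two monomers
at rate ``p_hat`` with re-aggregation ``q_hat*m**2``.  Local monomer is lost
to the circulation at rate ``c`` and degraded at rate ``d_i``; returned
peripheral insulin is fed proportionally to local monomer production (rate
``k``) and degraded at the same ``d_i``:

    dh/dt  = s(G)/6 - p*(h - q*d**3)
    dd/dt  = 3*p*(h - q*d**3) - p_hat*(d - q_hat*m**2)
    dm/dt  = 2*p_hat*(d - q_hat*m**2) - (c + d_i)*m
    dip/dt = k*m - d_i*ip

The system is cooperative and has a unique, globally asymptotically stable
equilibrium with the closed form (in dependency order)

    m*  = s(G)/(c + d_i)
    ip* = (k/d_i)*m*
    d*  = s(G)/(2*p_hat) + q_hat*m*^2
    h*  = s(G)/(6*p) + q*d*^3

so the new-to-peripheral monomer ratio m*/ip* = d_i/k is independent of
glucose, and the total intra-islet monomer pool is m* + ip*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .secretion import HillParams, hill_rate

__all__ = [
    "KineticParams",
    "IsletState",
    "SimulationTrace",
    "ZERO_STATE",
    "rhs",
    "equilibrium",
    "simulate_clamp",
    "new_to_peripheral_ratio",
    "total_intra_islet_monomer",
    "time_to_fraction",
]

_COMPONENTS = ("h", "d", "m", "ip")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the four-state model plus the embedded Hill response.

    Attributes
    ----------
    p:
        Hexamer -> dimer dissolution rate (min^-1).
    q:
        Dimer -> hexamer aggregation coefficient (L^2/pmol^2).
    p_hat:
        Dimer -> monomer dissolution rate (min^-1); a dimer splits faster
        than a hexamer does, so ``p_hat > p`` is enforced.
    q_hat:
        Monomer -> dimer aggregation coefficient (L/pmol).
    d_i:
        Insulin degradation rate, applied to both local and peripheral
        monomer (min^-1).
    c:
        Transfer rate of local monomer out to the peripheral circulation
        (min^-1).
    k:
        Return coefficient coupling local monomer production to the returned
        peripheral pool (min^-1).
    hill:
        Parameters of the glucose -> secretion-rate dose response.
    provenance:
        Optional free-text provenance per parameter; ignored in comparisons.
    """

    p: float
    q: float
    p_hat: float
    q_hat: float
    d_i: float
    c: float
    k: float
    hill: HillParams
    provenance: Mapping[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("p", "p_hat", "d_i", "c", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        for name in ("q", "q_hat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if not self.p_hat > self.p:
            raise ValueError(
                f"p_hat must exceed p (dimers dissolve faster than hexamers); "
                f"got p_hat={self.p_hat!r}, p={self.p!r}"
            )

    def secretion_rate(self, G: float) -> float:
        """Monomer-equivalent secretion rate s(G) in pM/min."""
        return hill_rate(G, self.hill)


@dataclass(frozen=True)
class IsletState:
    """Concentrations (pM) of the four insulin pools; all nonnegative."""

    h: float
    d: float
    m: float
    ip: float

    def __post_init__(self) -> None:
        for name in _COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be nonnegative, got {getattr(self, name)!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.h, self.d, self.m, self.ip], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "IsletState":
        h, d, m, ip = (float(v) for v in y)
        return cls(h=h, d=d, m=m, ip=ip)

    @property
    def total_monomer(self) -> float:
        """Total intra-islet monomeric insulin, new plus returned (pM)."""
        return self.m + self.ip


ZERO_STATE = IsletState(0.0, 0.0, 0.0, 0.0)


def _rhs_array(y: np.ndarray, G: float, params: KineticParams) -> np.ndarray:
    # Unchecked core used by the integrator (tolerates tiny solver negatives).
    h, d, m, ip = y
    s = params.secretion_rate(G)
    hex_to_dim = params.p * (h - params.q * d**3)
    dim_to_mon = params.p_hat * (d - params.q_hat * m**2)
    return np.array(
        [
            s / 6.0 - hex_to_dim,
            3.0 * hex_to_dim - dim_to_mon,
            2.0 * dim_to_mon - (params.c + params.d_i) * m,
            params.k * m - params.d_i * ip,
        ]
    )


def rhs(state: IsletState, G: float, params: KineticParams) -> np.ndarray:
    """Time derivative (pM/min) of the four pools, ordered (h, d, m, ip).

    Stoichiometry: one hexamer yields three dimers, one dimer yields two
    monomers; secretion enters the hexamer pool as s(G)/6.
    """
    if G < 0:
        raise ValueError("glucose must be nonnegative")
    return _rhs_array(state.to_array(), G, params)


def equilibrium(params: KineticParams, G: float) -> IsletState:
    """Closed-form unique equilibrium of the model at clamped glucose ``G``."""
    if G < 0:
        raise ValueError("glucose must be nonnegative")
    s = params.secretion_rate(G)
    m = s / (params.c + params.d_i)
    ip = (params.k / params.d_i) * m
    d = s / (2.0 * params.p_hat) + params.q_hat * m**2
    h = s / (6.0 * params.p) + params.q * d**3
    return IsletState(h=h, d=d, m=m, ip=ip)


@dataclass(frozen=True)
class SimulationTrace:
    """Time-indexed trajectory of the four pools under a clamped-glucose protocol."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 4), columns (h, d, m, ip)
    glucose: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or y.shape != (len(t), 4):
            raise ValueError("trace requires t of shape (n,) and y of shape (n, 4)")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def component(self, name: str) -> np.ndarray:
        if name == "total":
            return self.y[:, 2] + self.y[:, 3]
        try:
            return self.y[:, _COMPONENTS.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown component {name!r}; expected one of {_COMPONENTS + ('total',)}"
            ) from None

    @property
    def final_state(self) -> IsletState:
        return IsletState.from_array(np.clip(self.y[-1], 0.0, None))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "h_pM": self.y[:, 0],
                "d_pM": self.y[:, 1],
                "m_pM": self.y[:, 2],
                "Ip_pM": self.y[:, 3],
                "total_monomer_pM": self.y[:, 2] + self.y[:, 3],
                "glucose_mM": self.glucose,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_clamp(
    params: KineticParams,
    G: float,
    t_end: float,
    dt_out: float = 0.5,
    init: IsletState = ZERO_STATE,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationTrace:
    """Integrate the model at clamped glucose ``G`` from ``init`` until ``t_end``.

    Uses an adaptive stiff-capable integrator (LSODA) with tight tolerances;
    output is sampled on a uniform grid of spacing ``dt_out`` minutes.

    Raises
    ------
    RuntimeError
        If the solver fails; the message carries the solver diagnostics.
    """
    if not t_end > 0:
        raise ValueError("t_end must be strictly positive")
    if not dt_out > 0:
        raise ValueError("dt_out must be strictly positive")
    if G < 0:
        raise ValueError("glucose must be nonnegative")
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(
        lambda _t, y: _rhs_array(y, G, params),
        (0.0, t_end),
        init.to_array(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return SimulationTrace(t=sol.t, y=sol.y.T, glucose=float(G))


def new_to_peripheral_ratio(params: KineticParams) -> float:
    """Equilibrium ratio m*/ip* of new to returned monomer; equals d_i/k.

    Glucose-independent: both pools scale linearly with the secretion rate.
    """
    return params.d_i / params.k


def total_intra_islet_monomer(params: KineticParams, G: float) -> float:
    """Equilibrium total monomeric insulin m* + ip* (pM) at clamped glucose ``G``."""
    eq = equilibrium(params, G)
    return eq.total_monomer


def time_to_fraction(
    trace: SimulationTrace,
    component: str,
    fraction: float,
    reference: float,
) -> float | None:
    """First time (min) a trace component comes within ``(1-fraction)*reference`` of ``reference``.

    Linear interpolation between output points locates the crossing; returns
    ``None`` if the band is never entered within the trace ("not reached").
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    vals = trace.component(component)
    tol = (1.0 - fraction) * abs(reference)
    dist = np.abs(vals - reference)
    inside = dist <= tol
    if not inside.any():
        return None
    i = int(np.argmax(inside))
    if i == 0:
        return float(trace.t[0])
    # interpolate |x - ref| across the bracketing interval
    d0, d1 = dist[i - 1], dist[i]
    t0, t1 = trace.t[i - 1], trace.t[i]
    if d0 == d1:
        return float(t1)
    frac = (d0 - tol) / (d0 - d1)
    return float(t0 + frac * (t1 - t0))


def with_rates(params: KineticParams, **rates: float) -> KineticParams:
    """Return a copy of ``params`` with selected rate constants replaced."""
    return replace(params, **rates)
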