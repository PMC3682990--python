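"""Synthetic inputs with the statistical structure the analysis assumes.

Everything here is a pure function of its arguments and a seed: noisy
secretion-rate datasets drawn from a known Hill curve (for parameter-recovery
studies), random nonnegative initial states (for positivity/stability
property suites), and log-uniform multiplicative parameter perturbations
(for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .kinetics import IsletState, KineticParams
from .secretion import HillParams, SecretionDataset, hill_rate

__all__ = [
    "SynthSpec",
    "gen_secretion_data",
    "gen_initial_states",
    "perturb_params",
]


@dataclass(frozen=True)
class SynthSpec:
    """Design of a synthetic secretion-rate dataset.

    Rates are the Hill curve evaluated at the design points plus additive
    Gaussian noise (sd ``noise_sd`` pM/min), truncated at zero; each
    replicate repeats the whole design.
    """

    hill: HillParams
    glucose: tuple[float, ...] = (3.0, 4.0, 5.0, 7.0, 9.0, 16.5, 25.0)
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(g <= 0 for g in self.glucose):
            raise ValueError("design glucose values must be strictly positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def gen_secretion_data(spec: SynthSpec) -> SecretionDataset:
    """Draw a noisy secretion dataset from the Hill curve in ``spec``.

    Deterministic given the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    g = np.tile(np.asarray(spec.glucose, dtype=float), spec.n_replicates)
    clean = hill_rate(g, spec.hill)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=g.shape) if spec.noise_sd > 0 else clean
    rates = np.clip(noisy, 0.0, None)
    prov = tuple(f"synthetic (seed={spec.seed}, sd={spec.noise_sd})" for _ in g)
    return SecretionDataset.from_arrays(g, rates, prov)


def gen_initial_states(
    n: int, upper_bound: float, seed: int = 0
) -> list[IsletState]:
    """``n`` random states with components uniform on [0, upper_bound] pM."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not upper_bound >= 0:
        raise ValueError("upper_bound must be nonnegative")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, upper_bound, size=(n, 4))
    return [IsletState.from_array(row) for row in draws]


def perturb_params(
    params: KineticParams,
    factor_bounds: Mapping[str, tuple[float, float]],
    seed: int = 0,
) -> KineticParams:
    """Multiplicatively perturb selected rate constants, log-uniformly.

    ``factor_bounds`` maps rate names (any of ``p, q, p_hat, q_hat, d_i, c,
    k``) to (low, high) multiplicative factor bounds; each named rate is
    multiplied by exp(U(log low, log high)).  The perturbed set must still
    satisfy the parameter invariants (in particular p_hat > p), otherwise a
    ValueError propagates.
    """
    allowed = {"p", "q", "p_hat", "q_hat", "d_i", "c", "k"}
    unknown = set(factor_bounds) - allowed
    if unknown:
        raise ValueError(f"cannot perturb unknown rates: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    for name, (lo, hi) in factor_bounds.items():
        if not (0 < lo <= hi):
            raise ValueError(f"invalid factor bounds for {name}: ({lo}, {hi})")
        factor = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        updates[name] = getattr(params, name) * factor
    return replace(params, **updates)
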