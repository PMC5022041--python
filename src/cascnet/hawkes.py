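"""Univariate Hawkes process: linear original and refractory-revised forms.

The linear self-exciting process has per-capita intensity

    lambda(t) = rho + (R0 / N) * sum_k h(t - t_k)

summed over all past population events, so each event spawns R0 expected
descendants and the mean rate is rho / (1 - R0), diverging at R0 = 1.  The
revised form silences each individual for a refractory window 1/gamma after
it fires, multiplying the drive by the available fraction (1 - r(t)); its
mean rate equals gamma * i_inf of the spontaneously activated SIS model with
beta = R0 * gamma, removing the divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .epidemic import SISParams, sis_equilibrium
from .events import EventSeries

__all__ = ["Kernel", "HawkesParams", "hawkes_mean_rate", "simulate_hawkes"]


@dataclass(frozen=True)
class Kernel:
    """Causal, unit-integral excitation kernel.

    Only the exponential family is provided: h(t) = exp(-t / tau) / tau for
    t >= 0, zero before.  The SN critical point does not depend on the
    kernel shape, so tau matters only for the fluctuation timescale.
    """

    tau: float = 1.0
    family: str = "exponential"

    def __post_init__(self) -> None:
        if self.family != "exponential":
            raise ValueError(f"unsupported kernel family: {self.family}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / self.tau) / self.tau, 0.0)

    def integral(self, upto: float = np.inf) -> float:
        """Integral of h over [0, upto]; 1 in the limit (normalization)."""
        return 1.0 - math.exp(-upto / self.tau) if np.isfinite(upto) else 1.0


@dataclass(frozen=True)
class HawkesParams:
    """Base rate, reproduction ratio, refractory period and kernel.

    ``gamma = inf`` (zero refractory period) selects the original linear
    model; finite gamma the revised one.
    """

    rho: float
    R0: float
    gamma: float = math.inf
    kernel: Kernel = field(default_factory=Kernel)

    def __post_init__(self) -> None:
        if self.rho < 0 or not np.isfinite(self.rho):
            raise ValueError("rho must be finite and non-negative")
        if not (0.0 <= self.R0):
            raise ValueError("R0 must be non-negative")
        if not self.revised and self.R0 >= 1.0:
            raise ValueError("original model requires R0 < 1 (mean rate diverges)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive (or inf for no refractoriness)")

    @property
    def revised(self) -> bool:
        return np.isfinite(self.gamma)


def hawkes_mean_rate(params: HawkesParams) -> float:
    """Analytic per-capita mean event rate.

    Original model: rho / (1 - R0).  Revised model: gamma * i_inf of the
    spontaneously activated SIS model with beta = R0 * gamma (the two models
    share their mean-field equilibrium).
    """
    if not params.revised:
        return params.rho / (1.0 - params.R0)
    sis = SISParams(beta=params.R0 * params.gamma, gamma=params.gamma, rho=params.rho)
    return params.gamma * sis_equilibrium(sis)


def simulate_hawkes(
    params: HawkesParams,
    N: int = 1000,
    dt: float = 0.01,
    T: float = 2000.0,
    seed: int = 0,
) -> EventSeries:
    """Simulate by Bernoulli trials with probability lambda(t) dt per step.

    ``N`` individuals share the per-capita intensity; the exponential kernel
    is updated recursively (O(1) per step).  In the revised model each firing
    individual is refractory for a deterministic window 1/gamma.  Raises if
    the per-trial probability reaches 1 (decrease dt).
    """
    if N < 1 or dt <= 0 or T <= 0:
        raise ValueError("N, dt, T must be positive")
    n_steps = int(round(T / dt))
    refr_steps = int(round(1.0 / (params.gamma * dt))) if params.revised else 0
    times, _counts, status = _kernels.hawkes_univariate(
        N, params.rho, params.R0, params.kernel.tau, refr_steps, dt, n_steps,
        seed % 2**31,
    )
    if status != 0:
        raise RuntimeError("lambda * dt reached 1 during the run; decrease dt")
    return EventSeries(times, T, None)
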