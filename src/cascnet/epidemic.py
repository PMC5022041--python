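"""Mean-field SIS dynamics with spontaneous activation.

The classic susceptible-infected-susceptible model loses all activity below
the epidemic threshold R0 = beta/gamma = 1.  Adding a spontaneous-activation
inflow ``rho`` from the susceptible pool keeps the infected fraction positive
at every R0 and softens the transition:

    di/dt = -gamma * i + (1 - i) * (rho + beta * i)

The equilibrium ``i_inf`` of this one-dimensional flow is the positive root
of a quadratic, and ``gamma * i_inf`` equals the long-run mean event rate of
the refractory-revised Hawkes process with the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["SISParams", "sis_equilibrium", "sis_integrate"]


@dataclass(frozen=True)
class SISParams:
    """Rates of the spontaneously activated SIS model.

    Parameters
    ----------
    beta
        Infection rate per infected contact (1/time).
    gamma
        Recovery rate (1/time); the refractory period is ``1/gamma``.
    rho
        Spontaneous activation rate of susceptibles (1/time).
    """

    beta: float
    gamma: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def R0(self) -> float:
        """Reproduction ratio beta/gamma."""
        return self.beta / self.gamma


def _drift(i: float, p: SISParams) -> float:
    return -p.gamma * i + (1.0 - i) * (p.rho + p.beta * i)


def sis_equilibrium(params: SISParams) -> float:
    """Equilibrium infected fraction ``i_inf`` in [0, 1].

    Solves ``-gamma i + (1 - i)(rho + beta i) = 0``, i.e. the quadratic
    ``beta i^2 + (gamma + rho - beta) i - rho = 0``, and returns its root in
    the unit interval.  For ``rho = 0`` this reduces to the classic SIS
    equilibrium: 0 for R0 <= 1, otherwise ``1 - 1/R0``.
    """
    b, g, r = params.beta, params.gamma, params.rho
    if r == 0.0:
        return 0.0 if b <= g else 1.0 - g / b
    # beta i^2 + (gamma + rho - beta) i - rho = 0; pick the root form without
    # cancellation: conjugate form for p >= 0 (stable as beta -> 0), standard
    # form for p < 0 (stable as rho -> 0 in the supercritical branch)
    p = g + r - b
    disc = np.sqrt(p * p + 4.0 * b * r)
    i = 2.0 * r / (p + disc) if p >= 0 else (disc - p) / (2.0 * b)
    if not (0.0 <= i <= 1.0):
        # numerically marginal discriminant: fall back to bisection on the drift
        from scipy.optimize import brentq

        i = brentq(lambda x: _drift(x, params), 0.0, 1.0, xtol=1e-14)
    return float(min(max(i, 0.0), 1.0))


def sis_integrate(
    params: SISParams,
    i0: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Integrate the mean-field flow from ``i(0) = i0``, reporting on ``t_grid``.

    Uses adaptive Runge-Kutta (RK45, atol 1e-9); the dynamics are
    one-dimensional and non-stiff.  Returns ``i(t)`` on the grid, clipped to
    [0, 1] against roundoff (the flow itself is forward-invariant there).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (0.0 <= i0 <= 1.0):
        raise ValueError("i0 must lie in [0, 1]")
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must be non-negative (i0 is the state at t = 0)")
    sol = solve_ivp(
        lambda t, y: _drift(y[0], params),
        (0.0, t_grid[-1]),
        [i0],
        t_eval=t_grid,
        method="RK45",
        rtol=1e-9,
        atol=1e-9,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, 1.0)
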