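"""Agent-level stochastic SIS process and the SN-transition sweep.

The microscopic counterpart of the mean-field model in :mod:`.epidemic`: in
every step of width ``dt``, each of the ``N`` individuals draws a Bernoulli
trial -- susceptibles become infected with probability ``(beta i + rho) dt``
(``i`` the infected fraction at the start of the step), infecteds recover
with probability ``gamma dt``.  Infection (S -> I) times, tagged by
individual, form the event series; recoveries are silent.

``sweep_critical_R`` locates the stationary-nonstationary transition: it
simulates across a grid of reproduction ratios, pools the infection times of
each run, and finds where the inverse optimal bin size departs from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .epidemic import SISParams
from .events import EventSeries
from .sn_detect import optimal_binsize

__all__ = ["MarkovSimConfig", "MarkovResult", "simulate_markov", "SweepResult", "sweep_critical_R"]


@dataclass(frozen=True)
class MarkovSimConfig:
    """Configuration of one agent-level SIS run."""

    params: SISParams
    N: int
    T: float
    dt: float = 0.01
    i0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if not (0.0 <= self.i0 <= 1.0):
            raise ValueError("i0 must lie in [0, 1]")
        p = self.params
        if (p.beta + p.rho) * self.dt >= 1.0 or p.gamma * self.dt >= 1.0:
            raise ValueError(
                "per-step probabilities reach 1: decrease dt "
                f"((beta+rho)*dt={(p.beta + p.rho) * self.dt:.3g}, "
                f"gamma*dt={p.gamma * self.dt:.3g})"
            )


@dataclass
class MarkovResult:
    events: EventSeries
    infected_count: np.ndarray  # per step, after the update
    config: MarkovSimConfig = field(repr=False)

    @property
    def infected_fraction(self) -> np.ndarray:
        return self.infected_count / self.config.N


def simulate_markov(config: MarkovSimConfig) -> MarkovResult:
    """Run the synchronous-update SIS Markov chain; reproducible per seed."""
    p = config.params
    n_steps = int(round(config.T / config.dt))
    n_inf0 = int(round(config.i0 * config.N))
    times, ids, traj, status = _kernels.markov_sis(
        config.N, p.beta, p.gamma, p.rho, config.dt, n_steps, n_inf0,
        config.seed % 2**31,
    )
    if status != 0:
        raise RuntimeError("per-step probability reached 1 during the run; decrease dt")
    events = EventSeries(times, config.T, ids)
    return MarkovResult(events, traj, config)


@dataclass
class SweepResult:
    """Outcome of an SN-transition sweep over reproduction ratios."""

    R0_grid: np.ndarray
    inv_delta_star: np.ndarray       # replicate x grid matrix of 1/Delta*
    median_inv_delta_star: np.ndarray
    usable: np.ndarray               # per grid point: enough events in all replicates
    R_c: float                       # smallest grid R0 with median 1/Delta* > 0 (NaN if none)

    @property
    def transition_found(self) -> bool:
        return np.isfinite(self.R_c)


def sweep_critical_R(
    gamma: float,
    rho: float,
    N: int,
    R0_grid: np.ndarray,
    replicates: int = 5,
    seed: int = 0,
    T: float = 2000.0,
    dt: float = 0.01,
    min_events: int = 50,
) -> SweepResult:
    """Locate the SN transition of the SIS Markov process on an R0 grid.

    For each reproduction ratio, runs ``replicates`` seeded simulations,
    pools all infection times per run, and applies the optimal-bin-size
    detector.  The estimated critical point is the smallest grid value whose
    median inverse optimal bin size exceeds zero (the divergence threshold);
    NaN when the whole grid stays stationary.
    """
    R0_grid = np.asarray(R0_grid, dtype=float)
    if np.any(np.diff(R0_grid) <= 0):
        raise ValueError("R0_grid must be strictly increasing")
    if np.any(R0_grid >= 1.0):
        raise ValueError("sweep requires subthreshold ratios R0 < 1")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(R0_grid.size * replicates) % 2**31
    inv = np.full((replicates, R0_grid.size), np.nan)
    usable = np.ones(R0_grid.size, dtype=bool)
    for g, R0 in enumerate(R0_grid):
        params = SISParams(beta=R0 * gamma, gamma=gamma, rho=rho)
        for r in range(replicates):
            cfg = MarkovSimConfig(params, N=N, T=T, dt=dt,
                                  seed=int(child[g * replicates + r]))
            res = simulate_markov(cfg)
            if res.events.n_events < min_events:
                import warnings

                warnings.warn(
                    f"R0={R0:g}: only {res.events.n_events} events "
                    f"(< {min_events}); grid point marked unusable",
                    stacklevel=2,
                )
                usable[g] = False
                continue
            inv[r, g] = optimal_binsize(res.events.pooled()).inv_delta_star
    with np.errstate(all="ignore"):
        med = np.nanmedian(inv, axis=0)
    departed = usable & (med > 0)
    R_c = float(R0_grid[np.argmax(departed)]) if departed.any() else float("nan")
    return SweepResult(R0_grid, inv, med, usable, R_c)
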