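"""Mutually exciting Hawkes process on a weighted directed network.

Each node fires events at rate

    lambda_i(t) = rho_i + sum_j A[i, j] * sum_k h(t - t_k^(j)),

so ``A[i, j]`` measures how strongly events at node j excite node i.  The
simulation performs one Bernoulli trial per node per step of width dt, with
the exponential kernel carried recursively per source node.  Stationarity of
the mean rates requires the spectral radius of A below 1; the mean rates then
equal the Leontief prediction ``L rho`` of :mod:`.cascade`.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .events import EventSeries
from .hawkes import Kernel
from .network import Network

__all__ = ["simulate_multivariate"]


def simulate_multivariate(
    net: Network,
    kernel: Kernel | None = None,
    dt: float = 0.01,
    T: float = 1000.0,
    seed: int = 0,
) -> EventSeries:
    """Simulate the network process; events are tagged with their node id.

    Raises on a supercritical interaction matrix (spectral radius >= 1) and
    when any per-step probability ``lambda_i dt`` reaches 1.
    """
    if kernel is None:
        kernel = Kernel()
    sr = net.spectral_radius()
    if sr >= 1.0:
        raise ValueError(f"supercritical network: spectral radius {sr:.6g} >= 1")
    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    n_steps = int(round(T / dt))
    times, ids, status = _kernels.hawkes_multivariate(
        net.A, net.rho, kernel.tau, dt, n_steps, seed % 2**31
    )
    if status != 0:
        raise RuntimeError("lambda_i * dt reached 1 during the run; decrease dt")
    return EventSeries(times, T, ids)
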