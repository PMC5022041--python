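"""Cascading condition for multivariate self-exciting networks.

For a linear multivariate Hawkes process on a network ``A`` with base rates
``rho``, the stationary mean rates are ``<lambda> = L rho`` with
``L = (I - A)^{-1}`` the Leontief inverse, which sums direct and indirect
excitation along all paths.  The superposed event stream of the whole
population is nonstationary -- it exhibits visible rate cascades -- exactly
when the zero-frequency power of the summed rate fluctuation exceeds twice
the mean rate.  That criterion reduces to a single scalar

    C = sum_i u_i^2 <lambda_i> / sum_i <lambda_i>,    u_i = sum_k L_ki,

with threshold 2: cascading iff C > 2.  On a fully connected uniform network
C = 1/(1 - R0)^2, so the critical reproduction ratio is R_c = 1 - 1/sqrt(2).

This module also provides the exchange machinery used by the rewiring
optimizer: the first-order exchange score H and exact Delta-C evaluation via
Sherman-Morrison rank-1 updates of L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .network import Network

__all__ = [
    "CascadeReport",
    "leontief",
    "mean_rates",
    "cascading_C",
    "cascade_report",
    "critical_R",
    "solve_C_equals_2",
    "exchange_score_H",
    "exact_exchange_deltaC",
]

#: critical value of the cascading statistic
C_CRITICAL = 2.0

#: SN critical reproduction ratio of the uniform (and any regular) network
R_C_UNIFORM = 1.0 - 1.0 / math.sqrt(2.0)


@dataclass
class CascadeReport:
    """Mean rates, Leontief column sums, and the cascading verdict."""

    lambda_mean: np.ndarray  # per-node mean rates <lambda_i>
    colsum_L: np.ndarray     # u_i = sum_k L_ki
    C: float
    nonstationary: bool      # True iff C > 2

    @property
    def Lambda(self) -> np.ndarray:
        """diag(<lambda>) as a matrix."""
        return np.diag(self.lambda_mean)

    @property
    def total_rate(self) -> float:
        return float(self.lambda_mean.sum())


def _check_subcritical(net: Network) -> None:
    sr = net.spectral_radius()
    if sr >= 1.0:
        raise ValueError(
            f"interaction matrix is supercritical: spectral radius {sr:.6g} >= 1"
        )


def leontief(net: Network) -> np.ndarray:
    """Leontief inverse ``L = (I - A)^{-1}``; requires spectral radius < 1."""
    _check_subcritical(net)
    n = net.n_nodes
    L = np.linalg.inv(np.eye(n) - net.A)
    return L


def mean_rates(net: Network) -> np.ndarray:
    """Stationary mean rates ``<lambda> = L rho`` (solved, not inverted)."""
    n = net.n_nodes
    lam = np.linalg.solve(np.eye(n) - net.A, net.rho)
    if np.any(lam < net.rho - 1e-9 * (1.0 + np.abs(net.rho))):
        _check_subcritical(net)  # raises with the spectral radius
    return lam


def cascade_report(net: Network, check: bool = True) -> CascadeReport:
    """Compute ``<lambda>``, the Leontief column sums and the statistic C.

    ``u`` and ``<lambda>`` come from two linear solves with ``I - A`` (no
    explicit inverse).  With ``check=True`` the Leontief positivity
    ``u_i >= 1`` and ``<lambda_i> >= rho_i`` is verified and a supercritical
    matrix is reported by its spectral radius.
    """
    n = net.n_nodes
    if not np.any(net.rho > 0):
        raise ValueError("all base rates are zero: total rate vanishes, C undefined")
    M = np.eye(n) - net.A
    lam = np.linalg.solve(M, net.rho)
    u = np.linalg.solve(M.T, np.ones(n))
    if check and (np.any(u < 1.0 - 1e-9) or np.any(lam < net.rho - 1e-9 * (1 + net.rho))):
        _check_subcritical(net)
    C = float(np.sum(u * u * lam) / np.sum(lam))
    return CascadeReport(lam, u, C, C > C_CRITICAL)


def cascading_C(net: Network, check: bool = True) -> float:
    """The scalar cascading statistic C (see module docstring)."""
    return cascade_report(net, check=check).C


def solve_C_equals_2(
    C_of_r: Callable[[float], float],
    r_pole: float,
    tol: float = 1e-4,
) -> float:
    """Root of ``C(r) = 2`` on ``(0, r_pole)`` for an increasing C.

    ``r_pole`` is the supremum of admissible reproduction ratios (where the
    Leontief inverse blows up and C diverges).  Probes geometrically toward
    the pole to bracket the root, then applies Brent's method.  Returns NaN
    if C stays below 2 on the whole admissible range (no transition).
    """
    f = lambda r: C_of_r(r) - C_CRITICAL
    lo = 1e-9 * r_pole
    if f(lo) >= 0:
        return float(lo)
    hi = None
    for k in range(1, 40):
        r = r_pole * (1.0 - 0.5**k)
        try:
            val = f(r)
        except (ValueError, np.linalg.LinAlgError):
            break  # numerically at the pole already
        if val >= 0:
            hi = r
            break
        lo = r
    if hi is None:
        return math.nan
    return float(brentq(f, lo, hi, xtol=min(tol, 1e-6) * 1e-2))


def critical_R(
    net: Network | Callable[[float], Network],
    at_R0: float | None = None,
    tol: float = 1e-4,
) -> float:
    """Critical reproduction ratio solving ``C(R0) = 2``.

    Parameters
    ----------
    net
        Either a :class:`Network` whose weights scale linearly with the
        reproduction ratio (then ``at_R0`` must give the ratio the network
        was built with), or a callable ``R0 -> Network``.
    at_R0
        Reproduction ratio of the passed network (ignored for callables).
    tol
        Absolute tolerance on the returned ratio.

    Returns NaN when C never reaches 2 on the admissible range.
    """
    if isinstance(net, Network):
        if at_R0 is None or at_R0 <= 0:
            raise ValueError("at_R0 (positive) is required for a fixed network")
        B = net.A / at_R0
        rho = net.rho
        sr = float(np.max(np.abs(np.linalg.eigvals(B))))
        if sr == 0.0:
            return math.nan  # empty structure: C == 1 everywhere
        n = B.shape[0]
        I = np.eye(n)

        def C_of_r(r: float) -> float:
            M = I - r * B
            lam = np.linalg.solve(M, rho)
            u = np.linalg.solve(M.T, np.ones(n))
            return float(np.sum(u * u * lam) / np.sum(lam))

        return solve_C_equals_2(C_of_r, 1.0 / sr, tol=tol)
    builder = net
    sr = builder(1.0).spectral_radius()
    if sr == 0.0:
        return math.nan
    return solve_C_equals_2(
        lambda r: cascading_C(builder(r), check=False), 1.0 / sr, tol=tol
    )


# ---------------------------------------------------------------------------
# Exchange machinery


def exchange_score_H(report: CascadeReport, net: Network) -> np.ndarray:
    """First-order exchange score ``H_ij = (u_i^2 - C) rho_j + 2 u_j <lambda_j>``.

    Moving a connection from slot (i, j) to slot (i', j') changes C, to first
    order in the edge weight, proportionally to ``H_{i'j'} - H_{ij}``; the
    rewiring optimizer uses H to rank candidate exchanges before evaluating
    them exactly.
    """
    u = report.colsum_L
    lam = report.lambda_mean
    return np.outer(u * u - report.C, net.rho) + (2.0 * u * lam)[None, :]


def _apply_rank1(L: np.ndarray, u: np.ndarray, lam: np.ndarray,
                 a: int, b: int, w: float) -> None:
    """In-place Sherman-Morrison update for ``(I - A) -> (I - A) + w e_a e_b^T``.

    Removing edge weight ``w`` at A[a, b] corresponds to positive ``w``;
    adding uses ``-w``.  Updates L, its column sums u and the rates lam.
    """
    denom = 1.0 + w * L[b, a]
    if abs(denom) < 1e-12:
        raise np.linalg.LinAlgError("rank-1 update is singular (critical exchange)")
    c = w / denom
    col = L[:, a].copy()
    row = L[b, :].copy()
    L -= c * np.outer(col, row)
    u -= c * u[a] * row
    lam -= c * lam[b] * col


def _exchange_updates(net: Network, edge_out, edge_in) -> list[tuple[int, int, float]]:
    """The rank-1 update sequence realizing one connection exchange."""
    i, j = edge_out
    ip, jp = edge_in
    if (i, j) == (ip, jp):
        return []
    w = net.A[i, j]
    if w <= 0:
        raise ValueError(f"edge_out ({i},{j}) carries no connection")
    if ip == jp and not net.allow_self_loops:
        raise ValueError("exchange would create a self-loop")
    if net.A[ip, jp] != 0:
        raise ValueError(f"edge_in ({ip},{jp}) is already occupied")
    if net.directed:
        return [(i, j, +w), (ip, jp, -w)]
    # undirected: move the reciprocal pair atomically
    if {i, j} == {ip, jp}:
        return []
    if net.A[jp, ip] != 0:
        raise ValueError(f"reciprocal slot ({jp},{ip}) is already occupied")
    return [(i, j, +w), (j, i, +w), (ip, jp, -w), (jp, ip, -w)]


def exact_exchange_deltaC(
    net: Network,
    edge_out: tuple[int, int],
    edge_in: tuple[int, int],
    report: CascadeReport | None = None,
    L: np.ndarray | None = None,
) -> float:
    """Exact change in C from moving the connection at ``edge_out`` to ``edge_in``.

    Computed by Sherman-Morrison rank-1 updates of the Leontief inverse
    (a reciprocal pair of updates in undirected mode), which agrees with full
    recomputation to machine precision.  ``report``/``L`` may be supplied to
    avoid refactorization; the network itself is not modified.
    """
    updates = _exchange_updates(net, edge_out, edge_in)
    if report is None:
        report = cascade_report(net)
    if not updates:
        return 0.0
    if L is None:
        L = leontief(net)
    L = L.copy()
    u = report.colsum_L.copy()
    lam = report.lambda_mean.copy()
    for a, b, w in updates:
        _apply_rank1(L, u, lam, a, b, w)
    C_new = float(np.sum(u * u * lam) / np.sum(lam))
    return C_new - report.C
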