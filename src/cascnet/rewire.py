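"""Greedy reallocation of connections to raise or lower the cascading C.

One elementary move takes the weight of a present connection (i, j) and
places it on an empty slot (i', j'), conserving the number of connections.
Each step ranks candidate moves by the first-order exchange score H
(``cascade.exchange_score_H``), evaluates the change in C exactly on a
shortlist via Sherman-Morrison updates of the Leontief inverse, and applies
the best strictly improving move; the accepted-step C sequence is therefore
exactly monotone.  In undirected mode the reciprocal pair {ij, ji} moves
atomically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cascade import (
    C_CRITICAL,
    CascadeReport,
    _apply_rank1,
    cascade_report,
    exchange_score_H,
    leontief,
)
from .netbuild import clustering_coefficient
from .network import Network

__all__ = ["RewireStep", "RewireTrajectory", "rewire_optimize", "rewire_report"]


@dataclass(frozen=True)
class RewireStep:
    edge_out: tuple[int, int]
    edge_in: tuple[int, int]
    C: float                     # C after applying the move
    clustering: float            # average clustering after the move (NaN if untracked)


@dataclass
class RewireTrajectory:
    """Accepted moves of one greedy run, plus the start and final states."""

    mode: str
    C_start: float
    clustering_start: float
    steps: list[RewireStep] = field(default_factory=list)
    converged: bool = False
    final_net: Network | None = None

    @property
    def C_series(self) -> np.ndarray:
        return np.array([self.C_start] + [s.C for s in self.steps])

    @property
    def clustering_series(self) -> np.ndarray:
        return np.array([self.clustering_start] + [s.clustering for s in self.steps])

    @property
    def C_max(self) -> float:
        return float(self.C_series.max())

    @property
    def C_min(self) -> float:
        return float(self.C_series.min())


def _batch_deltaC(L, u, lam, w, i, j, ip, jp):
    """Exact new C for a batch of directed moves (remove (i,j), add (ip,jp)).

    Vectorized two-stage Sherman-Morrison: each row of the returned array is
    the C after one candidate move.  Invalid moves (singular update or a
    supercritical result, detected by loss of Leontief positivity) get NaN.
    """
    LT = L.T
    d1 = 1.0 + w * L[j, i]
    with np.errstate(all="ignore"):
        c1 = w / d1
        u1 = u[None, :] - (c1 * u[i])[:, None] * L[j, :]
        lam1 = lam[None, :] - (c1 * lam[j])[:, None] * LT[i, :]
        L1_jp_row = L[jp, :] - (c1 * L[jp, i])[:, None] * L[j, :]
        L1_ip_col = LT[ip, :] - (c1 * L[j, ip])[:, None] * LT[i, :]
        L1_jpip = L[jp, ip] - c1 * L[jp, i] * L[j, ip]
        d2 = 1.0 - w * L1_jpip
        c2 = -w / d2
        rows = np.arange(len(i))
        u2 = u1 - (c2 * u1[rows, ip])[:, None] * L1_jp_row
        lam2 = lam1 - (c2 * lam1[rows, jp])[:, None] * L1_ip_col
        C2 = np.sum(u2 * u2 * lam2, axis=1) / np.sum(lam2, axis=1)
        bad = (
            (np.abs(d1) < 1e-10)
            | (np.abs(d2) < 1e-10)
            | (np.min(u2, axis=1) < 1.0 - 1e-7)
            | (np.min(lam2, axis=1) <= 0)
        )
    C2[bad] = np.nan
    return C2


def _shortlist(score: np.ndarray, mask: np.ndarray, k: int, largest: bool):
    """Indices of the k best (largest or smallest) scores within a mask."""
    flat = np.where(mask.ravel(), score.ravel(), -np.inf if largest else np.inf)
    k = min(k, int(mask.sum()))
    if k == 0:
        return np.empty(0, dtype=int)
    order = np.argpartition(-flat if largest else flat, k - 1)[:k]
    return order


def rewire_optimize(
    net: Network,
    mode: str = "ascent",
    candidate_budget: int = 256,
    max_steps: int = 1000,
    seed: int = 0,
    track_clustering: bool = True,
    refresh_every: int = 200,
) -> RewireTrajectory:
    """Greedy steepest ascent/descent on C by exchanging connections.

    Parameters
    ----------
    net
        Starting network; its weights must be a single common value on
        present edges (the 0-1 convention), so moves are weight-preserving.
    mode
        ``ascent`` maximizes C (incite cascades), ``descent`` minimizes it.
    candidate_budget
        Shortlist size: ~sqrt(budget) removal slots x ~sqrt(budget) insertion
        slots ranked by the H score, each evaluated exactly.
    max_steps
        Upper bound on accepted moves.
    seed
        Recorded for provenance; the procedure itself is deterministic (ties
        in Delta-C break by lexicographic slot order).
    track_clustering
        Compute the average clustering coefficient after every step (costs
        one graph traversal per step).

    The run stops when no shortlisted move strictly improves C in the chosen
    direction (``converged=True``) or after ``max_steps``.
    """
    if mode not in ("ascent", "descent"):
        raise ValueError("mode must be 'ascent' or 'descent'")
    weights = net.A[net.A > 0]
    if weights.size == 0:
        raise ValueError("network has no connections to reallocate")
    w = float(weights[0])
    if not np.allclose(weights, w):
        raise ValueError("rewiring expects 0-1 connectivity (one common weight)")
    ascent = mode == "ascent"
    n = net.n_nodes
    A = net.A.copy()
    offdiag = ~np.eye(n, dtype=bool)
    L = leontief(net)
    u = np.linalg.solve((np.eye(n) - A).T, np.ones(n))
    lam = np.linalg.solve(np.eye(n) - A, net.rho)
    C = float(np.sum(u * u * lam) / np.sum(lam))
    clus = clustering_coefficient(net) if track_clustering else math.nan
    traj = RewireTrajectory(mode=mode, C_start=C, clustering_start=clus)
    k_each = max(1, int(math.isqrt(candidate_budget)))
    undirected = not net.directed

    def current_net() -> Network:
        return Network(A.copy(), net.rho.copy(), directed=net.directed,
                       meta=dict(net.meta))

    for step in range(max_steps):
        rep = CascadeReport(lam.copy(), u.copy(), C, C > C_CRITICAL)
        H = exchange_score_H(rep, net)
        present = (A > 0) & offdiag
        absent = (A == 0) & offdiag
        if undirected:
            upper = np.triu(np.ones((n, n), dtype=bool), 1)
            present &= upper
            absent &= upper
            score = H + H.T
        else:
            score = H
        # ascent: remove low-H slots, insert at high-H slots (and vice versa)
        rm = _shortlist(score, present, k_each, largest=not ascent)
        ins = _shortlist(score, absent, k_each, largest=ascent)
        if rm.size == 0 or ins.size == 0:
            traj.converged = True
            break
        rm_i, rm_j = np.unravel_index(rm, (n, n))
        in_i, in_j = np.unravel_index(ins, (n, n))
        # cross product of the two shortlists
        i = np.repeat(rm_i, in_i.size)
        j = np.repeat(rm_j, in_i.size)
        ip = np.tile(in_i, rm_i.size)
        jp = np.tile(in_j, rm_j.size)
        if undirected:
            C_new = _batch_deltaC_undirected(L, u, lam, w, i, j, ip, jp)
        else:
            C_new = _batch_deltaC(L, u, lam, w, i, j, ip, jp)
        dC = C_new - C
        good = np.isfinite(dC) & ((dC > 1e-13) if ascent else (dC < -1e-13))
        if not good.any():
            traj.converged = True
            break
        cand = np.nonzero(good)[0]
        best_val = dC[cand].max() if ascent else dC[cand].min()
        at_best = cand[np.isclose(dC[cand], best_val, rtol=0, atol=1e-15)]
        # deterministic tie-break: lexicographically smallest (i, j, i', j')
        keys = np.stack([i[at_best], j[at_best], ip[at_best], jp[at_best]])
        b = at_best[np.lexsort(keys[::-1])[0]]
        bi, bj, bip, bjp = int(i[b]), int(j[b]), int(ip[b]), int(jp[b])
        updates = [(bi, bj, +w), (bip, bjp, -w)]
        if undirected:
            updates = [(bi, bj, +w), (bj, bi, +w), (bip, bjp, -w), (bjp, bip, -w)]
        for a, bb, ww in updates:
            _apply_rank1(L, u, lam, a, bb, ww)
            A[a, bb] += -ww  # +w update to (I - A) means the entry was removed
        C = float(np.sum(u * u * lam) / np.sum(lam))
        if (step + 1) % refresh_every == 0:
            # refactorize to shed accumulated rank-1 roundoff
            M = np.eye(n) - A
            L = np.linalg.inv(M)
            u = np.linalg.solve(M.T, np.ones(n))
            lam = np.linalg.solve(M, net.rho)
            C = float(np.sum(u * u * lam) / np.sum(lam))
        clus = clustering_coefficient(current_net()) if track_clustering else math.nan
        traj.steps.append(RewireStep((bi, bj), (bip, bjp), C, clus))
    traj.final_net = current_net()
    traj.final_net.meta["rewire_seed"] = seed
    return traj


def _batch_deltaC_undirected(L, u, lam, w, i, j, ip, jp):
    """Exact new C for reciprocal-pair moves, by per-candidate rank-1 chains."""
    out = np.full(i.shape, np.nan)
    for t in range(i.size):
        Lc, uc, lc = L.copy(), u.copy(), lam.copy()
        try:
            for a, b, ww in [
                (i[t], j[t], +w), (j[t], i[t], +w),
                (ip[t], jp[t], -w), (jp[t], ip[t], -w),
            ]:
                _apply_rank1(Lc, uc, lc, a, b, ww)
        except np.linalg.LinAlgError:
            continue
        if uc.min() < 1.0 - 1e-7 or lc.min() <= 0:
            continue
        out[t] = float(np.sum(uc * uc * lc) / np.sum(lc))
    return out


@dataclass
class RewireSummary:
    mode: str
    n_steps: int
    C_series: np.ndarray
    clustering_series: np.ndarray
    crossing_step: int | None  # first step where C crosses the critical value


def rewire_report(traj: RewireTrajectory) -> RewireSummary:
    """Aligned per-step series and the first crossing of C = 2, if any."""
    Cs = traj.C_series
    above = Cs > C_CRITICAL
    crossing = None
    flips = np.nonzero(above[1:] != above[:-1])[0]
    if flips.size:
        crossing = int(flips[0] + 1)
    return RewireSummary(traj.mode, len(traj.steps), Cs, traj.clustering_series, crossing)
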