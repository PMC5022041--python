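"""Network generators and analytic special cases.

All generators follow the 0-1 connectivity convention: a present edge
carries weight ``R0 / (N c)``, where ``c`` is the fraction of ordered node
pairs connected (diagonal pairs included in the denominator), so that the
average column sum -- the per-event expected number of induced events --
equals R0 regardless of density.

Besides the standard models (uniform, Erdos-Renyi, Barabasi-Albert,
Watts-Strogatz, regular ring lattice, and the bundled Zachary karate club),
this module builds the four analytically tractable "extreme" block
configurations that bound the SN critical point, evaluates their cascading
statistic in O(1) through the block structure, and computes the degree-based
mean-field critical point for heterogeneous (e.g. scale-free) degree
sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .cascade import C_CRITICAL, R_C_UNIFORM, solve_C_equals_2
from .network import Network

__all__ = [
    "make_network",
    "karate_club",
    "ExtremeConfigSpec",
    "make_extreme",
    "extreme_connection_fraction",
    "extreme_Rc",
    "extreme_crossover",
    "scale_free_Rc_meanfield",
    "clustering_coefficient",
]


def _weight(R0: float, N: int, c: float) -> float:
    if not (0 < c <= 1):
        raise ValueError(f"connection fraction must lie in (0, 1], got {c}")
    return R0 / (N * c)


def karate_club() -> nx.Graph:
    """The 34-node Zachary karate club graph from the bundled edge list."""
    path = resources.files("cascnet").joinpath("data/karate.edges")
    G = nx.Graph()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        u, v = (int(x) for x in line.split()[:2])
        G.add_edge(u - 1, v - 1)  # file is 1-based
    return G


def make_network(
    model: str,
    N: int | None = None,
    R0: float = 0.2,
    rho: float | np.ndarray = 0.5,
    c: float | None = None,
    k: int | None = None,
    p: float = 0.1,
    directed: bool = False,
    include_diagonal: bool = False,
    seed: int | None = None,
) -> Network:
    """Build a weighted interaction network of the requested family.

    Parameters
    ----------
    model
        One of ``uniform``, ``er``, ``ba``, ``ws``, ``ring``, ``karate``.
    N, c
        Node count and target fraction of ordered pairs connected.  For
        ``ba``/``ws``/``ring`` the degree ``k`` may be given instead of ``c``
        (``c = k / N``); ``ba`` attaches ``k // 2`` edges per new node so the
        mean degree is ~k.  ``karate`` fixes N = 34.
    directed
        Only meaningful for ``er``: sample ordered pairs independently of
        their reciprocal.  All other families are undirected (symmetric).
    include_diagonal
        ``uniform`` only: keep the self-excitation diagonal so the closed
        form C = 1/(1 - R0)^2 holds exactly at finite N.

    Every present edge carries weight ``R0 / (N c_realized)`` with
    ``c_realized`` the fraction actually built.
    """
    rng = np.random.default_rng(seed)
    if model == "karate":
        G = karate_club()
        N = G.number_of_nodes()
        A01 = nx.to_numpy_array(G, nodelist=range(N), dtype=float)
        directed = False
    elif model == "uniform":
        if N is None:
            raise ValueError("N is required")
        A01 = np.ones((N, N))
        if not include_diagonal:
            np.fill_diagonal(A01, 0.0)
        directed = False
    elif model == "er":
        if N is None or c is None:
            raise ValueError("er requires N and c")
        A01 = _er_binary(N, c, directed, rng)
    elif model in ("ba", "ws", "ring"):
        if N is None:
            raise ValueError("N is required")
        if k is None:
            if c is None:
                raise ValueError(f"{model} requires k or c")
            k = int(round(c * N))
        if k < 2 or k % 2:
            raise ValueError(f"{model} requires an even degree k >= 2, got {k}")
        if model == "ba":
            G = nx.barabasi_albert_graph(N, k // 2, seed=int(rng.integers(2**31)))
        elif model == "ws":
            G = nx.watts_strogatz_graph(N, k, p, seed=int(rng.integers(2**31)))
        else:
            G = nx.watts_strogatz_graph(N, k, 0.0)  # ring lattice: no rewiring
        A01 = nx.to_numpy_array(G, nodelist=range(N), dtype=float)
        directed = False
    else:
        raise ValueError(f"unknown network model: {model!r}")
    n_edges = int(np.count_nonzero(A01))
    c_real = n_edges / N**2
    net = Network(
        A01 * _weight(R0, N, c_real),
        rho,
        directed=directed,
        allow_self_loops=bool(np.any(np.diag(A01))),
        meta={"model": model, "R0": R0, "c": c_real, "seed": seed},
    )
    return net


def _er_binary(N: int, c: float, directed: bool, rng: np.random.Generator) -> np.ndarray:
    """Exact-count Erdos-Renyi: sample pairs without replacement."""
    A = np.zeros((N, N))
    if directed:
        m = int(round(c * N * N))
        pairs = np.array([(i, j) for i in range(N) for j in range(N) if i != j])
        if m > len(pairs):
            raise ValueError(f"density c={c} unreachable without self-loops")
        sel = rng.choice(len(pairs), size=m, replace=False)
        A[pairs[sel, 0], pairs[sel, 1]] = 1.0
    else:
        m = int(round(c * N * N / 2.0))
        pairs = np.array([(i, j) for i in range(N) for j in range(i + 1, N)])
        if m > len(pairs):
            raise ValueError(f"density c={c} unreachable without self-loops")
        sel = rng.choice(len(pairs), size=m, replace=False)
        A[pairs[sel, 0], pairs[sel, 1]] = 1.0
        A += A.T
    return A


# ---------------------------------------------------------------------------
# Extreme block configurations


@dataclass(frozen=True)
class ExtremeConfigSpec:
    """Block-structured network: kind in {'i', 'ii', 'iii', 'iv'}, group size M.

    (i)   M nodes fully connected among themselves; the rest isolated.
    (ii)  As (i), plus reciprocal links between the M-group and every
          remaining node.
    (iii) M nodes each receiving only directed links from the other N - M.
    (iv)  Hierarchy: strictly triangular connectivity (no group size).
    """

    kind: str
    N: int
    M: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("i", "ii", "iii", "iv"):
            raise ValueError(f"kind must be one of i, ii, iii, iv, got {self.kind!r}")
        if self.kind != "iv" and not (1 <= self.M <= self.N):
            raise ValueError(f"group size M={self.M} out of range for N={self.N}")


def extreme_connection_fraction(spec: ExtremeConfigSpec) -> float:
    """Fraction of connections c implied by the block structure.

    Within-group full blocks are counted as M^2 pairs (diagonal pairs in the
    denominator convention), matching the analytic c-M relations
    c_i = M^2/N^2 and c_iii = M(N - M)/N^2.
    """
    N, M = spec.N, spec.M
    if spec.kind == "i":
        return M**2 / N**2
    if spec.kind == "ii":
        return (M**2 + 2 * M * (N - M)) / N**2
    if spec.kind == "iii":
        return M * (N - M) / N**2
    return (N - 1) / (2 * N)  # iv: N(N-1)/2 ordered pairs


def make_extreme(
    spec: ExtremeConfigSpec,
    R0: float = 0.2,
    rho: float | np.ndarray = 0.5,
) -> Network:
    """Materialize a block configuration as a dense network (no self-loops)."""
    N, M = spec.N, spec.M
    c = extreme_connection_fraction(spec)
    w = _weight(R0, N, c)
    A = np.zeros((N, N))
    if spec.kind == "i":
        A[:M, :M] = w
    elif spec.kind == "ii":
        A[:M, :M] = w
        A[:M, M:] = w
        A[M:, :M] = w
    elif spec.kind == "iii":
        A[:M, M:] = w  # group of M receives from the other N - M
    else:  # iv
        A[np.tril_indices(N, k=-1)] = w
    np.fill_diagonal(A, 0.0)
    directed = spec.kind in ("iii", "iv")
    return Network(A, rho, directed=directed,
                   meta={"extreme": spec.kind, "M": M, "R0": R0, "c": c})


def _block_C(sizes, W, rho_classes) -> float:
    """Cascading statistic of a class-structured network in O(k^3), k classes.

    ``W[a, b]`` is the per-edge weight from a class-b node into a class-a
    node; within-class blocks exclude the diagonal.  Mean rates and Leontief
    column sums are class-constant, so two k x k solves suffice.
    """
    sizes = np.asarray(sizes, dtype=float)
    W = np.asarray(W, dtype=float)
    rho_c = np.asarray(rho_classes, dtype=float)
    kk = len(sizes)
    eye = np.eye(kk)
    eff_in = W * (sizes[None, :] - eye)   # row a: summed weight received from class b
    eff_out = W * (sizes[:, None] - eye)  # column b: summed weight sent into class a
    lam = np.linalg.solve(eye - eff_in, rho_c)
    u = np.linalg.solve(eye - eff_out.T, np.ones(kk))
    return float(np.sum(sizes * u * u * lam) / np.sum(sizes * lam))


def _extreme_C_of_r(spec: ExtremeConfigSpec, rho: float = 1.0):
    """Return (C(R0) callable, pole R0 or None) using the block structure."""
    N, M = spec.N, spec.M
    c = extreme_connection_fraction(spec)

    if spec.kind == "iv":
        # strictly lower-triangular: L is the finite Neumann sum, O(N) exact
        def C_of_r(r: float) -> float:
            a = _weight(r, N, c)
            idx = np.arange(N)
            u = (1.0 + a) ** (N - 1 - idx)   # column sums of L
            lam = rho * (1.0 + a) ** idx     # mean rates down the hierarchy
            return float(np.sum(u * u * lam) / np.sum(lam))

        return C_of_r, None

    sizes = np.array([M, N - M], dtype=float)
    if spec.kind == "i":
        pattern = np.array([[1.0, 0.0], [0.0, 0.0]])
    elif spec.kind == "ii":
        pattern = np.array([[1.0, 1.0], [1.0, 0.0]])
    else:  # iii
        pattern = np.array([[0.0, 1.0], [0.0, 0.0]])

    def C_of_r(r: float) -> float:
        return _block_C(sizes, pattern * _weight(r, N, c), [rho, rho])

    if spec.kind == "iii":
        pole = None  # nilpotent: no finite pole
    else:
        eye = np.eye(2)
        eff = pattern * _weight(1.0, N, c) * (sizes[None, :] - eye)
        pole = 1.0 / float(np.max(np.abs(np.linalg.eigvals(eff))))
    return C_of_r, pole


def extreme_Rc(spec: ExtremeConfigSpec, rho: float = 1.0, tol: float = 1e-6) -> float:
    """Critical reproduction ratio C(R0) = 2 of a block configuration.

    Uses the O(1) block evaluation, so N may be large.  For the nilpotent
    kinds (iii, iv) C grows without a pole and the bracket is expanded
    geometrically; NaN is never returned for these since C is unbounded.
    """
    C_of_r, pole = _extreme_C_of_r(spec, rho)
    if pole is not None:
        return solve_C_equals_2(C_of_r, pole, tol=tol)
    lo, hi = 1e-9, 1.0
    while C_of_r(hi) < C_CRITICAL:
        lo, hi = hi, hi * 2.0
        if hi > 1e9:  # pragma: no cover
            return math.nan
    return float(brentq(lambda r: C_of_r(r) - C_CRITICAL, lo, hi, xtol=tol * 1e-2))


def extreme_crossover(
    N: int = 1000,
    c_lo: float = 0.02,
    c_hi: float = 0.6,
    n_grid: int = 120,
    rho: float = 1.0,
) -> float:
    """Connection fraction where the R_c(c) curves of kinds (i) and (ii) cross.

    Evaluates both critical-point curves on a common grid of c (group sizes
    M chosen per kind to realize each c) and locates the sign change of
    their difference by linear interpolation.
    """
    cs = np.linspace(c_lo, c_hi, n_grid)
    diff = np.empty(n_grid)
    for idx, c in enumerate(cs):
        M_i = max(2, int(round(N * math.sqrt(c))))           # c = M^2 / N^2
        m2 = 1.0 - math.sqrt(max(1.0 - c, 0.0))              # c = 2m - m^2, m = M/N
        M_ii = min(N - 1, max(1, int(round(N * m2))))
        r_i = extreme_Rc(ExtremeConfigSpec("i", N, M_i), rho)
        r_ii = extreme_Rc(ExtremeConfigSpec("ii", N, M_ii), rho)
        diff[idx] = r_i - r_ii
    sign = np.sign(diff)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        raise RuntimeError("R_c curves of configurations (i) and (ii) do not cross "
                           "on the scanned range")
    k = flips[0]
    # linear interpolation of the root between grid points
    c0, c1, d0, d1 = cs[k], cs[k + 1], diff[k], diff[k + 1]
    return float(c0 - d0 * (c1 - c0) / (d1 - d0))


# ---------------------------------------------------------------------------
# Degree-based mean field for heterogeneous degree sequences


def scale_free_Rc_meanfield(degrees: np.ndarray, rho: float = 1.0,
                            tol: float = 1e-6) -> float:
    """Annealed (degree-class) mean-field critical point for a degree sequence.

    Treats the network as annealed with edge probability k_i k_j / (N <k>)
    and 0-1 weight R0/<k> per edge, giving the rank-1 expected interaction
    A_ij = R0 k_i k_j / (N <k>^2).  The Leontief column sums and mean rates
    then follow in closed form and C(R0) = 2 is solved on (0, <k>^2/<k^2>).
    For an all-equal degree sequence this reduces exactly to the uniform
    network and returns 1 - 1/sqrt(2).
    """
    k = np.asarray(degrees, dtype=float)
    if np.any(k <= 0):
        raise ValueError("degrees must be positive")
    k1 = k.mean()
    k2 = (k**2).mean()
    pole = k1**2 / k2  # R0 where the rank-1 Leontief inverse blows up

    def C_of_r(r: float) -> float:
        g = r * k2 / k1**2
        x = r * k / (k1 * (1.0 - g))
        w = 1.0 + x  # both u_i and lambda_i / rho
        return float(np.sum(w**3) / np.sum(w))

    return solve_C_equals_2(C_of_r, pole, tol=tol)


def clustering_coefficient(net: Network) -> float:
    """Average Watts-Strogatz local clustering of the binary undirected projection."""
    A = (net.A != 0) | (net.A.T != 0)
    np.fill_diagonal(A, False)
    G = nx.from_numpy_array(A.astype(int))
    return float(nx.average_clustering(G))
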