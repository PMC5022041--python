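"""Weighted directed interaction networks.

``A[i, j]`` is the interaction strength from node ``j`` to node ``i``: an
event at ``j`` transiently raises the event rate of ``i`` by ``A[i, j]``
(integrated over the excitation kernel).  Per-node base rates ``rho`` hold
the spontaneous activity.  Node indexing is 0-based internally; the edge-list
reader accepts 1-based labels and the writer can preserve them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Network", "read_edgelist", "write_edgelist", "read_dense", "write_dense"]


@dataclass
class Network:
    """Interaction matrix plus per-node base rates.

    Parameters
    ----------
    A
        N x N non-negative matrix; ``A[i, j]`` is the weight of the directed
        edge j -> i.  Zero diagonal unless ``allow_self_loops``.
    rho
        Per-node base rates; a scalar is broadcast to all nodes.
    directed
        Bookkeeping flag: False promises ``A`` symmetric and makes rewiring
        treat reciprocal pairs atomically.
    """

    A: np.ndarray
    rho: np.ndarray | float = 1.0
    directed: bool = True
    allow_self_loops: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.ascontiguousarray(np.asarray(self.A, dtype=float))
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be a square matrix")
        if np.any(self.A < 0) or not np.all(np.isfinite(self.A)):
            raise ValueError("interaction weights must be finite and non-negative")
        if not self.allow_self_loops and np.any(np.diag(self.A) != 0):
            raise ValueError("self-loops present but allow_self_loops is False")
        rho = np.broadcast_to(np.asarray(self.rho, dtype=float), (self.A.shape[0],))
        self.rho = np.ascontiguousarray(rho)
        if np.any(self.rho < 0) or not np.all(np.isfinite(self.rho)):
            raise ValueError("base rates must be finite and non-negative")
        if not self.directed and not np.allclose(self.A, self.A.T):
            raise ValueError("directed=False requires a symmetric matrix")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero off-diagonal entries (ordered pairs)."""
        off = self.A != 0
        np.fill_diagonal(off, False)
        return int(off.sum())

    @property
    def connection_fraction(self) -> float:
        """Fraction of ordered node pairs (including self pairs) connected."""
        return self.n_edges / self.n_nodes**2

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    def copy(self) -> "Network":
        return Network(
            self.A.copy(),
            self.rho.copy(),
            directed=self.directed,
            allow_self_loops=self.allow_self_loops,
            meta=dict(self.meta),
        )


def write_edgelist(net: Network, path: str | Path, one_based: bool = False) -> None:
    """Write ``i j weight`` rows (edge j -> i listed as ``i j``)."""
    off = int(one_based)
    with open(path, "w") as fh:
        fh.write(f"# N={net.n_nodes} directed={int(net.directed)} "
                 f"index_base={off}\n")
        fh.write("# i j weight   (interaction from j to i)\n")
        rows, cols = np.nonzero(net.A)
        for i, j in zip(rows, cols):
            fh.write(f"{i + off} {j + off} {float(net.A[i, j])!r}\n")


def read_edgelist(
    path: str | Path,
    n_nodes: int | None = None,
    rho: float | np.ndarray = 1.0,
    directed: bool = True,
) -> Network:
    """Read ``i j [weight]`` rows; ``#`` lines are comments.

    A header ``# N=... index_base=...`` (as written by :func:`write_edgelist`)
    fixes the node count and indexing base; otherwise 1-based labels are
    detected from the absence of a 0 label, and missing weights default to 1.
    """
    n_hdr = None
    base = None
    directed_hdr = None
    edges: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("N="):
                        n_hdr = int(tok[2:])
                    elif tok.startswith("index_base="):
                        base = int(tok[11:])
                    elif tok.startswith("directed="):
                        directed_hdr = bool(int(tok[9:]))
                continue
            parts = line.split()
            try:
                i, j = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) > 2 else 1.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {line!r}") from exc
            edges.append((i, j, w))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    if base is None:
        labels = [e[0] for e in edges] + [e[1] for e in edges]
        base = 0 if min(labels) == 0 else 1
    if directed_hdr is not None:
        directed = directed_hdr
    n = n_hdr or n_nodes or (max(max(e[0], e[1]) for e in edges) - base + 1)
    A = np.zeros((n, n))
    for i, j, w in edges:
        A[i - base, j - base] = w
        if not directed:
            A[j - base, i - base] = w
    return Network(A, rho, directed=directed)


def write_dense(net: Network, path: str | Path) -> None:
    """Write the dense matrix, one row per line, full float precision."""
    header = f"N={net.n_nodes} directed={int(net.directed)}"
    np.savetxt(path, net.A, header=header, fmt="%.17g")


def read_dense(path: str | Path, rho: float | np.ndarray = 1.0) -> Network:
    A = np.loadtxt(path)
    directed = True
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "directed=0" in first:
            directed = False
    return Network(np.atleast_2d(A), rho, directed=directed)
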