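"""Event-series container and plain-text I/O.

An :class:`EventSeries` is an ordered list of event times on an observation
interval ``[0, T]``, optionally tagged with the id of the node (individual)
that generated each event.  It is the common currency between the simulators
and the stationarity detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EventSeries", "read_events", "write_events"]


@dataclass
class EventSeries:
    """Ordered event times on ``[0, T]``, optionally tagged by node id.

    Parameters
    ----------
    times
        Event times, sorted non-decreasing, all within ``[0, T]``.
    T
        Length of the observation interval.
    node_ids
        Optional integer node id per event (0-based), same length as
        ``times``.
    """

    times: np.ndarray
    T: float
    node_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size and (np.any(np.diff(self.times) < 0)):
            raise ValueError("event times must be sorted non-decreasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.T):
            raise ValueError("event times must lie within [0, T]")
        if self.node_ids is not None:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
            if self.node_ids.shape != self.times.shape:
                raise ValueError("node_ids must match times in length")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Empirical mean event rate over the observation interval."""
        return self.times.size / self.T

    def pooled(self) -> "EventSeries":
        """The same series with node tags dropped (superposed stream)."""
        return EventSeries(self.times.copy(), self.T, None)

    def by_node(self, n_nodes: int | None = None) -> list["EventSeries"]:
        """Split a tagged series into one untagged series per node."""
        if self.node_ids is None:
            raise ValueError("series carries no node ids")
        if n_nodes is None:
            n_nodes = int(self.node_ids.max()) + 1 if self.times.size else 0
        return [
            EventSeries(self.times[self.node_ids == j], self.T, None)
            for j in range(n_nodes)
        ]


def write_events(series: EventSeries, path: str | Path) -> None:
    """Write an event series as plain text: header, then ``time [node]`` rows."""
    with open(path, "w") as fh:
        fh.write(f"# T={series.T!r} n_events={series.n_events}\n")
        if series.node_ids is None:
            for t in series.times:
                fh.write(f"{float(t)!r}\n")
        else:
            for t, j in zip(series.times, series.node_ids):
                fh.write(f"{float(t)!r} {int(j)}\n")


def read_events(path: str | Path) -> EventSeries:
    """Read the text format written by :func:`write_events`.

    The header comment carries ``T``; without it, T defaults to the last
    event time.
    """
    T = None
    times: list[float] = []
    ids: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].replace(",", " ").split():
                    if tok.startswith("T="):
                        T = float(tok[2:])
                continue
            parts = line.split()
            try:
                times.append(float(parts[0]))
                if len(parts) > 1:
                    ids.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {line!r}") from exc
    if ids and len(ids) != len(times):
        raise ValueError(f"{path}: node-id column present on only some rows")
    t = np.asarray(times, dtype=float)
    if T is None:
        T = float(t[-1]) if t.size else 0.0
    return EventSeries(t, T, np.asarray(ids) if ids else None)
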