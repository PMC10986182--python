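"""Activation records: per-vertex ordered activation times from a run."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DimensionError


class ActivationRecord:
    """Ordered activation times (ms) for each simulation vertex.

    ``times[v]`` is a sorted 1-D float array; vertices that never activated
    (e.g. cleft-isolated or non-conducting tissue) have an empty array.
    ``active_mask`` marks vertices that take part in conduction at all
    (pruned/removed elements are excluded from fractions and analysis).
    """

    def __init__(self, times, n_vertices=None, active_mask=None):
        if n_vertices is None:
            n_vertices = len(times)
        self.n_vertices = int(n_vertices)
        self.times = [np.sort(np.asarray(t, dtype=float)) for t in times]
        if len(self.times) != self.n_vertices:
            raise DimensionError("times length != n_vertices")
        if active_mask is None:
            active_mask = np.ones(self.n_vertices, dtype=bool)
        self.active_mask = np.asarray(active_mask, dtype=bool)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times], dtype=np.int64)

    def first_times(self) -> np.ndarray:
        """First activation time per vertex; NaN where never activated."""
        out = np.full(self.n_vertices, np.nan)
        for v, t in enumerate(self.times):
            if len(t):
                out[v] = t[0]
        return out

    def max_time(self) -> float:
        m = [t[-1] for t in self.times if len(t)]
        return max(m) if m else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [(v, i, t) for v in range(self.n_vertices)
                for i, t in enumerate(self.times[v])]
        return pd.DataFrame(rows,
                            columns=["vertex_id", "activation_index",
                                     "time_ms"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_vertices=None,
                   active_mask=None) -> "ActivationRecord":
        if n_vertices is None:
            n_vertices = int(df["vertex_id"].max()) + 1 if len(df) else 0
        times = [[] for _ in range(n_vertices)]
        for v, t in zip(df["vertex_id"].to_numpy(),
                        df["time_ms"].to_numpy()):
            times[int(v)].append(float(t))
        return cls(times, n_vertices, active_mask)
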