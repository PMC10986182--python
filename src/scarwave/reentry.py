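"""Automatic reentry identification and initiation-site tracing.

Reentry is any activation of a vertex after its final pacing-induced
activation.  Rapid repeated activations of the same vertex (a cleft
artifact of current pivoting around a no-flux boundary) separated by less
than 50 ms are merged into one.  Initiation sites are found by walking the
reentrant activation times backward in 10 ms steps on the mesh adjacency
graph: an initiation cluster is a connected set of vertices activated
before all of their neighbours, confined to the earliest time step at
which it appears; its geometric center is the initiation site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, DimensionError
from .mesh import TissueMesh
from .records import ActivationRecord


def default_min_cluster(n_vertices: int) -> int:
    """Minimum initiation-cluster size.

    The published constant (1,000 vertices) presumes ~10-million-element
    meshes; at desk scale it is rescaled to ``max(20, 1e-4 * n_vertices)``.
    """
    return max(20, int(1e-4 * n_vertices))


def label_reentrant_activations(record: ActivationRecord, n_stimuli: int,
                                last_stim_time_ms: float | None = None,
                                settle_ms: float = 600.0) -> list:
    """Per-vertex reentrant activation times.

    For each vertex, activations beyond index ``n_stimuli`` are reentrant
    (the ``n+1``-th activation after ``n`` captured stimuli).  If
    ``last_stim_time_ms`` is given, vertices with locally blocked pacing
    beats (at most ``n_stimuli`` activations) also contribute: any
    activation later than ``last_stim_time_ms + settle_ms`` is reentrant
    regardless of index.  ``settle_ms`` must exceed the slowest pacing
    propagation delay, otherwise slowly conducting fibrotic regions are
    misread as reentrant; leave ``last_stim_time_ms`` as None (pure index
    rule) when that bound is unknown.  Vertices with zero activations are
    allowed (isolated tissue) and return empty arrays.
    """
    if n_stimuli < 0:
        raise ConfigError("n_stimuli must be >= 0")
    out = []
    for t in record.times:
        t = np.asarray(t)
        re = t[n_stimuli:]
        if last_stim_time_ms is not None and len(t) <= n_stimuli:
            late = t[t > last_stim_time_ms + settle_ms]
            if late.size > re.size:
                re = late
        out.append(np.sort(re))
    return out


def merge_rapid_activations(series, window_ms: float = 50.0):
    """Collapse consecutive activations separated by < ``window_ms``.

    Applied pairwise after each merge (each kept time starts a new gap
    measurement); idempotent and order-preserving.  Accepts a single
    sorted array or a list of them.
    """
    def _merge(t):
        t = np.asarray(t, dtype=float)
        if t.size <= 1:
            return t.copy()
        kept = [t[0]]
        for x in t[1:]:
            if x - kept[-1] >= window_ms:
                kept.append(x)
        return np.asarray(kept)

    if isinstance(series, (list, tuple)):
        return [_merge(t) for t in series]
    return _merge(series)


@dataclass
class InitiationCluster:
    vertices: np.ndarray      # connected vertex ids
    step_ms: float            # earliest back-trace step (discretised time)
    center_mm: np.ndarray     # arithmetic mean of vertex coordinates
    size: int


def trace_initiation(reentrant_series, mesh: TissueMesh,
                     step_ms: float = 10.0,
                     min_cluster: int | None = None,
                     severed_faces=None) -> list:
    """Back-trace reentrant activations to their initiation cluster(s).

    Vertex times are discretised to ``step_ms`` bins (the voltage-recording
    resolution).  A vertex is a source candidate when no neighbour (on the
    mesh adjacency graph, cleft-severed faces excluded) has a strictly
    earlier bin; connected candidate components necessarily share one bin,
    which is the step at which the cluster appears.  Components smaller
    than ``min_cluster`` are discarded.
    """
    if len(reentrant_series) != mesh.n_elements:
        raise DimensionError("series length != number of mesh vertices")
    if min_cluster is None:
        min_cluster = default_min_cluster(mesh.n_elements)

    first = np.full(mesh.n_elements, np.inf)
    for v, t in enumerate(reentrant_series):
        t = np.asarray(t)
        if t.size:
            first[v] = t[0]
    has = np.isfinite(first)
    if not has.any():
        return []
    t0 = first[has].min()
    binned = np.full(mesh.n_elements, np.iinfo(np.int64).max, dtype=np.int64)
    binned[has] = np.floor((first[has] - t0) / step_ms).astype(np.int64)

    faces = mesh.faces
    if severed_faces is not None:
        faces = faces[~np.asarray(severed_faces, dtype=bool)]
    a, b = faces[:, 0], faces[:, 1]
    # candidate: reentrant and no reentrant neighbour strictly earlier
    earliest_nbr = np.full(mesh.n_elements, np.iinfo(np.int64).max,
                           dtype=np.int64)
    np.minimum.at(earliest_nbr, a, binned[b])
    np.minimum.at(earliest_nbr, b, binned[a])
    cand = has & (binned <= earliest_nbr)

    keep = cand[a] & cand[b]
    n = mesh.n_elements
    adj = sp.csr_matrix(
        (np.ones(keep.sum()), (a[keep], b[keep])), shape=(n, n))
    ncomp, comp = sp.csgraph.connected_components(
        adj + adj.T, directed=False)
    clusters = []
    for c in range(ncomp):
        verts = np.flatnonzero((comp == c) & cand)
        if verts.size == 0:
            continue
        if verts.size < min_cluster:
            continue
        step = t0 + binned[verts[0]] * step_ms
        center = mesh.centers[verts].mean(axis=0)
        clusters.append(InitiationCluster(vertices=verts, step_ms=step,
                                          center_mm=center,
                                          size=int(verts.size)))
    clusters.sort(key=lambda cl: (cl.step_ms, -cl.size))
    return clusters


def classify_sustained(reentrant_series, last_pacing_time_ms: float,
                       horizon_ms: float = 4000.0,
                       output_interval_ms: float = 10.0) -> bool:
    """Sustained reentry: reentrant activity persists to the end of the
    observation window after the last pacing stimulus."""
    latest = -np.inf
    for t in reentrant_series:
        t = np.asarray(t)
        if t.size:
            latest = max(latest, t[-1])
    if not np.isfinite(latest):
        raise ConfigError("no reentrant activations: sustainment undefined")
    return latest >= last_pacing_time_ms + horizon_ms - output_interval_ms


@dataclass
class MorphologyLabel:
    label: str           # 'Type1' | 'Type2'
    mean_lge_pct: float
    heuristic: bool = True  # feature proxy, not visual classification


def classify_morphology(mean_local_lge_pct: float,
                        type2_cutoff_pct: float = 10.0) -> MorphologyLabel:
    """Feature-based morphology proxy.

    Functional rotors at healthy–fibrotic interfaces (Type 2) initiate in
    low-LGE surroundings; meandering double-loop reentries through fibrotic
    channels (Type 1) initiate in dense LGE.  Sites with mean local LGE
    below the cutoff are labelled Type 2, others Type 1.  The label carries
    a ``heuristic`` provenance flag: it is a proxy for visual
    classification of propagation patterns.
    """
    if mean_local_lge_pct is None or not np.isfinite(mean_local_lge_pct):
        raise ConfigError("local LGE features required for morphology")
    label = "Type2" if mean_local_lge_pct < type2_cutoff_pct else "Type1"
    return MorphologyLabel(label=label, mean_lge_pct=float(mean_local_lge_pct))


@dataclass
class ReentryLabel:
    reentry: bool
    sustained: bool
    clusters: list
    morphologies: list


def brute_force_clusters(reentrant_series, mesh: TissueMesh,
                         step_ms: float = 10.0, min_cluster: int = 1,
                         severed_faces=None) -> list:
    """Independent exhaustive oracle for :func:`trace_initiation`.

    At every time step (ascending), compare each vertex against all its
    neighbours directly and grow clusters with plain breadth-first search
    over networkx; intended for meshes up to ~30x30.
    """
    import networkx as nx

    first = {}
    for v, t in enumerate(reentrant_series):
        t = np.asarray(t)
        if t.size:
            first[v] = t[0]
    if not first:
        return []
    t0 = min(first.values())
    binned = {v: int(np.floor((tv - t0) / step_ms))
              for v, tv in first.items()}
    g = mesh.to_networkx(
        None if severed_faces is None
        else mesh.faces[~np.asarray(severed_faces, dtype=bool)])

    cand = set()
    for v, bv in binned.items():
        ok = True
        for u in g.neighbors(v):
            if u in binned and binned[u] < bv:
                ok = False
                break
        if ok:
            cand.add(v)
    sub = g.subgraph(cand)
    out = []
    for comp in nx.connected_components(sub):
        comp = sorted(comp)
        if len(comp) < min_cluster:
            continue
        step = t0 + binned[comp[0]] * step_ms
        center = mesh.centers[list(comp)].mean(axis=0)
        out.append(InitiationCluster(vertices=np.array(comp), step_ms=step,
                                     center_mm=center, size=len(comp)))
    out.sort(key=lambda cl: (cl.step_ms, -cl.size))
    return out
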