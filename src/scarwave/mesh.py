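"""Lattice tissue meshes.

The substrate for every simulation is a regular quadrilateral (2D) or
hexahedral (thin-3D) lattice of *elements*.  The monodomain solver is
cell-centered: each element carries one simulation node at its center, so
"vertex" in activation records and reentry analysis refers to an element
node.  Faces are the shared sides between axis-neighbouring elements;
severing a face removes its conductance (a no-flux cleft).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError


@dataclass
class TissueMesh:
    """Regular lattice mesh.

    Parameters
    ----------
    shape
        Element counts per axis, ``(nx, ny)`` or ``(nx, ny, nz)``.
    spacing_um
        Element edge length in micrometres (isotropic).
    fibers
        Per-element unit fiber vectors, shape ``(n, 3)``.
    segments
        Optional per-element integer segment labels, shape ``(n,)``.
    """

    shape: tuple
    spacing_um: float
    fibers: np.ndarray
    segments: np.ndarray | None = None
    _centers: np.ndarray = field(default=None, repr=False)
    _faces: np.ndarray = field(default=None, repr=False)
    _face_axis: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) == 2:
            self.shape = self.shape + (1,)
        if len(self.shape) != 3:
            raise DimensionError(f"shape must be 2D or 3D, got {self.shape}")
        self.fibers = np.asarray(self.fibers, dtype=float)
        if self.fibers.shape != (self.n_elements, 3):
            raise DimensionError(
                f"fibers shape {self.fibers.shape} != ({self.n_elements}, 3)")
        norms = np.linalg.norm(self.fibers, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise DimensionError("fiber vectors must be unit norm")
        if self.segments is not None:
            self.segments = np.asarray(self.segments, dtype=np.int64)
            if self.segments.shape != (self.n_elements,):
                raise DimensionError("segments shape mismatch")

    # -- geometry -----------------------------------------------------------

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    n_vertices = n_elements  # simulation nodes sit at element centers

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def element_volume_ml(self) -> float:
        """Volume of one element in mL (= cm^3); thin axes use the spacing."""
        return (self.spacing_um / 1e4) ** 3  # edge in cm, cubed

    @property
    def extent_mm(self) -> tuple:
        return tuple(s * self.spacing_mm for s in self.shape)

    @property
    def centers(self) -> np.ndarray:
        """Element-center coordinates in mm, shape ``(n, 3)``."""
        if self._centers is None:
            nx, ny, nz = self.shape
            ii, jj, kk = np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
            h = self.spacing_mm
            self._centers = np.column_stack(
                [(ii.ravel() + 0.5) * h, (jj.ravel() + 0.5) * h,
                 (kk.ravel() + 0.5) * h])
        return self._centers

    def index(self, i, j, k=0) -> int:
        nx, ny, nz = self.shape
        return (i * ny + j) * nz + k

    def unravel(self, idx):
        nx, ny, nz = self.shape
        return np.unravel_index(idx, (nx, ny, nz))

    # -- topology -----------------------------------------------------------

    def _build_faces(self):
        nx, ny, nz = self.shape
        idx = np.arange(self.n_elements).reshape(nx, ny, nz)
        pairs, axes = [], []
        for axis, n in enumerate((nx, ny, nz)):
            if n < 2:
                continue
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(0, -1)
            sl_b[axis] = slice(1, None)
            a = idx[tuple(sl_a)].ravel()
            b = idx[tuple(sl_b)].ravel()
            pairs.append(np.column_stack([a, b]))
            axes.append(np.full(a.size, axis, dtype=np.int8))
        self._faces = np.concatenate(pairs, axis=0)
        self._face_axis = np.concatenate(axes)

    @property
    def faces(self) -> np.ndarray:
        """Internal faces as element-index pairs, shape ``(nf, 2)``."""
        if self._faces is None:
            self._build_faces()
        return self._faces

    @property
    def face_axis(self) -> np.ndarray:
        """Axis (0/1/2) of each face normal."""
        if self._face_axis is None:
            self._build_faces()
        return self._face_axis

    def face_normals(self) -> np.ndarray:
        """Unit normals of internal faces, shape ``(nf, 3)``."""
        normals = np.zeros((self.faces.shape[0], 3))
        normals[np.arange(normals.shape[0]), self.face_axis] = 1.0
        return normals

    def adjacency_lists(self, faces: np.ndarray | None = None):
        """Neighbour lists per element from a face set (default: all faces)."""
        if faces is None:
            faces = self.faces
        nbrs = [[] for _ in range(self.n_elements)]
        for a, b in faces:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return nbrs

    def to_networkx(self, faces: np.ndarray | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_elements))
        g.add_edges_from(map(tuple, (self.faces if faces is None else faces)))
        return g


def uniform_fibers(n: int, angle_deg: float) -> np.ndarray:
    """In-plane fiber field at a constant angle from the x-axis."""
    th = np.deg2rad(angle_deg)
    f = np.tile([np.cos(th), np.sin(th), 0.0], (n, 1))
    return f


@dataclass
class LGEMap:
    """Per-element normalised LGE-like intensity in [0, 1]."""

    intensity: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise DimensionError("intensity must be a flat per-element array")
        if (self.intensity < 0).any() or (self.intensity > 1).any():
            raise DimensionError("intensity outside [0, 1]")

    @property
    def n_elements(self) -> int:
        return self.intensity.size

    def check_mesh(self, mesh: TissueMesh):
        if self.n_elements != mesh.n_elements:
            raise DimensionError(
                f"LGE map has {self.n_elements} elements, mesh has "
                f"{mesh.n_elements}")
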