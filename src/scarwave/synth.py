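"""Synthetic geometries, LGE intensity maps, segment labels and fixtures.

The study conditions the package emulates are patchy/diffuse ventricular
fibrosis seen as late gadolinium enhancement (LGE): a smooth intensity
gradient rising to a dense core, normalised per subject so 0 is healthy
tissue and 1 the subject's maximum.  Geometries are regular 2D sheets or
thin-3D slabs at the 530 um element scale of clinical-resolution meshes.

All randomness flows from one explicit integer seed.  Stages fork their
own generators with :func:`numpy.random.SeedSequence.spawn`-style keyed
children (``SeedSequence((seed, stage_key))``), so adding a stage never
perturbs another stage's draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .mesh import LGEMap, TissueMesh, uniform_fibers
from .records import ActivationRecord

#: stage keys for seed forking (documented scheme; never reuse a key)
STAGE_LGE = 1
STAGE_CLEFTS = 2
STAGE_PROTOCOL = 3
STAGE_STATS = 4


def stage_rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    """Deterministic per-stage generator from the master seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stage),
                                                         int(extra))))


@dataclass
class SyntheticSpec:
    """Specification of one synthetic geometry + LGE map.

    Defaults are the package's study conditions: a 100x100 element sheet at
    530 um spacing (5.3 cm square), fibers along x, a single fibrotic patch
    of 12 mm radius reaching intensity 1 at its center, with mild additive
    intensity noise.
    """

    grid_shape: tuple = (100, 100)
    spacing_um: float = 530.0
    fiber_angle_deg: float = 0.0
    lge_pattern: str = "single_patch"  # single_patch | multi_patch | diffuse_gradient
    patch_centers_mm: tuple = None  # defaults to domain center
    patch_radii_mm: tuple = (12.0,)
    intensity_peak: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0
    transmural_rotation_deg: float = 0.0  # thin-3D only: total fiber rotation

    def __post_init__(self):
        if self.spacing_um <= 0:
            raise InvalidSpecError(f"spacing must be > 0, got {self.spacing_um}")
        if not 0.0 <= self.intensity_peak <= 1.0:
            raise InvalidSpecError("intensity_peak must be in [0, 1]")
        if any(int(s) < 1 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape entries must be >= 1")


def cable_spec(length_cm: float = 10.0, spacing_um: float = 530.0) -> SyntheticSpec:
    """The standard conduction-velocity calibration cable.

    A 10 cm cable at 530 um resolution discretises to 189 elements
    (188 * 0.53 mm = 99.6 mm span between end nodes).
    """
    n = int(round(length_cm * 1e4 / spacing_um)) + 1
    return SyntheticSpec(grid_shape=(n, 1), spacing_um=spacing_um,
                         lge_pattern="single_patch", intensity_peak=0.0,
                         noise_sd=0.0)


def generate_mesh(spec: SyntheticSpec) -> TissueMesh:
    """Build the lattice mesh with fiber field from a spec."""
    shape = tuple(int(s) for s in spec.grid_shape)
    if len(shape) == 2:
        shape = shape + (1,)
    n = int(np.prod(shape))
    if shape[2] > 1 and spec.transmural_rotation_deg:
        # linear transmural rotation across the thin axis
        nz = shape[2]
        fibers = np.empty((n, 3))
        base = np.arange(n) % nz
        ang = np.deg2rad(spec.fiber_angle_deg
                         + spec.transmural_rotation_deg
                         * (base / max(nz - 1, 1) - 0.5))
        fibers[:, 0] = np.cos(ang)
        fibers[:, 1] = np.sin(ang)
        fibers[:, 2] = 0.0
    else:
        fibers = uniform_fibers(n, spec.fiber_angle_deg)
    return TissueMesh(shape=shape, spacing_um=spec.spacing_um, fibers=fibers)


def _patch_field(mesh: TissueMesh, centers, radii, peak):
    xy = mesh.centers
    out = np.zeros(mesh.n_elements)
    lo = np.zeros(3)
    hi = np.array(mesh.extent_mm)
    for c, r in zip(centers, radii):
        c = np.asarray(c, dtype=float)
        if c.size == 2:
            c = np.append(c, mesh.extent_mm[2] / 2.0)
        if (c < lo).any() or (c > hi).any():
            warnings.warn(
                f"patch center {tuple(c)} outside mesh bounds {tuple(hi)}; "
                "clipped", stacklevel=3)
            c = np.clip(c, lo, hi)
        d = np.linalg.norm(xy - c, axis=1)
        # linear radial ramp: peak at the center, 0 at radius r
        out = np.maximum(out, peak * np.clip(1.0 - d / r, 0.0, None))
    return out


def _diffuse_field(mesh: TissueMesh, peak, rng):
    """Low-frequency random field: diffuse fibrosis with smooth gradients."""
    from scipy.ndimage import gaussian_filter

    nx, ny, nz = mesh.shape
    raw = rng.standard_normal((nx, ny, nz))
    # correlation length ~ 8 elements (~4 mm at default spacing)
    smooth = gaussian_filter(raw, sigma=8.0, mode="reflect")
    smooth -= smooth.min()
    if smooth.max() > 0:
        smooth /= smooth.max()
    # sharpen toward a dense core: emphasise the top of the field
    smooth = smooth ** 2
    return peak * smooth.ravel()


def generate_lge(spec: SyntheticSpec, mesh: TissueMesh) -> LGEMap:
    """Synthetic normalised LGE intensity map on the mesh elements."""
    rng = stage_rng(spec.seed, STAGE_LGE)
    centers = spec.patch_centers_mm
    if centers is None:
        # snap to the nearest element center so the discrete maximum
        # equals intensity_peak exactly
        mid = np.array(mesh.extent_mm) / 2.0
        snap = mesh.centers[np.argmin(
            np.linalg.norm(mesh.centers - mid, axis=1))]
        centers = (tuple(snap),)
    radii = spec.patch_radii_mm
    if len(radii) == 1 and len(centers) > 1:
        radii = radii * len(centers)

    if spec.lge_pattern == "single_patch":
        field_ = _patch_field(mesh, centers[:1], radii[:1], spec.intensity_peak)
    elif spec.lge_pattern == "multi_patch":
        field_ = _patch_field(mesh, centers, radii, spec.intensity_peak)
    elif spec.lge_pattern == "diffuse_gradient":
        field_ = _diffuse_field(mesh, spec.intensity_peak, rng)
    else:
        raise InvalidSpecError(f"unknown lge_pattern {spec.lge_pattern!r}")

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=field_.shape)
        field_ = field_ + np.where(field_ > 0, noise, 0.0)
    return LGEMap(np.clip(field_, 0.0, 1.0))


def generate_segments(mesh: TissueMesh, n_segments: int = 17) -> np.ndarray:
    """Contiguous, near-equal-area segment labels (idealised AHA analogue).

    The sheet/slab is tiled into ``n_segments`` strips along its longest
    axis, with boundaries at ``floor(i * n_axis / n_segments)`` so strip
    widths differ pairwise by at most one element row.
    """
    if n_segments < 1:
        raise InvalidSpecError("n_segments must be >= 1")
    axis = int(np.argmax(mesh.shape))
    n_axis = mesh.shape[axis]
    if n_segments > n_axis:
        raise InvalidSpecError(
            f"n_segments {n_segments} exceeds axis length {n_axis}")
    bounds = (np.arange(n_segments + 1) * n_axis) // n_segments
    coord = np.stack(mesh.unravel(np.arange(mesh.n_elements)), axis=0)[axis]
    labels = np.searchsorted(bounds, coord, side="right") - 1
    return labels.astype(np.int64)


# ---------------------------------------------------------------------------
# planted activation fixtures (ground truth for the reentry tracer)

@dataclass
class PlantedFixture:
    record: ActivationRecord
    source_elements: tuple
    source_onsets_ms: tuple
    n_stimuli: int
    last_stim_time_ms: float


def _lattice_distance_mm(mesh: TissueMesh, source: int) -> np.ndarray:
    """Graph (L1) distance from a source element along lattice faces."""
    src = np.array(mesh.unravel(source)).reshape(3)
    coords = np.stack(mesh.unravel(np.arange(mesh.n_elements)), axis=1)
    return np.abs(coords - src).sum(axis=1) * mesh.spacing_mm


def plant_activation_fixture(mesh: TissueMesh, scenario: str,
                             sources=None, onsets_ms=None,
                             speed_mm_ms: float = 0.05,
                             n_stimuli: int = 2,
                             cycle_ms: float = 400.0,
                             pacing_origin=None) -> PlantedFixture:
    """Activation-time fixtures with known reentry sources.

    Pacing waves spread from ``pacing_origin`` (default element 0) at
    ``speed_mm_ms``; scenario ``single_source`` adds one extra wave from a
    planted source, ``two_source_merge`` adds two waves whose fronts merge,
    each front reaching a vertex at ``onset + distance / speed``.  Fronts
    follow lattice (L1) distance, the shortest path along element faces;
    the slow default speed represents reentrant conduction through fibrosis
    and keeps successive lattice shells in distinct 10 ms trace bins, so a
    planted source is the unique leading vertex of its wave.
    """
    if scenario not in ("no_reentry", "single_source", "two_source_merge"):
        raise InvalidSpecError(f"unknown scenario {scenario!r}")
    centers = mesh.centers
    n = mesh.n_elements
    if pacing_origin is None:
        pacing_origin = 0
    if not 0 <= pacing_origin < n:
        raise InvalidSpecError("pacing origin off-mesh")
    d0 = _lattice_distance_mm(mesh, pacing_origin)

    times = [list((d0[v] / speed_mm_ms) + cycle_ms * np.arange(n_stimuli))
             for v in range(n)]
    last_stim = cycle_ms * (n_stimuli - 1)

    if scenario == "no_reentry":
        sources, onsets_ms = (), ()
    else:
        want = 1 if scenario == "single_source" else 2
        if sources is None:
            mid = mesh.index(mesh.shape[0] // 2, mesh.shape[1] // 2)
            sources = (mid,) if want == 1 else (
                mesh.index(mesh.shape[0] // 4, mesh.shape[1] // 4), mid)
        if onsets_ms is None:
            base = last_stim + 2 * cycle_ms
            onsets_ms = (base,) if want == 1 else (base, base + 30.0)
        if len(sources) != want or len(onsets_ms) != want:
            raise InvalidSpecError(f"{scenario} needs {want} source(s)")
        for s in sources:
            if not 0 <= s < n:
                raise InvalidSpecError(f"source {s} off-mesh")
        ds = np.stack([_lattice_distance_mm(mesh, s) for s in sources])
        extra = np.min(np.asarray(onsets_ms)[:, None]
                       + ds / speed_mm_ms, axis=0)
        for v in range(n):
            times[v].append(extra[v])

    rec = ActivationRecord(times, n)
    return PlantedFixture(rec, tuple(sources), tuple(onsets_ms),
                          n_stimuli, last_stim)
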