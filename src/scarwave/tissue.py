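"""Fibrotic substrate construction from an LGE map.

Two families of representation:

* **Cleft models** — interstitial fibrosis as a random network of no-flux
  boundaries: the face between two neighbouring elements is severed with
  probability ``p = p_max * I * |cos(theta)|**alpha`` where ``I`` is the
  local normalised LGE intensity and ``theta`` the angle between the face
  normal and the fiber-sheet-normal direction, so clefts align with the
  fiber direction.  Optionally combined with a step-wise conductivity
  reduction over four LGE-intensity bands.
* **Non-cleft models** — a dense core (top fraction of the intensity
  range; non-conducting or very slowly conducting) surrounded by a border
  zone with reduced conduction velocities.

Shipped conductivities were obtained by bisection calibration of the
target conduction velocities on the standard 10 cm / 530 um cable
(:func:`scarwave.monodomain.calibrate_conductivity`); discrete lattices
distort the continuous CV–sigma relation, so velocities are never scaled
analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .mesh import LGEMap, TissueMesh
from .synth import STAGE_CLEFTS, stage_rng

# ---------------------------------------------------------------------------
# shipped conductivity table (S/m), calibrated on the standard cable

#: target conduction velocities (cm/s) behind each shipped conductivity
TARGET_CV_CMS = {
    "healthy_l": 54.4, "healthy_t": 33.5,           # non-fibrotic tissue
    "bz_l": 43.2, "bz_t": 17.9,                     # non-cleft border zone
    "reduced60_l": 0.6 * 54.4, "reduced20_l": 0.2 * 54.4,
    "reduced60_t": 0.6 * 33.5, "reduced20_t": 0.2 * 33.5,
}

#: calibrated conductivities achieving TARGET_CV_CMS on the standard cable
DEFAULT_SIGMA_SM = {
    "healthy_l": 0.18699992, "healthy_t": 0.10239474,
    "bz_l": 0.13910859, "bz_t": 0.05207053,
    "reduced60_l": 0.09919988, "reduced20_l": 0.0327102,
    "reduced60_t": 0.05848833, "reduced20_t": 0.02236068,
}

SIGMA_CORE_NONCONDUCTING = 1e-7   # S/m, isotropic: conduction block
SIGMA_CORE_COLLAGEN = 0.01        # S/m, isotropic: dense interstitial collagen


def calibrate_default_conductivities(tol_cms: float = 0.1) -> dict:
    """Recompute the shipped table by cable calibration (slow; minutes)."""
    from .monodomain import calibrate_conductivity

    out = {}
    for key, cv in TARGET_CV_CMS.items():
        direction = "longitudinal" if key.endswith("_l") else "transverse"
        out[key] = calibrate_conductivity(cv, direction, tol_cms)[0]
    return out


# ---------------------------------------------------------------------------
# cleft models

@dataclass(frozen=True)
class CleftParams:
    """Cleft-density parameters: ``p_max`` scales the maximum cleft density,
    ``alpha`` the anisotropy sharpening of the fiber-alignment factor."""

    p_max: float
    alpha: float = 2.0
    seed: int = 0
    #: 'exponent' uses |cos theta|**alpha; 'cos_alpha_theta' uses |cos(alpha*theta)|
    form: str = "exponent"

    def __post_init__(self):
        if not 0.0 <= self.p_max <= 1.0:
            raise ConfigError("p_max must be in [0, 1]")
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.form not in ("exponent", "cos_alpha_theta"):
            raise ConfigError(f"unknown Eq-form {self.form!r}")


@dataclass
class CleftMesh:
    """A mesh with severed faces (clefts) and fully isolated elements pruned."""

    mesh: TissueMesh
    severed: np.ndarray            # bool mask over mesh.faces
    removed_elements: np.ndarray   # element ids isolated by the clefts
    params: CleftParams | None = None

    @property
    def n_severed(self) -> int:
        return int(self.severed.sum())

    @property
    def n_removed(self) -> int:
        return int(self.removed_elements.size)


def cleft_probabilities(mesh: TissueMesh, lge: LGEMap,
                        params: CleftParams) -> np.ndarray:
    """Per-face severing probability ``p_max * I_face * |cos theta|**alpha``.

    ``I_face`` is the mean of the two adjacent elements' intensities; the
    sheet-normal direction is the in-plane perpendicular to the local fiber.
    """
    lge.check_mesh(mesh)
    faces = mesh.faces
    fib = mesh.fibers
    # in-plane sheet normal: rotate the fiber 90 degrees in the xy-plane
    sheet_n = np.column_stack([-fib[:, 1], fib[:, 0], np.zeros(len(fib))])
    face_sn = 0.5 * (sheet_n[faces[:, 0]] + sheet_n[faces[:, 1]])
    nrm = np.linalg.norm(face_sn, axis=1)
    face_sn = face_sn / np.where(nrm > 0, nrm, 1.0)[:, None]
    cos_t = np.abs((face_sn * mesh.face_normals()).sum(axis=1))
    if params.form == "exponent":
        aniso = cos_t ** params.alpha
    else:
        aniso = np.abs(np.cos(params.alpha * np.arccos(np.clip(cos_t, 0, 1))))
    i_face = 0.5 * (lge.intensity[faces[:, 0]] + lge.intensity[faces[:, 1]])
    return params.p_max * i_face * aniso


def split_clefts(mesh: TissueMesh, lge: LGEMap,
                 params: CleftParams) -> CleftMesh:
    """Sever each internal face independently with its cleft probability;
    prune elements left with no neighbours at all."""
    p = cleft_probabilities(mesh, lge, params)
    rng = stage_rng(params.seed, STAGE_CLEFTS)
    severed = rng.random(p.shape) < p

    faces = mesh.faces
    degree = np.zeros(mesh.n_elements, dtype=np.int64)
    np.add.at(degree, faces[~severed, 0], 1)
    np.add.at(degree, faces[~severed, 1], 1)
    # elements that had neighbours but lost all of them
    had = np.zeros(mesh.n_elements, dtype=np.int64)
    np.add.at(had, faces[:, 0], 1)
    np.add.at(had, faces[:, 1], 1)
    removed = np.flatnonzero((degree == 0) & (had > 0))
    return CleftMesh(mesh=mesh, severed=severed, removed_elements=removed,
                     params=params)


def default_fibmax_ladder(alpha: float = 2.0, seed: int = 0,
                          p_steps=None) -> list:
    """Default 10-entry ladder: ``p_max`` from 0 to 0.9 at fixed alpha."""
    if p_steps is None:
        p_steps = [0.1 * k for k in range(10)]
    return [CleftParams(p_max=p, alpha=alpha, seed=seed + k)
            for k, p in enumerate(p_steps)]


def build_fibmax_ladder(mesh: TissueMesh, lge: LGEMap,
                        ladder: list) -> list:
    """Split with every ladder entry and order by global cleft density.

    Returned list index is the fib_max value (0–9): entries are sorted
    ascending by severed-face count (removed-element count breaking ties),
    so fib_max 0 is the unsplit mesh and fib_max 9 the densest.
    """
    if len(ladder) != 10:
        raise ConfigError(f"fib_max ladder needs 10 entries, got {len(ladder)}")
    if ladder[0].p_max != 0.0:
        raise ConfigError("ladder entry 0 must have p_max = 0 (zero clefts)")
    metas = [split_clefts(mesh, lge, par) for par in ladder]
    metas.sort(key=lambda cm: (cm.n_severed, cm.n_removed))
    return metas


# ---------------------------------------------------------------------------
# region / conductivity assignment

CLEFT_LABELS = ("healthy", "band_0_25", "band_25_50", "band_50_75",
                "band_75_100")
NONCLEFT_LABELS = ("healthy", "border_zone", "core")


@dataclass
class RegionAssignment:
    """Per-element region label and conductivities (S/m)."""

    kind: str                 # 'cleft' or 'noncleft'
    labels: np.ndarray        # indices into label_names
    label_names: tuple
    sigma_l: np.ndarray
    sigma_t: np.ndarray

    def label_of(self, element: int) -> str:
        return self.label_names[self.labels[element]]

    def counts(self) -> dict:
        return {name: int((self.labels == i).sum())
                for i, name in enumerate(self.label_names)}


def assign_cleft_conductivity(lge: LGEMap,
                              sigma_table: dict | None = None
                              ) -> RegionAssignment:
    """Step-wise conductivity bands of the cleft models.

    Intensity bands over fibrotic tissue (half-open ``[lo, hi)``, top band
    closed at 1): 0–25 % and 25–50 % keep longitudinal velocity and reduce
    transverse velocity by 40 % and 80 %; 50–75 % and 75–100 % also reduce
    longitudinal velocity by 40 % and 80 %, with transverse reduced 80 %.
    Elements with zero intensity stay healthy.
    """
    tab = sigma_table or DEFAULT_SIGMA_SM
    for key in ("healthy_l", "healthy_t", "reduced60_l", "reduced20_l",
                "reduced60_t", "reduced20_t"):
        if key not in tab:
            raise ConfigError(f"calibration table missing {key!r}")
    I = lge.intensity
    labels = np.zeros(I.size, dtype=np.int64)
    pos = I > 0
    labels[pos & (I < 0.25)] = 1
    labels[(I >= 0.25) & (I < 0.5)] = 2
    labels[(I >= 0.5) & (I < 0.75)] = 3
    labels[I >= 0.75] = 4

    band_sigma = {
        0: (tab["healthy_l"], tab["healthy_t"]),
        1: (tab["healthy_l"], tab["reduced60_t"]),
        2: (tab["healthy_l"], tab["reduced20_t"]),
        3: (tab["reduced60_l"], tab["reduced20_t"]),
        4: (tab["reduced20_l"], tab["reduced20_t"]),
    }
    sl = np.empty(I.size)
    st = np.empty(I.size)
    for b, (l, t) in band_sigma.items():
        sl[labels == b] = l
        st[labels == b] = t
    return RegionAssignment("cleft", labels, CLEFT_LABELS, sl, st)


def assign_noncleft_regions(lge: LGEMap, core_size: int,
                            variant: str = "c",
                            sigma_table: dict | None = None
                            ) -> RegionAssignment:
    """Core / border-zone regions of the non-cleft models.

    The core is the top ``core_size`` per cent of the map's intensity range
    (elements with ``I >= (1 - core_size/100) * max(I)``); remaining
    LGE-positive elements form the border zone.  Core conductivity is
    isotropic: 1e-7 S/m for variant ``'nc'`` (conduction block) or
    0.01 S/m for variant ``'c'`` (dense collagen, slow conduction).
    """
    if core_size not in (25, 50, 75):
        raise ConfigError(f"core_size must be 25, 50 or 75, got {core_size}")
    if variant not in ("c", "nc"):
        raise ConfigError(f"variant must be 'c' or 'nc', got {variant!r}")
    tab = sigma_table or DEFAULT_SIGMA_SM
    I = lge.intensity
    imax = I.max()
    if imax <= 0:
        raise ConfigError("non-cleft model undefined on an all-zero LGE map")
    core = I >= (1.0 - core_size / 100.0) * imax
    bz = (I > 0) & ~core
    labels = np.zeros(I.size, dtype=np.int64)
    labels[bz] = 1
    labels[core] = 2
    sig_core = (SIGMA_CORE_COLLAGEN if variant == "c"
                else SIGMA_CORE_NONCONDUCTING)
    sl = np.full(I.size, tab["healthy_l"])
    st = np.full(I.size, tab["healthy_t"])
    sl[bz] = tab["bz_l"]
    st[bz] = tab["bz_t"]
    sl[core] = sig_core
    st[core] = sig_core
    return RegionAssignment("noncleft", labels, NONCLEFT_LABELS, sl, st)


def remodeling_mask(lge: LGEMap) -> np.ndarray:
    """Elements receiving HCM ionic remodeling: the entire fibrotic region
    (every element with positive intensity); binary, not intensity-graded."""
    return lge.intensity > 0
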