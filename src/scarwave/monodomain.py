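"""Anisotropic monodomain reaction–diffusion solver on lattice meshes.

Cell-centered finite volumes on the element lattice: each element carries
one node, faces carry a conductance from the harmonic mean of the two
elements' conductivity-tensor components along the face normal, and a
severed (cleft) face simply contributes no conductance — the no-flux
contract is exact by construction.  The anisotropic tensor is
``sigma_l f f^T + sigma_t (I - f f^T)``; on the lattice only the diagonal
components enter the 5/7-point stencil, so off-axis fiber angles are
represented through their axis projections.

Voltage is integrated forward-Euler, gates Rush–Larsen, with the membrane
kinetics of :mod:`scarwave.cell`.  Conductivities are in S/m and are
converted to a diffusion coefficient ``D = sigma / (beta * C_m)`` with the
standard monodomain constants ``beta`` = 1400 /cm and ``C_m`` = 1 uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .cell import CellParams, _cell_update, initial_state
from .errors import (BlowUpError, CalibrationError, ConfigError,
                     DimensionError, PropagationFailureError)
from .mesh import TissueMesh
from .records import ActivationRecord
from .synth import cable_spec, generate_mesh


@dataclass
class SimulationConfig:
    dt_ms: float = 0.02
    output_interval_ms: float = 10.0   # voltage-recording resolution
    duration_ms: float = 1000.0
    beta_per_cm: float = 1400.0        # surface-to-volume ratio
    cm_uf_per_cm2: float = 1.0         # membrane capacitance
    activation_threshold_mv: float = -40.0  # upstroke crossing
    max_activations: int = 128
    use_tables: bool = True            # table-accelerated membrane kernel
    rev_refresh_ms: float = 1.0        # reversal-potential refresh period

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ConfigError("dt must be > 0")
        if self.output_interval_ms < self.dt_ms:
            raise ConfigError("output interval must be >= dt")


@dataclass
class StimulusSpec:
    """Transmembrane current pulse over an electrode element set.

    Defaults follow the programmed-pacing pulse: 10 ms duration,
    100 uA/cm^2 amplitude over a ~1 mm^3 electrode volume.
    """

    nodes: np.ndarray
    onset_ms: float
    duration_ms: float = 10.0
    amplitude: float = 100.0

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)


def electrode_nodes(mesh: TissueMesh, center_element: int,
                    volume_mm3: float = 1.0) -> np.ndarray:
    """Element set nearest a center totalling the requested electrode volume."""
    elem_vol_mm3 = mesh.element_volume_ml * 1e3
    k = max(1, int(round(volume_mm3 / elem_vol_mm3)))
    d = np.linalg.norm(mesh.centers - mesh.centers[center_element], axis=1)
    return np.argsort(d, kind="stable")[:k].astype(np.int64)


# ---------------------------------------------------------------------------
# diffusion operator

def assemble_diffusion(mesh: TissueMesh, sigma_l: np.ndarray,
                       sigma_t: np.ndarray,
                       severed_faces: np.ndarray | None = None,
                       removed_elements: np.ndarray | None = None,
                       beta_per_cm: float = 1400.0,
                       cm_uf_per_cm2: float = 1.0) -> sp.csr_matrix:
    """Sparse operator ``L`` with ``dV/dt|_diff = L V`` (units 1/ms).

    ``sigma_l``/``sigma_t`` are per-element longitudinal and transverse
    conductivities in S/m.  ``severed_faces`` is a boolean mask over
    ``mesh.faces`` (True = cleft, zero conductance).  Removed elements get
    fully decoupled rows/columns.
    """
    n = mesh.n_elements
    sigma_l = np.asarray(sigma_l, dtype=float)
    sigma_t = np.asarray(sigma_t, dtype=float)
    if sigma_l.shape != (n,) or sigma_t.shape != (n,):
        raise DimensionError("sigma arrays must be per-element")
    bad = np.flatnonzero(~np.isfinite(sigma_l) | ~np.isfinite(sigma_t))
    if bad.size:
        raise ConfigError(f"element {int(bad[0])} has no assigned conductivity")

    faces = mesh.faces
    axis = mesh.face_axis
    f2 = mesh.fibers ** 2  # squared axis components of the fiber vectors
    # diagonal tensor component along each axis, per element
    sig_axis = sigma_t[:, None] + (sigma_l - sigma_t)[:, None] * f2  # (n, 3)

    keep = np.ones(faces.shape[0], dtype=bool)
    if severed_faces is not None:
        keep &= ~np.asarray(severed_faces, dtype=bool)
    if removed_elements is not None and len(removed_elements):
        rm = np.zeros(n, dtype=bool)
        rm[np.asarray(removed_elements, dtype=np.int64)] = True
        keep &= ~(rm[faces[:, 0]] | rm[faces[:, 1]])

    a = faces[keep, 0]
    b = faces[keep, 1]
    ax = axis[keep]
    sa = sig_axis[a, ax]
    sb = sig_axis[b, ax]
    harm = np.where(sa + sb > 0, 2.0 * sa * sb / np.maximum(sa + sb, 1e-300),
                    0.0)
    # S/m -> diffusion coefficient in cm^2/ms
    d_face = harm * 0.01 / (beta_per_cm * cm_uf_per_cm2 * 1e-6) / 1000.0
    h_cm = mesh.spacing_um / 1e4
    w = d_face / h_cm ** 2

    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([b, a, a, b])
    vals = np.concatenate([w, w, -w, -w])
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    L.sum_duplicates()
    return L


# ---------------------------------------------------------------------------
# compiled time stepping

@njit(cache=True)
def _advance_tissue(S, scales, g_nal, active, dt, nsteps, t0,
                    indptr, indices, data,
                    stim_ptr, stim_nodes, stim_on, stim_off, stim_amp,
                    vthresh, act_times, act_counts, above,
                    frames, frame_every):
    n = S.shape[0]
    nstim = stim_on.shape[0]
    frame_row = 0
    istim = np.zeros(n)
    for k in range(nsteps):
        t = t0 + k * dt
        # stimulus currents for this step
        for i in range(n):
            istim[i] = 0.0
        for q in range(nstim):
            if stim_on[q] <= t < stim_off[q]:
                for p in range(stim_ptr[q], stim_ptr[q + 1]):
                    istim[stim_nodes[p]] += stim_amp[q]
        for i in range(n):
            if not active[i]:
                continue
            # diffusion term (CSR row)
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * S[indices[p], 0]
            vold = S[i, 0]
            _cell_update(S[i], scales[i], g_nal, dt, istim[i], acc)
            vnew = S[i, 0]
            if not above[i] and vnew >= vthresh:
                c = act_counts[i]
                if c < act_times.shape[1]:
                    frac = (vthresh - vold) / (vnew - vold)
                    act_times[i, c] = t + frac * dt
                    act_counts[i] = c + 1
                above[i] = True
            elif above[i] and vnew < vthresh - 20.0:
                above[i] = False
        if frame_every > 0 and (k + 1) % frame_every == 0:
            for i in range(n):
                frames[frame_row, i] = S[i, 0]
            frame_row += 1
    return frame_row


@dataclass
class VoltageRecord:
    times_ms: np.ndarray
    frames: np.ndarray  # (n_frames, n_vertices), float32


@dataclass
class TissueState:
    """Resumable solver state (used by the pacing protocol for checkpoints)."""

    S: np.ndarray
    above: np.ndarray
    act_times: np.ndarray
    act_counts: np.ndarray
    t_ms: float

    def copy(self) -> "TissueState":
        return TissueState(self.S.copy(), self.above.copy(),
                           self.act_times.copy(), self.act_counts.copy(),
                           self.t_ms)


class MonodomainModel:
    """Assembled substrate: mesh + diffusion operator + per-cell parameters."""

    def __init__(self, mesh: TissueMesh, sigma_l, sigma_t,
                 remodeled_mask=None,
                 healthy: CellParams | None = None,
                 fibrotic: CellParams | None = None,
                 severed_faces=None, removed_elements=None,
                 config: SimulationConfig | None = None):
        self.mesh = mesh
        self.config = config or SimulationConfig()
        self.L = assemble_diffusion(
            mesh, sigma_l, sigma_t, severed_faces, removed_elements,
            self.config.beta_per_cm, self.config.cm_uf_per_cm2)
        n = mesh.n_elements
        healthy = healthy or CellParams()
        self.g_nal = healthy.g_NaL
        if remodeled_mask is None:
            remodeled_mask = np.zeros(n, dtype=bool)
        self.remodeled_mask = np.asarray(remodeled_mask, dtype=bool)
        self.scales = np.tile(healthy.scale_vector(), (n, 1))
        if fibrotic is not None:
            self.scales[self.remodeled_mask] = fibrotic.scale_vector()
        self.active = np.ones(n, dtype=bool)
        if removed_elements is not None and len(removed_elements):
            self.active[np.asarray(removed_elements, dtype=np.int64)] = False

    def fresh_state(self) -> TissueState:
        n = self.mesh.n_elements
        S = np.tile(initial_state(), (n, 1))
        return TissueState(
            S=S, above=np.zeros(n, dtype=bool),
            act_times=np.full((n, self.config.max_activations), np.nan),
            act_counts=np.zeros(n, dtype=np.int64), t_ms=0.0)

    def advance(self, state: TissueState, duration_ms: float,
                stimuli=(), record_frames: bool = True) -> VoltageRecord:
        """Advance ``state`` in place by ``duration_ms``."""
        cfg = self.config
        dt = cfg.dt_ms
        nsteps = int(round(duration_ms / dt))
        frame_every = int(round(cfg.output_interval_ms / dt)) \
            if record_frames else 0
        nframes = nsteps // frame_every if frame_every else 0
        frames = np.empty((nframes, self.mesh.n_elements), dtype=np.float32)

        if stimuli:
            stim_ptr = np.zeros(len(stimuli) + 1, dtype=np.int64)
            for i, st in enumerate(stimuli):
                stim_ptr[i + 1] = stim_ptr[i] + len(st.nodes)
            stim_nodes = np.concatenate([st.nodes for st in stimuli])
            stim_on = np.array([st.onset_ms for st in stimuli])
            stim_off = np.array([st.onset_ms + st.duration_ms
                                 for st in stimuli])
            stim_amp = np.array([st.amplitude for st in stimuli])
        else:
            stim_ptr = np.zeros(1, dtype=np.int64)
            stim_nodes = np.zeros(0, dtype=np.int64)
            stim_on = np.zeros(0)
            stim_off = np.zeros(0)
            stim_amp = np.zeros(0)

        Lc = self.L.tocsr()
        t0 = state.t_ms
        if cfg.use_tables:
            from .engine import _advance_tissue_tab, build_tables

            tab, xk1tab, rc_hl = build_tables(dt)
            if not hasattr(state, "_rev") or state._rev is None:
                state._rev = np.zeros((self.mesh.n_elements, 4))
            rev_every = max(1, int(round(cfg.rev_refresh_ms / dt)))
            nrow = _advance_tissue_tab(
                state.S, self.scales, self.g_nal, self.active, dt, nsteps,
                t0, Lc.indptr, Lc.indices, Lc.data,
                stim_ptr, stim_nodes, stim_on, stim_off, stim_amp,
                cfg.activation_threshold_mv, state.act_times,
                state.act_counts, state.above, frames, frame_every,
                tab, xk1tab, rc_hl, state._rev, rev_every)
        else:
            nrow = _advance_tissue(
                state.S, self.scales, self.g_nal, self.active, dt, nsteps,
                t0, Lc.indptr, Lc.indices, Lc.data,
                stim_ptr, stim_nodes, stim_on, stim_off, stim_amp,
                cfg.activation_threshold_mv, state.act_times,
                state.act_counts, state.above, frames, frame_every)
        state.t_ms = t0 + nsteps * dt
        v = state.S[self.active, 0]
        if not np.all(np.isfinite(v)):
            raise BlowUpError(
                f"monodomain solution diverged by t = {state.t_ms:.1f} ms",
                time_ms=state.t_ms)
        times = t0 + (np.arange(nrow) + 1) * cfg.output_interval_ms
        return VoltageRecord(times_ms=times, frames=frames[:nrow])

    def activation_record(self, state: TissueState) -> ActivationRecord:
        times = [state.act_times[v, :state.act_counts[v]]
                 for v in range(self.mesh.n_elements)]
        return ActivationRecord(times, self.mesh.n_elements,
                                active_mask=self.active.copy())


def simulate(mesh: TissueMesh, sigma_l, sigma_t, stimuli,
             config: SimulationConfig | None = None,
             remodeled_mask=None, fibrotic: CellParams | None = None,
             severed_faces=None, removed_elements=None):
    """One-shot simulation; returns ``(VoltageRecord, ActivationRecord)``."""
    config = config or SimulationConfig()
    model = MonodomainModel(mesh, sigma_l, sigma_t, remodeled_mask,
                            fibrotic=fibrotic, severed_faces=severed_faces,
                            removed_elements=removed_elements, config=config)
    state = model.fresh_state()
    vrec = model.advance(state, config.duration_ms, stimuli)
    return vrec, model.activation_record(state)


# ---------------------------------------------------------------------------
# conduction-velocity measurement and calibration on the standard cable

def measure_cable_cv(sigma_sm: float, direction: str = "longitudinal",
                     length_cm: float = 10.0, spacing_um: float = 530.0,
                     dt_ms: float = 0.02) -> float:
    """Conduction velocity (cm/s) on the standard 1D cable.

    The cable carries fibers along its axis for ``direction ==
    'longitudinal'`` and perpendicular for ``'transverse'``, so propagation
    samples the requested tensor component with conductivity ``sigma_sm``.
    Velocity is distance over activation-time difference between the 25 %
    and 75 % cable positions (central half, away from the ends).
    """
    if sigma_sm <= 0:
        raise PropagationFailureError("non-positive conductivity")
    spec = cable_spec(length_cm, spacing_um)
    mesh = generate_mesh(spec)
    n = mesh.n_elements
    if direction == "longitudinal":
        sl = np.full(n, sigma_sm)
        st = np.full(n, sigma_sm * 0.1)  # unused by axial propagation
        mesh.fibers[:] = [1.0, 0.0, 0.0]
    elif direction == "transverse":
        sl = np.full(n, sigma_sm * 10.0)  # unused by axial propagation
        st = np.full(n, sigma_sm)
        mesh.fibers[:] = [0.0, 1.0, 0.0]
    else:
        raise ConfigError(f"unknown direction {direction!r}")

    stim = StimulusSpec(nodes=np.arange(7), onset_ms=0.0)
    cfg = SimulationConfig(dt_ms=dt_ms, duration_ms=100.0,
                           output_interval_ms=10.0)
    model = MonodomainModel(mesh, sl, st, config=cfg)
    state = model.fresh_state()
    i25, i75 = int(0.25 * n), int(0.75 * n)
    # generous horizon (3 s): slow fibrotic waves can need > 2 s on 10 cm
    for _ in range(30):  # advance in 100 ms chunks until the wave arrives
        model.advance(state, 100.0, [stim] if state.t_ms == 0 else (),
                      record_frames=False)
        if state.act_counts[i75] > 0:
            break
    if state.act_counts[i75] == 0 or state.act_counts[i25] == 0:
        raise PropagationFailureError(
            f"wave failed to traverse the cable (sigma = {sigma_sm} S/m)")
    t25 = state.act_times[i25, 0]
    t75 = state.act_times[i75, 0]
    dist_cm = (i75 - i25) * spacing_um / 1e4
    return dist_cm / (t75 - t25) * 1000.0


def calibrate_conductivity(target_cv_cms: float,
                           direction: str = "longitudinal",
                           tol_cms: float = 0.1,
                           sigma_bracket=(1e-4, 5.0),
                           max_iter: int = 60):
    """Conductivity (S/m) whose cable velocity matches ``target_cv_cms``.

    Bisection on sigma, exploiting CV monotonicity in sigma; returns
    ``(sigma, achieved_cv)``.  Raises if the target lies outside what the
    discrete cable can propagate.
    """
    lo, hi = sigma_bracket

    def cv_or_zero(sig):
        try:
            return measure_cable_cv(sig, direction)
        except PropagationFailureError:
            return 0.0

    cv_hi = cv_or_zero(hi)
    if cv_hi < target_cv_cms:
        raise CalibrationErrorWithBracket(target_cv_cms, lo, hi, cv_hi)
    sig = hi
    cv = cv_hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection (sigma spans decades)
        cv_mid = cv_or_zero(mid)
        if abs(cv_mid - target_cv_cms) < tol_cms:
            return mid, cv_mid
        if cv_mid < target_cv_cms:
            lo = mid
        else:
            hi, sig, cv = mid, mid, cv_mid
    if abs(cv - target_cv_cms) < 10 * tol_cms:
        return sig, cv
    raise CalibrationErrorWithBracket(target_cv_cms, lo, hi, cv)


class CalibrationErrorWithBracket(CalibrationError):
    def __init__(self, target, lo, hi, best_cv):
        super().__init__(
            f"target CV {target} cm/s unreachable on the cable "
            f"(bracket [{lo:.2e}, {hi:.2e}] S/m, best {best_cv:.2f} cm/s)")
        self.bracket = (lo, hi)
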