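"""Human ventricular myocyte membrane model.

The membrane kinetics are the ten Tusscher–Panfilov 2006 human ventricular
model (epicardial variant) with the late sodium current I_NaL of the
O'Hara–Rudy 2011 model added to the total membrane current.  Fibrotic
("HCM-remodeled") tissue applies eight ionic scale factors measured in
hypertrophic-cardiomyopathy myocytes: I_NaL x2.07, I_CaL x1.19, I_Kr x0.66,
I_Ks x0.73, I_to x0.15, I_K1 x0.85, Na+/Ca2+ exchange x1.34 and SERCA
uptake x0.57.

Integration is Rush–Larsen for the Hodgkin–Huxley gates and forward Euler
for voltage and concentrations; the default time step of 0.02 ms is within
the forward-Euler stability bound for this model.  The single compiled
scalar kernel (:func:`_cell_update`) is the only implementation of the
kinetics and is shared by the single-cell and tissue solvers.

Units: voltage mV, time ms, currents pA/pF (equivalently uA/cm^2 at
C_m = 1 uF/cm^2), concentrations mM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import BlowUpError, ConfigError, NumericalError

# ---------------------------------------------------------------------------
# state layout

STATE_NAMES = (
    "V", "Nai", "Ki", "Cai", "CaSS", "CaSR",
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
    "d", "f", "f2", "fcass", "rbar", "mL", "hL",
)
N_STATE = len(STATE_NAMES)

#: order of the ionic scale factors in a scale vector
SCALE_NAMES = ("I_NaL", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1",
               "NCX", "SERCA")

HCM_SCALES = {
    "I_NaL": 2.07, "I_CaL": 1.19, "I_Kr": 0.66, "I_Ks": 0.73,
    "I_to": 0.15, "I_K1": 0.85, "NCX": 1.34, "SERCA": 0.57,
}


@dataclass(frozen=True)
class CellParams:
    """Maximal-conductance scale factors on top of the published model.

    ``g_NaL`` is the baseline late-sodium maximal conductance in mS/uF;
    the default is the O'Hara–Rudy endocardial value.  All scale factors
    default to 1 (healthy).
    """

    g_NaL: float = 0.0075
    scales: dict = field(default_factory=lambda: {k: 1.0 for k in SCALE_NAMES})
    remodeled: bool = False
    variant: str = "epi"  # informational; only the epicardial variant ships

    def scale_vector(self) -> np.ndarray:
        return np.array([self.scales[k] for k in SCALE_NAMES], dtype=float)


def apply_hcm_remodeling(params: CellParams) -> CellParams:
    """Apply the eight HCM ionic scale factors to a healthy parameter set."""
    if params.remodeled:
        raise ConfigError("HCM remodeling already applied; refusing to stack")
    scales = {k: params.scales[k] * HCM_SCALES[k] for k in SCALE_NAMES}
    return replace(params, scales=scales, remodeled=True)


def initial_state() -> np.ndarray:
    """Published resting initial conditions (settled further by pre-pacing)."""
    s = np.zeros(N_STATE)
    s[0] = -86.2     # V
    s[1] = 7.67      # Nai
    s[2] = 138.3     # Ki
    s[3] = 0.00007   # Cai
    s[4] = 0.00007   # CaSS
    s[5] = 1.3       # CaSR
    s[6] = 0.0       # m
    s[7] = 0.75      # h
    s[8] = 0.75      # j
    s[9] = 0.0       # xr1
    s[10] = 1.0      # xr2
    s[11] = 0.0      # xs
    s[12] = 0.0      # r
    s[13] = 1.0      # s
    s[14] = 0.0      # d
    s[15] = 1.0      # f
    s[16] = 1.0      # f2
    s[17] = 1.0      # fcass
    s[18] = 1.0      # rbar
    s[19] = 0.0      # mL
    s[20] = 0.5      # hL
    return s


# ---------------------------------------------------------------------------
# compiled kernel (single source of truth for the kinetics)

@njit(cache=True, fastmath=True)
def _cell_update(s, sc, g_nal_base, dt, i_dep, dv_diff):
    """Advance one cell by ``dt``.

    ``s`` is a length-21 state slice (updated in place), ``sc`` the
    8-vector of ionic scale factors, ``i_dep`` a depolarising (positive)
    stimulus current in pA/pF and ``dv_diff`` the diffusion contribution
    to dV/dt in mV/ms.
    """
    # constants -------------------------------------------------------------
    RTONF = 26.713760659695648  # R*T/F at 310 K, mV
    F = 96485.3415
    CAP = 0.185                 # uF, membrane capacitance of the cell
    Vc = 0.016404
    Vsr = 0.001094
    Vss = 0.00005468
    Ko = 5.4
    Nao = 140.0
    Cao = 2.0
    GNa = 14.838
    GK1 = 5.405
    Gto = 0.294                 # epicardial
    GKr = 0.153
    GKs = 0.392                 # epicardial
    GCaL = 0.0000398
    GbNa = 0.00029
    GbCa = 0.000592
    GpCa = 0.1238
    KpCa = 0.0005
    GpK = 0.0146
    pKNa = 0.03
    knak = 2.724
    KmK = 1.0
    KmNa = 40.0
    knaca = 1000.0
    KmNai = 87.5
    KmCa = 1.38
    ksat = 0.1
    nexp = 0.35
    Vmaxup = 0.006375
    Kup = 0.00025
    Vrel = 0.102
    k1_ = 0.15
    k2_ = 0.045
    k3 = 0.060
    k4 = 0.005
    EC = 1.5
    maxsr = 2.5
    minsr = 1.0
    Vleak = 0.00036
    Vxfer = 0.0038
    Bufc = 0.2
    Kbufc = 0.001
    Bufsr = 10.0
    Kbufsr = 0.3
    Bufss = 0.4
    Kbufss = 0.00025

    V = s[0]
    Nai = s[1]
    Ki = s[2]
    Cai = s[3]
    CaSS = s[4]
    CaSR = s[5]

    s_nal, s_cal, s_kr, s_ks, s_to, s_k1, s_ncx, s_serca = (
        sc[0], sc[1], sc[2], sc[3], sc[4], sc[5], sc[6], sc[7])

    # reversal potentials ----------------------------------------------------
    ENa = RTONF * math.log(Nao / Nai)
    EK = RTONF * math.log(Ko / Ki)
    EKs = RTONF * math.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    ECa = 0.5 * RTONF * math.log(Cao / Cai)

    # currents ---------------------------------------------------------------
    INa = GNa * s[6] ** 3 * s[7] * s[8] * (V - ENa)
    INaL = g_nal_base * s_nal * s[19] * s[20] * (V - ENa)

    x = 2.0 * (V - 15.0) / RTONF
    if abs(x) < 1e-7:
        dfac = 2.0 * F * (0.25 * CaSS - Cao)
    else:
        ex = math.exp(x)
        dfac = (4.0 * (V - 15.0) * F / RTONF
                * (0.25 * CaSS * ex - Cao) / (ex - 1.0))
    ICaL = GCaL * s_cal * s[14] * s[15] * s[16] * s[17] * dfac

    Ito = Gto * s_to * s[12] * s[13] * (V - EK)
    IKr = GKr * s_kr * math.sqrt(Ko / 5.4) * s[9] * s[10] * (V - EK)
    IKs = GKs * s_ks * s[11] * s[11] * (V - EKs)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - EK - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - EK + 100.0))
            + math.exp(0.1 * (V - EK - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - EK))))
    IK1 = GK1 * s_k1 * (ak1 / (ak1 + bk1)) * (V - EK)

    INaCa = (knaca * s_ncx
             * (1.0 / (KmNai ** 3 + Nao ** 3)) * (1.0 / (KmCa + Cao))
             * (1.0 / (1.0 + ksat * math.exp((nexp - 1.0) * V / RTONF)))
             * (math.exp(nexp * V / RTONF) * Nai ** 3 * Cao
                - math.exp((nexp - 1.0) * V / RTONF) * Nao ** 3 * Cai * 2.5))
    INaK = (knak * (Ko / (Ko + KmK)) * (Nai / (Nai + KmNa))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
               + 0.0353 * math.exp(-V / RTONF)))
    IpCa = GpCa * Cai / (KpCa + Cai)
    IpK = GpK * (V - EK) / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - ENa)
    IbCa = GbCa * (V - ECa)

    istim = -i_dep  # published sign convention: negative = depolarising
    itot = (INa + INaL + ICaL + Ito + IKr + IKs + IK1 + INaCa + INaK
            + IpCa + IpK + IbNa + IbCa + istim)

    # calcium subsystem ------------------------------------------------------
    kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / CaSR) ** 2)
    k1 = k1_ / kcasr
    k2 = k2_ * kcasr
    rbar = s[18]
    drbar = k4 * (1.0 - rbar) - k2 * CaSS * rbar
    s[18] = rbar + dt * drbar
    oo = k1 * CaSS * CaSS * s[18] / (k3 + k1 * CaSS * CaSS)
    Irel = Vrel * oo * (CaSR - CaSS)
    Ileak = Vleak * (CaSR - Cai)
    Iup = Vmaxup * s_serca / (1.0 + (Kup / Cai) ** 2)
    Ixfer = Vxfer * (CaSS - Cai)

    # analytic-buffer updates (quadratic solve per compartment)
    cacsqn = Bufsr * CaSR / (CaSR + Kbufsr)
    dcasr = dt * (Iup - Irel - Ileak)
    bjsr = Bufsr - cacsqn - dcasr - CaSR + Kbufsr
    cjsr = Kbufsr * (cacsqn + dcasr + CaSR)
    s[5] = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cassbuf = Bufss * CaSS / (CaSS + Kbufss)
    dcass = dt * (-Ixfer * (Vc / Vss) + Irel * (Vsr / Vss)
                  - ICaL * CAP / (2.0 * Vss * F))
    bcss = Bufss - cassbuf - dcass - CaSS + Kbufss
    ccss = Kbufss * (cassbuf + dcass + CaSS)
    s[4] = (math.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    cabuf = Bufc * Cai / (Cai + Kbufc)
    dcai = dt * (-(IbCa + IpCa - 2.0 * INaCa) * CAP / (2.0 * Vc * F)
                 - (Iup - Ileak) * (Vsr / Vc) + Ixfer)
    bc = Bufc - cabuf - dcai - Cai + Kbufc
    cc = Kbufc * (cabuf + dcai + Cai)
    s[3] = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    s[1] = Nai + dt * (-(INa + INaL + IbNa + 3.0 * INaK + 3.0 * INaCa)
                       * CAP / (Vc * F))
    s[2] = Ki + dt * (-(istim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK)
                      * CAP / (Vc * F))

    # gates (Rush-Larsen) ----------------------------------------------------
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
          + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 310000.0 * math.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * V)
              / (1.0 + math.exp(-0.1 * (V + 32.0))))
    else:
        aj = ((-25428.0 * math.exp(0.2444 * V)
               - 0.000006948 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * math.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8

    s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau_s = (85.0 * math.exp(-(V + 45.0) ** 2 / 320.0)
             + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * math.exp(-(V + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)

    f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * math.exp(-(V + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))

    css = CaSS / 0.05
    fcass_inf = 0.6 / (1.0 + css * css) + 0.4
    tau_fcass = 80.0 / (1.0 + css * css) + 2.0

    # O'Hara-Rudy late sodium gates
    ml_inf = 1.0 / (1.0 + math.exp(-(V + 42.85) / 5.264))
    tau_ml = 1.0 / (6.765 * math.exp((V + 11.64) / 34.77)
                    + 8.552 * math.exp(-(V + 77.42) / 5.955))
    hl_inf = 1.0 / (1.0 + math.exp((V + 87.61) / 7.488))
    tau_hl = 200.0

    s[6] = m_inf - (m_inf - s[6]) * math.exp(-dt / tau_m)
    s[7] = h_inf - (h_inf - s[7]) * math.exp(-dt / tau_h)
    s[8] = j_inf - (j_inf - s[8]) * math.exp(-dt / tau_j)
    s[9] = xr1_inf - (xr1_inf - s[9]) * math.exp(-dt / tau_xr1)
    s[10] = xr2_inf - (xr2_inf - s[10]) * math.exp(-dt / tau_xr2)
    s[11] = xs_inf - (xs_inf - s[11]) * math.exp(-dt / tau_xs)
    s[12] = r_inf - (r_inf - s[12]) * math.exp(-dt / tau_r)
    s[13] = s_inf - (s_inf - s[13]) * math.exp(-dt / tau_s)
    s[14] = d_inf - (d_inf - s[14]) * math.exp(-dt / tau_d)
    s[15] = f_inf - (f_inf - s[15]) * math.exp(-dt / tau_f)
    s[16] = f2_inf - (f2_inf - s[16]) * math.exp(-dt / tau_f2)
    s[17] = fcass_inf - (fcass_inf - s[17]) * math.exp(-dt / tau_fcass)
    s[19] = ml_inf - (ml_inf - s[19]) * math.exp(-dt / tau_ml)
    s[20] = hl_inf - (hl_inf - s[20]) * math.exp(-dt / tau_hl)

    s[0] = V + dt * (dv_diff - itot + 0.0)


@njit(cache=True)
def _advance_single(s, sc, g_nal, dt, nsteps, i_dep_amp, stim_steps,
                    vtrace, rec_every):
    """Advance one cell; stimulus applied for the first ``stim_steps`` steps."""
    row = 0
    for k in range(nsteps):
        i_dep = i_dep_amp if k < stim_steps else 0.0
        _cell_update(s, sc, g_nal, dt, i_dep, 0.0)
        if rec_every > 0 and (k + 1) % rec_every == 0:
            vtrace[row] = s[0]
            row += 1
    return row


# ---------------------------------------------------------------------------
# public API

def step_cell(state: np.ndarray, params: CellParams, dt: float = 0.02,
              I_stim: float = 0.0) -> np.ndarray:
    """Advance a single cell state one time step (returns a new array).

    ``dt`` must stay within the forward-Euler stability bound for voltage
    (<= 0.02 ms at default conductances).  ``I_stim >= 0`` is depolarising,
    in pA/pF.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    s = np.array(state, dtype=float)
    if s.shape != (N_STATE,):
        raise ConfigError(f"state must have shape ({N_STATE},)")
    _cell_update(s, params.scale_vector(), params.g_NaL, dt, I_stim, 0.0)
    if not np.all(np.isfinite(s)):
        bad = int(np.flatnonzero(~np.isfinite(s))[0])
        raise BlowUpError(
            f"non-finite state after step: variable {STATE_NAMES[bad]!r}",
            variable=STATE_NAMES[bad])
    return s


@dataclass
class PacingResult:
    t_ms: np.ndarray          # time within the final beat
    v_mV: np.ndarray
    apd90_ms: float
    apd_history: np.ndarray   # APD90 of every beat simulated
    final_state: np.ndarray
    n_beats_run: int
    captured: bool            # 1:1 capture on the final beat


def pace_single_cell(params: CellParams, bcl_ms: float = 500.0,
                     n_beats: int = 1000, dt: float = 0.02,
                     stim_amp: float = 52.0, stim_dur_ms: float = 1.0,
                     steady_delta_ms: float = 0.5,
                     steady_window: int = 10,
                     state: np.ndarray | None = None) -> PacingResult:
    """Pace a single cell at fixed cycle length and report the final beat.

    Pacing stops early once APD90 changes by less than ``steady_delta_ms``
    across ``steady_window`` beats (steady state), else after ``n_beats``.
    """
    if n_beats < 1:
        raise ConfigError("n_beats must be >= 1")
    s = initial_state() if state is None else np.array(state, dtype=float)
    sc = params.scale_vector()
    steps = int(round(bcl_ms / dt))
    stim_steps = int(round(stim_dur_ms / dt))
    rec_every = max(1, int(round(0.2 / dt)))   # 0.2 ms trace resolution
    nrec = steps // rec_every
    vtrace = np.empty(nrec)
    tvec = (np.arange(nrec) + 1) * rec_every * dt

    apds = []
    captured = False
    for beat in range(n_beats):
        nrow = _advance_single(s, sc, params.g_NaL, dt, steps, stim_amp,
                               stim_steps, vtrace, rec_every)
        if not np.all(np.isfinite(s)):
            raise BlowUpError("cell model diverged during pacing",
                              time_ms=(beat + 1) * bcl_ms)
        captured = bool(vtrace[:nrow].max() > 0.0)
        try:
            apds.append(apd90(tvec[:nrow], vtrace[:nrow]))
        except NumericalError:
            apds.append(np.nan)
            captured = False
        if (len(apds) > steady_window
                and np.isfinite(apds[-1])
                and abs(apds[-1] - apds[-1 - steady_window])
                < steady_delta_ms):
            break

    return PacingResult(t_ms=tvec.copy(), v_mV=vtrace[:nrec].copy(),
                        apd90_ms=apds[-1], apd_history=np.asarray(apds),
                        final_state=s, n_beats_run=len(apds),
                        captured=captured)


def apd90(t_ms: np.ndarray, v_mV: np.ndarray) -> float:
    """Action-potential duration at 90 % repolarization.

    Measured from the maximum-upstroke-velocity time to the first downward
    crossing of ``V_rest + 0.1 (V_peak - V_rest)``, with linear
    interpolation between samples.  If the trace holds several action
    potentials, the first is measured and a warning emitted.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mV, dtype=float)
    if t.size < 3 or t.size != v.size:
        raise NumericalError("trace too short for APD measurement")
    dv = np.diff(v) / np.diff(t)
    up_candidates = np.flatnonzero(dv > 10.0)  # mV/ms upstroke threshold
    if up_candidates.size == 0 or v.max() < -40.0:
        raise NumericalError("no action potential in trace")
    # group upstroke samples separated by > 5 ms into distinct APs
    groups = [up_candidates[0]]
    for i in up_candidates[1:]:
        if t[i] - t[groups[-1]] > 5.0 and v[i] < 0.0:
            groups.append(i)
    if len(groups) > 1:
        warnings.warn("trace contains multiple action potentials; "
                      "measuring the first", stacklevel=2)
    seg_start = groups[0]
    i_up = seg_start + int(np.argmax(dv[seg_start:seg_start + max(
        1, int(5.0 / max(t[1] - t[0], 1e-9)))]))
    t_up = 0.5 * (t[i_up] + t[i_up + 1])
    end = groups[1] if len(groups) > 1 else t.size - 1

    v_rest = v[:max(i_up, 1)].min() if i_up > 0 else v[0]
    v_peak = v[i_up:end + 1].max()
    i_peak = i_up + int(np.argmax(v[i_up:end + 1]))
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    for i in range(i_peak, end):
        if v[i] >= v90 > v[i + 1]:
            frac = (v[i] - v90) / (v[i] - v[i + 1])
            return t[i] + frac * (t[i + 1] - t[i]) - t_up
    raise NumericalError("repolarization never crossed the 90 % level")
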