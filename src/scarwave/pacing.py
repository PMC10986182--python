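"""Programmed S1–S4 electrical stimulation and experiment enumeration.

Each pacing site receives a drive train (S1) followed by up to three
progressively premature extrastimuli (S2–S4).  Extrastimulus couplings are
chosen adaptively around a refractory-period estimate: a coupling that
fails to capture is lengthened, a captured one is optionally tightened, so
each stage ends at (close to) its most premature captured coupling.  Once
reentry is detected no further extrastimuli are delivered, and every run
ends with an observation window after the last stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mesh import TissueMesh
from .monodomain import MonodomainModel, StimulusSpec, electrode_nodes
from .records import ActivationRecord
from .reentry import label_reentrant_activations, merge_rapid_activations

log = logging.getLogger("scarwave.pacing")


@dataclass(frozen=True)
class ProtocolSpec:
    """S1–S4 programmed-stimulation constants (all config-exposed)."""

    s1_count: int = 6
    s1_cycle_ms: float = 600.0
    coupling_start_ms: float = 320.0   # first S2 attempt after last S1
    coupling_decrement_ms: float = 10.0
    coupling_min_ms: float = 180.0
    scan_down: int = 2          # extra tightening attempts once captured
    scan_up: int = 6            # lengthening attempts after failed capture
    max_extrastimuli: int = 3
    observation_ms: float = 4000.0
    capture_fraction: float = 0.9
    capture_window_ms: float = 220.0
    stim_duration_ms: float = 10.0
    stim_amplitude: float = 100.0
    electrode_volume_mm3: float = 1.0
    merge_window_ms: float = 50.0

    def __post_init__(self):
        if self.coupling_start_ms <= self.coupling_min_ms:
            raise ConfigError("coupling_start must exceed coupling_min")
        if self.max_extrastimuli > 3:
            raise ConfigError("at most 3 extrastimuli (S2-S4)")


@dataclass
class RunOutcome:
    site: int
    n_captured: int
    extrastimuli_delivered: int
    extrastimuli_before_reentry: int | None  # 1-3, or None if no reentry
    reentry: bool
    sustained: bool
    stimulus_log: list                        # (label, onset_ms, coupling_ms)
    record: ActivationRecord
    last_stim_time_ms: float
    couplings_ms: tuple


def select_pacing_sites(mesh: TissueMesh, segments: np.ndarray,
                        volume_mm3: float = 1.0):
    """One electrode element set per segment, centered in the segment."""
    segments = np.asarray(segments)
    sites = []
    for s in np.unique(segments):
        elems = np.flatnonzero(segments == s)
        centroid = mesh.centers[elems].mean(axis=0)
        center = elems[np.argmin(
            np.linalg.norm(mesh.centers[elems] - centroid, axis=1))]
        nodes = electrode_nodes(mesh, int(center), volume_mm3)
        if not np.isin(nodes, elems).all():
            # electrode clipped to its own segment to keep sets disjoint
            nodes = nodes[np.isin(nodes, elems)]
        if nodes.size == 0:
            raise ConfigError(f"segment {s} too small for an electrode")
        sites.append(nodes)
    return sites


def _capture_and_reentry(model, state, t_stim, n_captured, spec):
    """Capture check plus a quick reentry probe on the accumulated record."""
    rec = model.activation_record(state)
    first_after = np.array([
        t[(t > t_stim)][0] if (t > t_stim).any() else np.nan
        for t in (np.asarray(x) for x in rec.times)])
    conducting = rec.active_mask
    frac = np.mean(np.isfinite(first_after[conducting]))
    captured = frac >= spec.capture_fraction

    # pure index rule: slow fibrotic conduction must not read as reentry
    re_series = label_reentrant_activations(
        rec, n_captured + (1 if captured else 0))
    re_series = merge_rapid_activations(re_series, spec.merge_window_ms)
    reentry = any(len(t) for t in re_series)
    return captured, reentry


def run_protocol(model: MonodomainModel, site_nodes, spec: ProtocolSpec,
                 site_id: int = 0) -> RunOutcome:
    """Deliver the full programmed-stimulation sequence from one site."""
    nodes = np.asarray(site_nodes, dtype=np.int64)
    state = model.fresh_state()
    stim_log = []

    def stim(onset):
        return StimulusSpec(nodes=nodes, onset_ms=onset,
                            duration_ms=spec.stim_duration_ms,
                            amplitude=spec.stim_amplitude)

    # S1 drive train ---------------------------------------------------------
    stims = [stim(k * spec.s1_cycle_ms) for k in range(spec.s1_count)]
    for k, st in enumerate(stims):
        stim_log.append((f"S1.{k + 1}", st.onset_ms,
                         spec.s1_cycle_ms if k else 0.0))
    last_stim = (spec.s1_count - 1) * spec.s1_cycle_ms
    model.advance(state, last_stim + spec.capture_window_ms, stims,
                  record_frames=False)
    n_captured = spec.s1_count  # S1 capture assumed; verified by analysis
    captured, reentry = _capture_and_reentry(model, state, last_stim,
                                             n_captured - 1, spec)
    if not captured:
        log.warning("site %d: S1 train failed the capture criterion", site_id)

    couplings = []
    n_extra = 0
    extra_before_reentry = None

    # extrastimuli -----------------------------------------------------------
    while not reentry and n_extra < spec.max_extrastimuli:
        c = spec.coupling_start_ms if not couplings else couplings[-1]
        checkpoint = state.copy()
        chosen = None
        # lengthen until capture
        for _ in range(spec.scan_up + 1):
            trial = checkpoint.copy()
            t_stim = last_stim + c
            model.advance(trial, t_stim + spec.capture_window_ms
                          - trial.t_ms, [stim(t_stim)], record_frames=False)
            cap, re_flag = _capture_and_reentry(model, trial, t_stim,
                                                n_captured, spec)
            if cap:
                chosen = (c, trial, re_flag)
                break
            c += spec.coupling_decrement_ms
        if chosen is None:
            log.info("site %d: S%d never captured; stopping protocol",
                     site_id, n_extra + 2)
            break
        # tighten while still capturing (most premature captured coupling)
        c_cap, trial_cap, re_flag = chosen
        for _ in range(spec.scan_down):
            c_try = c_cap - spec.coupling_decrement_ms
            if c_try < spec.coupling_min_ms or re_flag:
                break
            trial = checkpoint.copy()
            t_stim = last_stim + c_try
            model.advance(trial, t_stim + spec.capture_window_ms
                          - trial.t_ms, [stim(t_stim)], record_frames=False)
            cap, re2 = _capture_and_reentry(model, trial, t_stim,
                                            n_captured, spec)
            if not cap:
                break
            c_cap, trial_cap, re_flag = c_try, trial, re2

        state = trial_cap
        last_stim = last_stim + c_cap
        couplings.append(c_cap)
        n_extra += 1
        n_captured += 1
        stim_log.append((f"S{n_extra + 1}", last_stim, c_cap))
        reentry = re_flag
        if reentry:
            extra_before_reentry = n_extra

    # observation window -----------------------------------------------------
    remaining = last_stim + spec.observation_ms - state.t_ms
    if remaining > 0:
        model.advance(state, remaining, (), record_frames=False)

    rec = model.activation_record(state)
    re_series = merge_rapid_activations(
        label_reentrant_activations(rec, n_captured), spec.merge_window_ms)
    reentry_final = any(len(t) for t in re_series)
    if reentry_final and extra_before_reentry is None and n_extra > 0:
        extra_before_reentry = n_extra
    sustained = False
    if reentry_final:
        latest = max(t[-1] for t in re_series if len(t))
        sustained = latest >= last_stim + spec.observation_ms \
            - 2 * model.config.output_interval_ms

    return RunOutcome(site=site_id, n_captured=n_captured,
                      extrastimuli_delivered=n_extra,
                      extrastimuli_before_reentry=extra_before_reentry,
                      reentry=bool(reentry_final), sustained=bool(sustained),
                      stimulus_log=stim_log, record=rec,
                      last_stim_time_ms=last_stim,
                      couplings_ms=tuple(couplings))


# ---------------------------------------------------------------------------
# experiment enumeration

def full_design_populations() -> dict:
    """The full model-population design (37 models per geometry)."""
    from .models import DEFAULT_LEVELS

    return {v: list(levels) for v, levels in DEFAULT_LEVELS.items()}


def enumerate_experiments(populations, geometries, n_sites: int = 17
                          ) -> pd.DataFrame:
    """Run manifest over (geometry, variant, level, site) combinations.

    ``populations`` maps variant name -> iterable of parameter levels
    (fib_max values or core sizes); the full study design over five
    geometries enumerates (10+10+10+1+3+3) x 5 x 17 = 3,145 runs.
    """
    from .models import ALL_VARIANTS

    rows = []
    for geom in geometries:
        for variant, levels in populations.items():
            if variant not in ALL_VARIANTS:
                raise ConfigError(f"unknown variant {variant!r}")
            for level in levels:
                for site in range(n_sites):
                    rows.append((geom, variant, level, site))
    df = pd.DataFrame(rows, columns=["geometry", "variant", "level", "site"])
    df.insert(0, "run_id", [
        f"{g}_{v}_{l}_s{s:02d}" for g, v, l, s in rows])
    return df
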