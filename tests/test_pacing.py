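"""Protocol logic (on a scripted substrate) and experiment enumeration."""

import numpy as np
import pytest

from scarwave.errors import ConfigError
from scarwave.monodomain import SimulationConfig
from scarwave.pacing import (ProtocolSpec, enumerate_experiments,
                             full_design_populations, run_protocol,
                             select_pacing_sites)
from scarwave.records import ActivationRecord
from scarwave.synth import SyntheticSpec, generate_mesh, generate_segments


class FakeState:
    def __init__(self):
        self.t_ms = 0.0
        self.stims = []

    def copy(self):
        c = FakeState()
        c.t_ms = self.t_ms
        c.stims = list(self.stims)
        return c


class FakeModel:
    """Scripted substrate: captures above an ERP, reenters below a coupling.

    Lets the protocol logic (adaptive coupling scan, early stopping,
    observation) be tested without any reaction–diffusion simulation.
    """

    def __init__(self, n=40, erp_ms=250.0, reentry_coupling_ms=None,
                 sustained=False):
        self.n = n
        self.erp = erp_ms
        self.reentry_coupling = reentry_coupling_ms
        self.sustained = sustained
        self.config = SimulationConfig()

    def fresh_state(self):
        return FakeState()

    def advance(self, state, duration_ms, stimuli=(), record_frames=True):
        for st in stimuli:
            state.stims.append(float(st.onset_ms))
        state.t_ms += float(duration_ms)

    def activation_record(self, state):
        times = [[] for _ in range(self.n)]
        prev = None
        reentry_onset = None
        for onset in sorted(state.stims):
            captured = prev is None or (onset - prev) >= self.erp
            if not captured:
                continue
            coupling = onset - prev if prev is not None else np.inf
            for v in range(self.n):
                times[v].append(onset + 1.0)
            if (self.reentry_coupling is not None
                    and coupling <= self.reentry_coupling
                    and reentry_onset is None):
                reentry_onset = onset
            prev = onset
        if reentry_onset is not None:
            t = reentry_onset + 60.0
            while t < state.t_ms:
                for v in range(self.n):
                    times[v].append(t)
                if not self.sustained:
                    break
                t += 55.0  # above the merge window, dense enough to last
        return ActivationRecord(times, self.n)


def quick_spec(**kw):
    base = dict(s1_count=2, s1_cycle_ms=400.0, coupling_start_ms=320.0,
                coupling_min_ms=200.0, scan_down=2, scan_up=3,
                observation_ms=1000.0)
    base.update(kw)
    return ProtocolSpec(**base)


class TestRunProtocolLogic:
    def test_reentry_stops_further_extrastimuli(self):
        model = FakeModel(erp_ms=250.0, reentry_coupling_ms=300.0)
        out = run_protocol(model, np.arange(3), quick_spec())
        assert out.reentry
        assert out.extrastimuli_delivered == 1
        assert out.extrastimuli_before_reentry == 1
        labels = [lab for lab, *_ in out.stimulus_log]
        assert "S2" in labels and "S3" not in labels

    def test_failed_capture_lengthens_coupling(self):
        model = FakeModel(erp_ms=330.0)  # S2 at 320 cannot capture
        out = run_protocol(model, np.arange(3), quick_spec())
        assert out.couplings_ms[0] == 330.0
        assert out.extrastimuli_delivered == 3
        assert not out.reentry

    def test_tightening_finds_most_premature_captured_coupling(self):
        model = FakeModel(erp_ms=250.0)  # everything captures; no reentry
        out = run_protocol(model, np.arange(3), quick_spec())
        # scan_down = 2: 320 -> 310 -> 300 all captured
        assert out.couplings_ms[0] == 300.0

    def test_sustained_flag_implies_reentry(self):
        model = FakeModel(erp_ms=250.0, reentry_coupling_ms=310.0,
                          sustained=True)
        out = run_protocol(model, np.arange(3), quick_spec())
        assert out.reentry and out.sustained
        unsust = run_protocol(FakeModel(erp_ms=250.0,
                                        reentry_coupling_ms=310.0),
                              np.arange(3), quick_spec())
        assert unsust.reentry and not unsust.sustained

    def test_stimulus_log_strictly_ordered(self):
        model = FakeModel(erp_ms=250.0)
        out = run_protocol(model, np.arange(3), quick_spec())
        onsets = [t for _, t, _ in out.stimulus_log]
        assert np.all(np.diff(onsets) > 0)


class TestPacingSites:
    def test_17_disjoint_electrode_sets(self):
        mesh = generate_mesh(SyntheticSpec(grid_shape=(100, 100)))
        segs = generate_segments(mesh, 17)
        sites = select_pacing_sites(mesh, segs)
        assert len(sites) == 17
        all_nodes = np.concatenate(sites)
        assert len(all_nodes) == len(set(all_nodes))
        for s, nodes in zip(range(17), sites):
            assert np.all(segs[nodes] == s)

    def test_single_segment_gets_centroid_site(self):
        mesh = generate_mesh(SyntheticSpec(grid_shape=(20, 20)))
        sites = select_pacing_sites(mesh, np.zeros(400, dtype=int))
        assert len(sites) == 1
        center = mesh.centers[sites[0]].mean(axis=0)
        assert np.allclose(center[:2], 5.3, atol=0.6)

    def test_electrode_volume_near_1mm3(self):
        mesh = generate_mesh(SyntheticSpec(grid_shape=(100, 100)))
        segs = generate_segments(mesh, 17)
        sites = select_pacing_sites(mesh, segs, volume_mm3=1.0)
        ev = mesh.element_volume_ml * 1e3  # mm^3
        for nodes in sites:
            assert abs(len(nodes) * ev - 1.0) <= ev  # within one element


class TestEnumeration:
    def test_full_design_yields_3145_runs(self):
        manifest = enumerate_experiments(
            full_design_populations(),
            geometries=[f"g{i}" for i in range(5)], n_sites=17)
        assert len(manifest) == 3145
        assert manifest["run_id"].is_unique

    def test_single_population_single_geometry(self):
        manifest = enumerate_experiments({"noncleft_c": [25, 50, 75]},
                                         ["g0"], n_sites=17)
        assert len(manifest) == 51

    def test_empty_population_list(self):
        manifest = enumerate_experiments({}, ["g0"], n_sites=17)
        assert len(manifest) == 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            enumerate_experiments({"mystery": [1]}, ["g0"])

    def test_manifest_is_product_of_factor_levels(self):
        pops = {"cleft_gm": [0, 5, 9], "noncleft_nc": [25]}
        manifest = enumerate_experiments(pops, ["g0", "g1"], n_sites=4)
        assert len(manifest) == (3 + 1) * 2 * 4
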