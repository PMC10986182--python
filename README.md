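# scarwave

Fibrosis representations in ventricular electrophysiology models — and
how the choice changes simulated reentrant arrhythmia.

Patients with non-ischemic cardiomyopathy show fibrosis on late
gadolinium enhancement (LGE) imaging, and computational models use that
signal to build arrhythmia substrates two very different ways:

* **cleft models** — a random network of microscopic no-flux boundaries
  ("clefts") severing element faces with probability
  `p = p_max · I · |cos θ|^α` (I = normalised LGE intensity, θ = angle to
  the fiber-sheet normal), optionally with step-wise conductivity
  reduction and ionic remodeling; global density indexed by `fib_max` 0–9;
* **non-cleft models** — a dense core (top 25/50/75 % of the intensity
  range; non-conducting at 1e-7 S/m or slowly conducting at 0.01 S/m)
  inside a border zone with reduced conduction velocities (43.2/17.9 cm/s
  vs. healthy 54.4/33.5 cm/s).

`scarwave` builds both substrate families on synthetic LGE maps over
regular lattices (530 µm resolution), simulates anisotropic monodomain
propagation with a human ventricular myocyte model (ten Tusscher 2006 +
O'Hara–Rudy late sodium current; hypertrophic-cardiomyopathy ionic
remodeling in fibrotic tissue), induces reentry with programmed S1–S4
pacing, and then automatically detects reentry, back-traces it to its
initiation sites on the activation graph, extracts local LGE features,
and tests segment-level associations with negative-binomial count
regression.  See `docs/methods.md` for the model details and numerical
choices.

## Worked example

```python
import numpy as np
from scarwave import SyntheticSpec, generate_mesh, generate_lge, generate_segments
from scarwave.models import build_model
from scarwave.pacing import ProtocolSpec, run_protocol, select_pacing_sites
from scarwave.reentry import (label_reentrant_activations,
                              merge_rapid_activations, trace_initiation)
from scarwave.features import local_lge_features

spec = SyntheticSpec(grid_shape=(40, 40), patch_radii_mm=(9.0,), seed=3)
mesh = generate_mesh(spec)          # 2.12 cm sheet at 530 µm
lge = generate_lge(spec, mesh)      # radial fibrotic patch, peak 1.0
segs = generate_segments(mesh, 17)
sites = select_pacing_sites(mesh, segs)

model = build_model(mesh, lge, "noncleft_c", 75, seed=3)  # large slow core
proto = ProtocolSpec(s1_count=2, s1_cycle_ms=450.0, coupling_start_ms=300.0,
                     coupling_min_ms=200.0, scan_down=3, observation_ms=1000.0)
out = run_protocol(model, sites[0], proto)
print(f"reentry={out.reentry}, extrastimuli before reentry="
      f"{out.extrastimuli_before_reentry}")

series = merge_rapid_activations(
    label_reentrant_activations(out.record, out.n_captured))
for cl in trace_initiation(series, mesh, min_cluster=5)[:3]:
    f = local_lge_features(cl.center_mm, mesh, lge, radius_mm=5.0)
    print(f"site at ({cl.center_mm[0]:.1f}, {cl.center_mm[1]:.1f}) mm, "
          f"{cl.size} vertices, mean local LGE {f.mean_lge_pct:.1f} %")
```

prints (a few minutes on one CPU):

```
reentry=True, extrastimuli before reentry=3
site at (7.2, 17.6) mm, 22 vertices, mean local LGE 18.2 %
site at (5.7, 18.6) mm, 163 vertices, mean local LGE 10.0 %
site at (15.8, 19.1) mm, 81 vertices, mean local LGE 9.4 %
```

meaning the third extrastimulus induced reentry, initiated from several
clusters around the slow core, in surroundings of intermediate LGE
intensity (the first two classify as Type 1, the third as Type 2 under
the 10 % morphology heuristic).

The same pipeline is scriptable from the shell (`scarwave generate`,
`scarwave run-study`, `scarwave analyze`, `scarwave stats`) driven by a
YAML study config; `scarwave run-study` is resumable and enumerates the
full factorial design — 37 models × 5 geometries × 17 sites = 3,145 runs
for the complete study — as a manifest you can execute selectively.

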