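# Methods

`scarwave` compares two ways of representing fibrosis in ventricular
electrophysiology models — heterogeneous networks of interstitial clefts
versus a dense core with a surrounding border zone — and measures how the
choice shapes reentry induction, initiation sites and their statistics.
Everything runs at desk scale on idealized lattice geometries carrying
synthetic LGE-like intensity maps.

## Tissue and geometry

The substrate is a regular quadrilateral (2D) or thin hexahedral (3D)
lattice of elements at 530 um spacing, the element scale of
clinical-resolution ventricular meshes.  Patient anatomy, image
segmentation and rule-based fiber fields are out of scope; fibers default
to a uniform in-plane angle with an optional linear transmural rotation
for slabs.  The solver is cell-centered: one node per element, faces
carrying the conductance.  This makes the cleft contract exact: severing a
face removes its conductance and nothing else, so a cleft is a perfect
local no-flux boundary regardless of discretization details.

Synthetic LGE maps are normalised to [0, 1] per map (0 = healthy, 1 = the
subject's maximum).  Three patterns ship: a single radial-ramp patch
(default: 12 mm radius, peak 1.0, centered), multiple patches, and a
smoothed Gaussian random field for diffuse texture (correlation length
~4 mm, squared to sharpen a dense core).  Additive Gaussian intensity
noise (default SD 0.02) is applied inside lesions and clipped to [0, 1].
What the generator does *not* emulate: imaging point-spread and partial
voluming, anisotropic lesion shapes tied to fiber architecture, and
through-wall intensity gradients — so passing tests demonstrate the
machinery on plausible intensity fields, not fidelity to any patient.

Segment labels tile the longest axis into near-equal contiguous strips
(boundaries by integer division), an idealized analogue of the 17-segment
left-ventricular parcellation used for pacing-site placement and
segment-level statistics.

All randomness descends from one integer master seed through keyed
`SeedSequence` children, one stage key each for LGE generation, cleft
splitting, protocol and statistics, so runs are bit-reproducible and
adding a stage never shifts another stage's draws.

## Cleft models

The face between neighbouring elements is severed with probability

    p = p_max * I_face * |cos(theta)| ** alpha

with `I_face` the mean of the two elements' intensities and `theta` the
angle between the face normal and the fiber-sheet-normal direction (in
2D, the in-plane perpendicular to the fiber).  The anisotropy exponent
concentrates clefts on faces aligned with the fiber direction, the
geometry of interstitial fibrosis.  The printed form of this rule is
typographically ambiguous ("|cos a theta|"); the exponent reading is
implemented as the default because an exponent is the standard sharpening
form, and the multiplier-inside-cosine reading remains selectable
(`CleftParams.form`).  Elements isolated from all neighbours are removed
from the conducting mesh.

Global cleft density is indexed by `fib_max` 0–9: ten parameter
combinations (default `p_max` = 0.0–0.9 at fixed `alpha` = 2) are split
and then ordered by the number of severed faces (removed elements
breaking ties), with index 0 the unsplit mesh.  The exact parameter grid
behind the ten levels is configuration, not physics.

Step-wise conductivity reduction divides fibrotic tissue into four
intensity bands (half-open, top band closed): 0–25 % and 25–50 % keep
longitudinal velocity and reduce transverse velocity by 40 % and 80 %;
50–75 % and 75–100 % additionally reduce longitudinal velocity by 40 %
and 80 %, transverse staying at −80 %.

## Non-cleft models

The core is the top `core_size` per cent of the map's intensity range
(25/50/75; larger `core_size` = larger core); remaining LGE-positive
tissue is border zone, with conduction velocities 43.2/17.9 cm/s.  Core
conductivity is isotropic: 1e-7 S/m (conduction block, `noncleft_nc`) or
0.01 S/m (dense collagen, `noncleft_c`).  On the 530 um lattice a uniform
0.01 S/m cable blocks with healthy membrane kinetics but conducts at
~3 cm/s with the remodeled (high late-sodium) kinetics that core tissue
actually carries — slow-core conduction at desk scale is a joint property
of the conductivity and the remodeled membrane.

## Membrane model

Healthy tissue uses the ten Tusscher–Panfilov 2006 human ventricular
model with the O'Hara–Rudy late sodium current added to the total
current.  The epicardial variant is the default because its
action-potential duration at the 2 Hz working rate is closest to the
model population's stated behaviour; the baseline late-sodium conductance
is the O'Hara–Rudy endocardial value (0.0075 mS/uF).  Both choices are
configuration, and APD targets carry a ±10 ms tolerance because neither
is pinned down externally.

Fibrotic ("HCM") remodeling applies eight scale factors to every element
with positive LGE intensity, binary rather than intensity-graded:
I_NaL x2.07, I_CaL x1.19, I_Kr x0.66, I_Ks x0.73, I_to x0.15, I_K1 x0.85,
Na+/Ca2+ exchange x1.34, SERCA x0.57.  At 500 ms cycle length, pacing to
the steady-state criterion below gives APD90 = 287.8 ms (healthy) and
338.7 ms (remodeled); full 1,000-beat pre-pacing gives 270.3/325.0 ms.
Pre-pacing stops early once APD90 changes by < 0.5 ms across 10 beats
(capped at 1,000 beats) — a documented scaled-down stand-in for fixed
1,000-beat pre-pacing.

Integration is Rush–Larsen for Hodgkin–Huxley gates and forward Euler for
voltage and concentrations at dt = 0.02 ms; halving dt moves steady-state
APD90 by < 1 ms.  Tissue runs use a table-accelerated kernel (all
voltage-dependent rates pre-tabulated on a 0.05 mV grid over
[−200, 600] mV, reversal potentials refreshed every 1 ms); it agrees with
the direct kernel to < 0.05 ms in activation times and is cross-checked in
the suite.

## Monodomain solver and calibration

Standard monodomain constants: surface-to-volume ratio 1400 /cm, membrane
capacitance 1 uF/cm^2, conductivity tensor `sigma_l f f^T + sigma_t
(I − f f^T)` reduced to its diagonal components on the lattice stencil
(off-diagonal anisotropy terms of obliquely angled fibers are not
represented — a stated limitation of the 5/7-point scheme).  Face
conductances use the harmonic mean of the adjacent elements' tensor
components, so a near-insulating element blocks flux into it.

Conductivities are never derived analytically from velocities: the
discrete lattice slows waves below the continuum `CV ∝ sqrt(sigma)` law
(on a refined 100 um / 0.5 us cable the quadrupling ratio returns to
2.0 within a few per cent; on the standard cable it is ~2.5).  Every
shipped conductivity was instead calibrated by geometric bisection on the
standard 10 cm, 530 um cable (tolerance 0.1 cm/s), measuring velocity
between the 25 % and 75 % positions:

| target CV (cm/s) | sigma (S/m) |
|---|---|
| 54.4 (healthy longitudinal) | 0.18700 |
| 33.5 (healthy transverse) | 0.10239 |
| 43.2 (border-zone longitudinal) | 0.13911 |
| 17.9 (border-zone transverse) | 0.05207 |
| 32.6 / 10.9 (reduced longitudinal) | 0.09920 / 0.03271 |
| 20.1 / 6.7 (reduced transverse) | 0.05849 / 0.02236 |

`calibrate_default_conductivities()` regenerates the table.

Stimuli are transmembrane current pulses (default 10 ms, 100 uA/cm^2)
over an electrode element set nearest 1 mm^3.  The strong pulse drives
electrode elements far above the physiological range transiently
(~+450 mV); the kernel and its tables cover this range and the overshoot
stays confined to the electrode during the pulse.  Activation is the
upstroke crossing of −40 mV (re-armed 20 mV below threshold), linearly
interpolated in time.

## Pacing protocol

Programmed stimulation delivers an S1 drive train (default 6 beats at
600 ms) and up to three extrastimuli.  Coupling intervals adapt around
capture: a failed coupling is lengthened in 10 ms steps; a captured one is
optionally tightened while capture persists, ending at (close to) the most
premature captured coupling.  Capture means ≥ 90 % of conducting vertices
activate within a 220 ms window of the stimulus.  Once reentry is
detected — any vertex with more merged activations than captured
stimuli — no further extrastimuli are delivered, and each run ends with a
4,000 ms observation window after the last stimulus.  All constants are
configuration; the desk-scale tests shorten the train (2 beats at 450 ms)
and the observation window, stated with each test.

## Reentry analysis

Reentrant activations are those beyond the n-th for n captured stimuli
(pure index rule).  A time-based fallback for locally blocked vertices
exists but is opt-in: it requires a settle margin exceeding the slowest
pacing propagation delay, otherwise slow conduction through dense
fibrosis is misread as reentry.  Consecutive activations less than 50 ms
apart merge into one (strict inequality; applied pairwise after each
merge), absorbing the isolated re-activation artifact of cleft meshes.

Initiation tracing discretises each vertex's first reentrant activation
into 10 ms bins (the voltage-recording resolution) and finds connected
sets of vertices none of whose neighbours activated in an earlier bin;
such components necessarily share one bin, the step at which the cluster
appears, and the cluster center (arithmetic mean of vertex coordinates)
is the initiation site.  Severed faces are excluded from the adjacency.
The within-step comparison (with earlier-step exclusion) is validated
against an exhaustive per-step oracle on meshes up to 30x30.  The
published minimum cluster size (1,000 vertices) presumes ~10-million
element meshes; the default rescales it as `max(20, 1e-4 * n_vertices)`.

Reentry morphology is a *feature heuristic*, not visual classification:
sites whose mean LGE within 5 mm (Euclidean ball) is below 10 % are
labelled Type 2 (functional rotors at healthy–fibrotic interfaces,
reported mean local LGE ~1.5 %), others Type 1 (meandering reentry
through dense fibrosis, ~36 %).  The 10 % cutoff sits above the reported
Type-2 range (0–9.2 %); every label carries a `heuristic` provenance
flag.

## Statistics

Segment tables count initiation sites per segment alongside LGE volume,
mean/max intensity and core volume.  The association test is a
negative-binomial (NB2) count regression with log link
(`statsmodels.NegativeBinomial`, dispersion estimated by ML), covariate
of interest plus LGE-volume adjustment, with geometry and fibrotic level
as categorical fixed adjusters — a deliberate approximation of a
random-effects NB model, which is fragile at desk-scale sample sizes;
single-level grouping variables are dropped with a warning.  Continuous
covariates are standardised internally and estimates mapped back.  On
synthetic tables from a known gamma–Poisson model the 95 % CI covers the
true slope at nominal rate and the null covariate keeps its type-I error
near 0.05 (checked over 200 replicates).

## Desk-scale test conditions

Simulation-based checks run on fixed, seeded configurations: 50x50 sheets
(2.65 cm) with a 12 mm patch for the cleft-density findings, 40x40 sheets
with a 9 mm patch for the core-size findings, shortened drive trains and
observation windows as stated above.  At this scale a single extra beat
(an interface echo) already satisfies the activation-index definition of
reentry, so inducibility is summarised by a staged score — earlier-stage
induction (fewer extrastimuli before reentry) scores higher, no reentry
scores zero — mirroring the reported finding that denser fibrosis needs
fewer extrastimuli.  Under these conditions the cleft substrate at
maximum density induces reentry after a single extrastimulus while the
cleft-free substrate induces none, and the large-core non-cleft substrate
induces reentry where the small-core one does not.

## Known limitations

* 2D/thin-3D lattices cannot host the full 3D scroll-wave repertoire;
  morphology labels are heuristic proxies.
* Off-diagonal anisotropy terms are dropped by the lattice stencil.
* Binary remodeling (not intensity-graded) follows the modeled study
  design and likely sharpens healthy–fibrotic interface phenomena.
* Desk-scale reentry statistics are demonstrations of mechanism and
  machinery, not reproductions of patient-level counts.
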