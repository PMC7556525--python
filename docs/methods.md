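# Methods

## Model overview

The package simulates the workflow by which a force-controlled natural-knee
simulator is given specimen-specific soft-tissue constraints.  Three model
layers are involved:

1. **Gait inputs.** One 1 Hz walking cycle on a uniform half-open grid
   [0, 1) s, 128 points by default, with four channels: flexion/extension
   (FE) angle, axial compressive force, anterior-posterior (AP) shear force
   and tibial-rotation (TR) torque.  Shapes follow the ISO 14243-1
   force-control convention, except that the axial force carries two stance
   peaks (instrumented-implant studies report two, not the standard's three).
   The exact numeric tables of the standard are licensed, so the packaged
   waveforms are a documented piecewise-linear approximation, stated by knot
   tables and fully overridable; every downstream algorithm is
   waveform-agnostic.  Signs: anterior, internal and flexion positive.

2. **Surrogate knee.** Each donor is a lumped quasi-static model: one
   load-displacement restraint curve per axis and polarity (anterior,
   posterior, internal, external), each with a low-stiffness *toe region* of
   length `toe_length` and stiffness `toe_stiffness` followed by a stiff
   linear region (`linear_stiffness`), continuous at the knee point.  An
   intact knee carries these curves plus a flexion-to-TR coupling; a resected
   knee (soft tissue removed, menisci and cartilage retained) keeps only a
   small residual linear stiffness per axis, with no toe region and no
   coupling.  There is no joint geometry, no medial/lateral compartment
   resolution and no abduction/adduction axis: the tuning procedure consumes
   only AP and TR traces, so nothing more is modelled.

3. **Trial engine.** Force control is realised as a memoryless balance: at
   each time point the applied load is equated to the sum of restraint and
   virtual-spring loads, and the displacement is found by bisection on the
   dislocation-bounded interval (default limits 25 mm / 30°, tolerance
   1e-4).  No inertia or viscoelastic history is modelled — at 1 Hz gait the
   elastic restraint dominates, and the tuning logic depends only on trace
   shapes.  A point with no balance inside the limit marks the cycle
   unstable (dislocation); unstable cycles are flagged and excluded from
   averaging rather than aborting the trial.  Measurement-like Gaussian
   noise (default SD 0.05 mm / 0.05° per sample) is added to the outputs of
   each cycle, so the standard ten-cycle average reduces noise by √10.

## Virtual springs and candidate grids

A spring condition per axis holds two independent halves, each a dead-zone
linear law: zero load within the free gap, `rate × (|d| − gap)` beyond it,
always opposing motion and continuous at the gap boundary.  The symmetric
ISO-style spring (e.g. 9.3 N/mm with a ±2.5 mm gap) is the special case of
equal halves.  Candidate grids default to AP rates 20–70 N/mm in steps of
5 N/mm with free lengths 0–3 mm, and TR rates 0.1–1.2 Nm/° in steps of
0.1 Nm/° with free angles 0–3°; grid spacing is a configuration choice
matched to the granularity at which such conditions are reported in
practice.  Free gaps of 4 mm / 4° or more are excluded (strict inequality):
beyond that free motion the force tuning of a physical rig becomes
unreliable and the joint risks dislocation.

## Staged tuning and the deviation metric

The three stages (AP under AP-force-only drive with TR-1 imposed; TR under
both-driven with the stage-1 AP spring; AP refinement under both-driven with
the selected TR spring) are exhaustive searches over the stability-filtered
grid — the grids are small, so no heuristic search is warranted, and the
two-step decomposition avoids the instability a simultaneous two-axis search
risks.

The match criterion is windowed-peak based.  Analysis windows are the time
ranges in which the kinematic extremes occur: 0.06, 0.13 and 0.67 ± 0.05 s
for AP, 0.10 and 0.50 ± 0.05 s for TR, wrapping periodically.  In each
window the polarity is resolved from the *reference* trace (the direction of
its larger-magnitude extremum) and the signed extremum of that polarity is
compared between reference and candidate.  The scalar deviation is the
maximum absolute peak difference across windows (an RMS alternative is
configurable); all windows contribute, and the window containing each axis's
global extremum — which is specimen-specific — is recorded with the result.
Ties are broken by smaller all-window deviation sum, then stiffer total
rate, then smaller total gap (stability-favouring), then grid order.

In AP-force-only mode a trial with no TR series leaves the TR axis free
(zero applied torque): that is how the intact TR-1 reference is recorded,
since no displacement profile exists before the intact study.

## Flexion-TR coupling

Intact knees commonly show an extra TR excursion near peak stance flexion,
when the TR torque changes polarity (around 0.16–0.3 s).  The surrogate
reproduces it with the simplest mechanism consistent with the observation:
an additive internal-rotation offset `c · clip(FE − 14°, 0, 4°)` applied to
the intact TR output.  The threshold restricts the coupling to flexion
beyond mid-stance levels and the saturation bounds the swing-phase offset so
it cannot displace the global internal peak; with the packaged FE waveform
the offset is zero inside both TR analysis windows, peaking between them.
Resected knees have no coupling, which is why the stage-2 spring match is
evaluated on the windowed peaks rather than the whole trace: like its
physical counterpart, a dead-zone spring cannot reproduce every intact
feature, only the peak behaviour the selection criterion targets.

## Synthetic donor population and calibration

Donor restraint stiffnesses are not observable in a cadaveric study; peak
kinematics are.  The generator therefore samples *target peak
displacements/rotations* uniformly inside calibration ranges chosen just
inside the inter-donor ranges observed for intact human knees (anterior
2.2–10.3 mm, posterior 4.1–6.7 mm, external 1.0–7.0°, internal 4.1–11.4°),
plus toe-region shape fractions, coupling coefficient (0.35–0.6 °/°),
and residual stiffnesses (1.0–1.8 N/mm AP, 0.02–0.038 Nm/° TR).  Because
the engine is quasi-static and each restraint monotone, calibration is a
closed-form inversion: with toe length `L` and toe stiffness a fraction `f`
of the linear stiffness `k`, the peak input load `F` of the sampled profile
satisfies `F = f·k·L + k·(d* − L)`, so `k = F / (d* − L(1−f))` places the
simulated intact peak exactly on the target `d*`.  The resulting stiffnesses
are a package construction, not measured donor properties.  Sampling is
uniform with a fixed seed protocol (the observed ranges come from n = 4
specimens; no distributional information exists to justify anything richer).

The packaged four-donor fixture set uses fixed targets spanning those ranges
(including the anterior, external and internal endpoints); donor 4 has zero
coupling, mirroring the roughly one-in-four incidence of knees without the
stance TR excursion.  The TR residual stiffness default (0.035 Nm/°) is
kept below the smallest toe stiffness the population can produce, so
resection never stiffens any axis.

What the generator does *not* emulate: joint geometry and its load-dependent
kinematics, active muscle forces, compartment-resolved contact (the medial
axial-load offset of the physical protocol is metadata only), viscoelastic
or history-dependent tissue behaviour, and rig transients (the surrogate has
no start-up, so no warm-up cycles are modelled).  Passing tests therefore
demonstrate that the *procedure* — reference recording, windowed-peak
matching, staged selection, stability filtering — behaves correctly and
recovers known constraints, not that any particular human knee would yield
these spring values.

## Numerical choices

- Bisection with tolerance 1e-4 mm/° on the dislocation-bounded bracket;
  the scalar solver scans outward from neutral first, so a non-monotone
  total restraint yields the root closest to neutral (with a warning).
- Windows are index sets on the circular grid with a 1e-9 time tolerance at
  the edges; a half-width of 0.5 s covers the whole cycle exactly once.
- Per-candidate trial seeds derive deterministically from the tuning seed,
  stage index and candidate index; identical seeds give bit-identical
  traces.
- Statistics across donors use two-sided Student-t confidence limits on the
  donor dimension (half-width `t(1−α/2, n−1)·SD/√n`), the standard small-n
  construction for a four-specimen study; whether a normal approximation was
  intended instead is undocumented, so the t form is an explicit assumption.
- The stance-TR-excursion detector requires a local maximum of ≥0.1°
  prominence inside 0.16–0.3 s, comfortably above the ~0.016° noise floor
  of a ten-cycle average and below the ≥0.3° bumps the coupling produces.

## Problem sizes

Default runs use the 128-point grid, ten cycles per trial, 1936 AP and 2304
TR candidates per stage; a full three-stage tuning of one donor evaluates
about six thousand trials in ~5 s, and the four-donor acceptance run
completes in about a minute on one CPU.  Property suites use reduced grids
and single-cycle noise-free trials where the property does not depend on
grid size or noise.

## Known limitations

- The waveform knot tables are shape-faithful approximations, not the
  standard's numeric tables; absolute kinematic values therefore have no
  claim to match any specific experimental series.
- AP and TR axes are mechanically uncoupled in the surrogate (only FE→TR
  coupling exists), so stage 3 changes the AP selection only through noise;
  in a physical knee cross-axis geometry can make refinement substantive.
- The deviation metric inspects windowed peaks only; matching the full
  trace shape (e.g. the second anterior swing peak some knees show) is
  explicitly out of the selection criterion, as in the physical protocol.
- Uniform sampling within observed ranges overstates tail donors relative
  to any realistic population distribution; the ranges bound, not model,
  inter-donor variability.
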