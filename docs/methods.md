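# Methods

This note documents the models behind `mrdose`, the choices made where
the design was genuinely open, and what the synthetic experiments do and
do not demonstrate.

## Stream and segment model

Linac state messages carry `(t, gantry, jaws, MLC, cumulative MU,
beam_on)` and are interpreted as control points.  A beam segment is
created for every consecutive message pair whose *start* message has the
beam on and whose MU increment is positive; the segment holds the start
control point's aperture and gantry angle (step-and-shoot assumption —
plans whose jaws/MLC/gantry change *within* a segment, e.g. VMAT, are
out of scope).  The beam-state of an interval follows the start
message's flag: the simplest causal rule, declared rather than inferred,
since message edge semantics are vendor-specific.

Motion synchronization assigns each message the motion sample nearest in
time; equidistant ties resolve to the earlier sample (causally
available) and a motion stream that ends early holds its last sample.

The stream generator integrates cumulative MU at the dose rate
(default and maximum 420 MU/min, 5 Hz messages) and clamps it exactly at
each plan-segment boundary, holding the beam for one message plus a
configurable dead time (default 0.4 s) while the leaves travel.  This
mirrors step-and-shoot delivery and makes the stream segments an exact
partition of the plan's MU, so delivered-equals-planned identities hold
to accumulation round-off (< 1e-9 Gy) in the static scenario.

## Dose engine

The clinical workflow uses a Monte Carlo engine; its role here is played
by an analytic primary-beam model chosen so that every behaviour the
*workflow* depends on (linearity in MU, depth attenuation, field shape,
statistical noise) is present and exactly testable:

D(v) = ΔMU · O · F(u, v) · (SAD / r)² · exp(−μ · d_rad(v))

- `O` (Gy/MU at SAD, zero depth, unit fluence) is calibrated per plan so
  the mean planned CTV dose equals the prescription (7.5 Gy/fraction).
- `F` is the aperture fluence: the jaw∩MLC opening is a union of
  disjoint per-leaf-pair rectangles, so its convolution with the
  Gaussian penumbra (σ = 4 mm at isocenter) is an exact separable sum of
  `erf` terms, evaluated analytically at each voxel's divergent
  projection onto the isocenter plane.  A straight field edge reads
  exactly 0.5.
- `d_rad` is water-equivalent radiological depth.  Per-ray queries use
  an exact Siddon-style voxel traversal (`radiological_depth`), which
  also serves as the oracle.  The volumetric calculation resamples the
  density into a beam-aligned frame (gantry rotation about the CC axis;
  gantry 0 needs no resampling), takes a midpoint cumulative sum along
  the beam axis, computes the dose there, and rotates it back.  This
  parallel-ray depth is exact on the central axis — the closed-form
  depth-dose check holds to 1e-6 — and accurate to interpolation error
  off axis at the ~20 cm scales of these phantoms.
- MC-like noise multiplies each voxel by `1 + ε`, ε ~ N(0, 0.05)
  i.i.d. per voxel per calculation (the live engine's quoted 5%
  statistical uncertainty, referenced at voxels above 50% of the
  segment maximum — the reference region is our declared convention, as
  the quoted figure does not define one).  Accumulating n equal noisy
  segments shrinks the relative sd as 1/√n, so three 1.4 MU live
  segments beat a 3% plan calculation: 5%/√3 = 2.89% < 3%.  No scatter
  kernel, electron-return effect, or heterogeneity correction beyond
  radiological depth is modelled; the engine sits behind one function
  (`compute_segment_dose`) so a better model can be swapped in.

Default grid: 3 mm isotropic, 64³; dose and density share the grid.
SAD = 1435 mm, μ = 0.06 cm⁻¹ (nominal MV-beam effective attenuation).

## Registration and DVF conventions

A DVF `u` is a per-voxel mm displacement used for pull-back warping,
`warp(vol, u)(x) = vol(x + u(x))`.  The field that builds the current
anatomy from the reference (`current = warp(reference, u)`) has as its
inverse the material motion; segment dose computed on the current
anatomy returns to the reference frame by warping with that inverse
(`invert_dvf`, fixed-point iteration, residual < 0.1 voxel on all
generator-produced fields).  One convention had to be declared — the
source workflow does not state the mapping direction — and every use in
the package goes through it; a round-trip test against a closed-form
field pins it down.

The registrar is a deliberately simple stand-in for the clinical
multi-modal DIR: mono-modal, multi-resolution (3 levels), demons-style
intensity forces with Gaussian field smoothing (σ = 6 mm), and a
step-halving acceptance rule that makes the per-level intensity MSE
non-increasing and the whole procedure deterministic.  It recovers a
4 mm rigid shift of a textured volume to < 0.5 voxel and the 8 mm roll
deformation to < 1 voxel endpoint error at the film interface.  External
DVFs are accepted anywhere a registrar output is, so a faithful DIR can
be plugged in.

## Accumulation and forecasting

Three distributions live on the reference frame: the running delivered
dose (with a per-segment MU ledger that must sum exactly to the
delivered MU), the planned dose to the same MU (full segments plus a
linear fraction of the straddled segment — linear because the aperture
is held within a segment), and the forecast (delivered plus the plan
remainder computed on the anatomy frozen at the latest state).  Planned
and remainder doses are computed noise-free: the plan-vs-live
uncertainty discussion is carried by the analytic combination rule
rather than by emulating two different MC noise levels, which would add
nothing testable.

Coverage (V95% against the prescription, the common clinical convention,
rather than against the maximum dose) is always evaluated with the
planning CTV: since all dose is mapped back to the reference/material
frame, the planning structures are the consistent ones in both rigid and
deformable modes.  Forecast cadence defaults to every 10 segments
(rigid) or one 10 s imaging window (deformable).

## Virtual phantoms and ground truth

- **Diode cylinder**: water cylinder (r = 85 mm) with 5 mm diode
  lattices on two orthogonal interior planes (338 diodes) and a 15 mm
  spherical CTV at isocenter; diode readouts at 40 Hz.
- **Water-bag/film phantom**: water (ρ = 1.0) over a water-equivalent
  slab (ρ = 1.02) with a 5 × 10 cm film plane at the interface, two
  bright fiducial markers at the film ends, and an MR-like image channel
  (tissue contrast plus a gentle smooth intensity modulation standing in
  for coil/signal inhomogeneity, which gives the registrar gradients
  away from material edges).  Densities are nominal and configurable;
  air is 0.0012.
- **Plan generator**: evenly spaced gantry angles, conformal-ish MLC
  openings around the spherical target with a 14 mm margin and seeded
  per-leaf jitter emulating IMRT modulation; a single-segment plan is
  the open 10 × 10 cm deformable-test beam.  The 14 mm margin keeps the
  planned V95 near 100% for the 4 mm penumbra while leaving a 10 mm
  drift clearly visible in coverage — margins much below ~3 penumbra
  sigmas put the CTV edge into the penumbra even without motion.
- **Motion traces**: static; linear 0→10 mm cranial-caudal drift; and a
  piecewise-linear patient-like trace (rise to an 8 mm apex at 45% of
  the fraction, partial return to 2 mm) — the source trace is not
  tabulated, only its rise-then-recover shape is reproduced.
- **Roll deformation**: a smooth ridge `A·exp(−d²/w²)` (amplitude 8 mm,
  width 22 mm, zero within a 12 mm boundary margin), applied at two
  pause points at different CC positions.  The width parameter is the
  1/e half-width, which puts the field below 1% of its amplitude beyond
  three widths.

Ground truth is the same engine run noise-free on the true anatomy —
diodes sampled on the reference frame under the true rigid motion, the
film accumulated at its *moving* material points per epoch.  This makes
the measurement an honest oracle, independent of the reconstruction
under test (which consumes only the stream, the synced motion and the
registered images): in the static scenario, measurement equals plan to
machine precision, so any σ_P in a motion scenario is attributable to
motion, not to the instrument model.  What passing these tests does
*not* show: behaviour under real multi-modal image contrast, MR
geometric distortion, detector calibration drift, breathing-rate motion
(the 10 s imaging window is too slow for it, a stated limitation of the
workflow) or MC transport physics.

## Timing model

Wall-clock performance is hardware-bound in the real system, so the
package simulates it with a per-stage cost model: 82 ms per segment
dose, 3 s per DIR, an engine-reset constant, and a forecast cost
proportional to the number of remaining plan segments (hence forecast
intervals shrink as the fraction progresses).  The sustainable duty
cycle is the largest beam-on fraction d with
`d · window · msg_rate · t_segment + t_DIR + t_reset ≤ window`.  The
reset duration is not reported by the source workflow; it is derived
from the reported 92% limit, 3 s DIR, 82 ms segment cost and 10 s
window as `t_reset = 10 − 3 − 0.92·50·0.082 ≈ 3.23 s`, so the default
cost model reproduces the 92% budget by construction — the arithmetic,
not the hardware, is the reproducible object.  A discrete-event worker
simulation provides the MU-trailing backlog over a session and serves
as the oracle for the closed-form budget.

## Problem sizes and numerical choices

Default experiment sizes (64³ grid at 3 mm, 12-segment 144 MU rigid
fraction ≈ 108 stream segments, 150 MU deformable fraction, 1000
repeats for the noise-recovery check) were chosen so the complete suite
and the acceptance script each run in a few minutes on one CPU while
keeping ≥ 100 segments per fraction and ≥ 300 diodes.  Gamma analysis
searches a lattice of dta/10 steps within 3·dta (exhaustive with
distance-sorted pruning; a brute-force per-point search is kept in the
test suite as the oracle).  σ uses the sample (n−1) standard deviation;
the 60–85% diode band bounds are inclusive, with the maximum taken over
the full-fraction planned diode doses.  Deviation statistics are
cumulative up to the MU they are indexed by.  Degenerate inputs
(empty streams, beam-off fractions, all-sub-threshold gamma inputs,
single-diode selections) raise informative errors rather than returning
NaNs.
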