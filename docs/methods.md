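# Methods

## The stepping model

One plus-end-directed kinesin and one minus-end-directed DDB
(dynein–dynactin–BicD2) complex walk on a one-dimensional microtubule
lattice, each connected by its own linear spring (stiffness κ, default
0.2 pN/nm from a 6 pN force stretching the motor–DNA assembly to 30 nm) to a
zero-mass, zero-volume cargo. Because the cargo is massless it equilibrates
instantly: with both motors attached it sits at the stiffness-weighted mean
of their positions, with one attached it coincides with that motor. While
both motors are attached the spring forces on them are therefore equal in
magnitude and opposite in lab-frame sign at all times.

All positions and forces live in a single lab frame, plus-end positive.
Each motor carries a direction sign (+1 kinesin, −1 DDB); the per-motor
assisting/hindering load used in the rate laws is the lab-frame spring force
times that sign. This keeps the state unambiguous and confines convention
changes to one line.

### Rate laws

Four reactions per motor: forward step, backstep, detach, reattach. Steps
move the motor 8 nm along (forward) or against (back) its own direction.

- **Forward stepping.** Unloaded rate k_forward⁰ = V₀/L + k_back (the
  unloaded velocity reflects the net of forward and backward steps). Under
  hindering load of magnitude m the rate falls linearly, reaching k_back at
  the stall force — net velocity exactly zero at stall — and continuing
  along the same line under super-stall loads, floored at zero. A
  super-stalled motor therefore slips backward at up to k_back·L per second
  rather than anchoring in place. This is the literal continuation of the
  linear force–velocity law; the alternative (clamping the forward rate at
  k_back beyond stall, so a super-stalled motor holds its ground
  indefinitely) is available as `superstall_anchor=True`. The slip reading
  matters: with an anchoring DDB the pair deadlocks at the kinesin's stall
  tension, kinesin detachment cycles dominate, and every simulated velocity
  distribution shifts tens of nm/s toward the minus end. Assisting loads
  leave the forward rate unchanged; backstepping is load-independent.
- **Detachment.** Bell model k_detach(F) = k_detach⁰·e^{|F|/F_detach},
  using the magnitude of linkage tension for hindering and assisting load
  alike (no separate assisting-load law is established; the symmetric slip
  bond is the minimal choice). F_detach = k_BT/δ with k_BT = 4.1 pN·nm. DDB
  is modeled as an ideal bond (F_detach infinite): its off-rate never
  changes with load.
- **Attachment bookkeeping.** When a motor detaches, the cargo snaps to the
  remaining attached motor. A detached motor reattaches at the current
  cargo position, at its constant first-order k_reattach. A run ends at the
  recording horizon or when both motors are detached.

The bundled parameter table covers kinesin-1/2/3 and DDB. Two deliberate
internal inconsistencies of the stated values are kept (stated values win
over derivations, since they may encode measurements the closed forms
cannot): DDB's k_forward⁰ of 60 s⁻¹ exceeds V₀/L + k_back = 50 s⁻¹, and is
flagged by `validate_consistency` as a warning rather than an error.

### Simulation algorithm

Exact Gillespie SSA: between events the state, hence every propensity, is
constant, so waiting times are exponential in the total rate and events are
chosen proportionally to their rates. No tau-leaping — total rates are at
most ~10³ s⁻¹, so exact simulation is cheap at study scale (a 1000-run × 50 s
ensemble takes seconds on one core). Both motors start attached at position
0 with zero tension; the long-run behavior at 50 s is insensitive to this
choice. Ensembles draw per-run generators from
`numpy.random.SeedSequence(master_seed).spawn`, making them bitwise
reproducible and order-independent. The inner loop is hand-inlined for
speed but calls the same rate-law functions as the public per-event API; a
test replays logged events through `apply_event` and asserts identical
states.

## Trace analysis

Simulated cargo paths are averaged into camera frames (time-weighted mean
over each 286 ms interval, matching camera integration at 3.5 frames/s)
before any analysis, so simulated and experimental-style traces share one
representation.

- **Instantaneous velocity**: endpoint displacement over non-overlapping
  windows of round(window/frame_dt) frame intervals — 3 intervals (0.858 s)
  for the 1 s default — normalized by the actual span to avoid quantization
  bias. A least-squares-slope variant is available.
- **Trace velocity**: net displacement over total duration; a trace is
  "fast" when this strictly exceeds the condition's threshold (250 nm/s for
  DDB–Kin1/3, 125 nm/s for DDB–Kin2), interpreted as kinesin-only motility
  with DDB in a weakly bound state.
- **Distribution center**: mode of a Gaussian KDE. The bandwidth defaults
  to Scott's rule; a fixed narrow bandwidth makes the mode of broad, flat
  distributions unstable between near-equal local maxima, while the
  sample-size-adaptive rule is the standard compromise.

### Segmentation

Traces are decomposed into constant-velocity segments by exact penalized
least-squares change-point detection: dynamic programming over partitions
of the frames into disjoint consecutive blocks (each ≥ 3 frames = 858 ms),
minimizing per-block linear-fit SSE plus a per-block penalty. Design
choices that proved load-bearing:

- **Disjoint blocks, not shared endpoints.** The latent path is continuous
  and its kinks fall between frames; with shared-endpoint segments the
  boundary frame can lie on neither fitted line, and the optimizer inserts
  3-frame artifact segments around every strong kink even without noise.
  With disjoint blocks every noiseless frame lies exactly on its own line,
  so noiseless piecewise-linear fixtures are recovered exactly for any
  positive penalty.
- **Segment velocity = OLS slope** of the block (displacement =
  slope × duration). The raw endpoint difference is fragile under the
  one-pixel pause rule: a single boundary frame quantized into the wrong
  block shifts an endpoint by a full frame's travel, while it perturbs the
  slope only by its leverage share.
- **Penalty** = 4σ²·ln(n), with σ the localization noise estimated robustly
  from the median absolute second difference (second differences cancel
  linear trends; for i.i.d. noise their s.d. is σ√6). The factor is
  calibrated on synthetic fixtures: small enough to resolve 3–5-frame
  pauses, large enough not to split constant-velocity traces at σ ≤ 30 nm.
  An explicit `penalty` argument overrides the default.
- **Merging.** Adjacent blocks merge (closest pair first, refitting after
  each merge) when their velocities differ by less than 10 nm/s — the
  minimum detectable velocity change — *and* their fitted lines agree at
  the shared boundary within one camera pixel. The second condition is
  essential: the two-state motility of DDB produces sub-3-frame processive
  bursts between pauses, and without it the two flanking pauses (both
  near-zero velocity) merge across the super-pixel position step into one
  slowly drifting "moving" segment, systematically deflating the measured
  pause-time fraction. A sub-pixel step is below the resolution the pause
  rule itself assumes, so merging across it is consistent.

Pauses are segments whose |displacement| is strictly less than one 73 nm
pixel; otherwise the displacement sign labels the segment plus or minus.
Directional switches count immediately adjacent moving segments of opposite
sign (a pause breaks the sequence; a variant that looks through pauses is a
flag). Duration-weighted velocity distributions give each segment
round(duration) one-second samples, excluding pauses by default.
Dwell-duration samples are fit by the exponential MLE (the sample mean;
censoring not modeled) with a seeded nonparametric bootstrap
(resample-with-replacement means, 2.5/97.5 percentiles, 1000 resamples by
default). Degenerate cases error early: traces shorter than two frames,
empty velocity samples, fewer than two durations.

## Synthetic data

The generator emulates the statistical structure of single-particle TIRF
tracking so the pipeline can be validated against known truth:

- sampling at 3.5 frames/s for at most 100 s; i.i.d. Gaussian localization
  noise per frame, default σ = 20 nm (a conservative single-fluorophore
  figure; configurable);
- piecewise-constant-velocity plans with exact truth segments (breakpoints
  quantized to the frame grid);
- a two-state DDB motility model — processive sojourns with per-sojourn
  velocity drawn around the unloaded DDB speed (−360 nm/s, s.d. 100), and
  zero-velocity "stuck" sojourns — with exponential dwells. Stuck dwell
  defaults to 2.8 s; `from_stuck_fraction` sets the processive dwell so the
  alternating-renewal stuck-time fraction hits a target (e.g. 0.26). An
  optional zero-drift diffusive state exists but is off by default, since
  the pipeline does not classify diffusion;
- a fast/slow population mixture: "fast" traces at unloaded-kinesin-like
  constant velocity (586 ± 80 nm/s) with short exponential durations
  (mean 5 s), "slow" traces from the state model with near-zero drift and
  long durations (mean 22.2 s), truncated at the 100 s imaging window with
  a censoring flag in the truth table.

Not emulated: photophysics (blinking, bleaching), two-channel registration
error, tracking outliers, microtubule geometry. Passing recovery tests
therefore demonstrates correctness of the analysis under idealized
noise, not robustness to every artifact of real microscopy data.

## Problem sizes and tolerances

The simulation checks use the full reference protocol (1000 runs × 50 s per
condition); the statistical recovery suites use 100–1000 synthetic
repetitions, sized so each suite completes in well under five minutes on
one core. Closed-form recovery tests assert 2% (velocity) and 5% (run
length) at n = 1000, where Monte-Carlo standard errors are several-fold
smaller. Exponential-fit coverage is checked against a ≥ 93% criterion at
nominal 95%, leaving room for the small-sample optimism of percentile
bootstrap bands.

## Known limitations

- The tug-of-war model has no sub-step mechanochemistry (ATP states,
  gating), no vertical-force geometry, no lattice-site exclusion (motors
  may pass each other; springs may compress), and exactly one motor per
  team.
- Super-stall behavior beyond the linear-slip reading is unconstrained by
  the underlying measurements; the `superstall_anchor` variant exists for
  sensitivity analysis.
- The DDB stuck state is a property of the synthetic generator, not of the
  stepping simulation: simulated pairs pause by force balance, synthetic
  DDB traces pause by state switching.
- Segmentation resolution is bounded by the 3-frame minimum: motility
  structure shorter than 858 ms cannot be represented as its own segment,
  so pause-time fractions recovered through the full pipeline carry a
  small, duration-structure-dependent downward bias relative to generator
  truth.
- Bootstrap CIs ignore censoring at the imaging window; for dwell means
  much shorter than 100 s the bias is negligible.
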