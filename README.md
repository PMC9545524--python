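# motorpair

Stochastic stepping simulation and single-molecule trace analysis for
bidirectional cargo transport by a kinesin–dynein motor pair.

## The problem

In neurons, cargoes carry both plus-end-directed kinesins (families 1, 2 and
3) and the minus-end-directed dynein–dynactin–BicD2 complex (DDB), and their
mechanical competition — a molecular tug-of-war through an elastic linkage —
helps set transport speed and direction. In vitro, one kinesin and one DDB
can be joined through a DNA scaffold and tracked by two-channel TIRF
microscopy; the resulting kymograph traces show slow, heterogeneous motion
with pauses and rare directional switches. This package provides, for that
experimental system:

- **a stochastic stepping model** of the coupled pair (`motorpair.gillespie`),
- **the trace-analysis pipeline** used on such kymograph data
  (`motorpair.trace_analysis`),
- **a synthetic-trace generator** with full ground truth, so the pipeline is
  testable without microscopy data (`motorpair.synthetic`),
- a thin CLI tying them together (`motorpair.cli`).

## The model

Each motor is described by its unloaded velocity *V₀*, step size *L* = 8 nm,
backstepping rate *k_back*, stall force *F_s*, unloaded detachment rate
*k_detach⁰*, detachment force parameter *F_detach* = *k_BT*/δ, reattachment
rate *k_reattach*, and linkage stiffness κ = 0.2 pN/nm. The two motors are
coupled through linear springs to a massless cargo, which therefore sits at
the force-balance point of the attached motors. A Gillespie SSA draws, at
every event, one of eight reactions (forward step, backstep, detachment,
reattachment, per motor) with propensities evaluated at the instantaneous
linkage tension *F* = κ·Δℓ:

- **force–velocity**: *k_forward(F)* falls linearly from *k_forward⁰* =
  *V₀/L* + *k_back* at zero load through *k_back* at stall (net velocity
  zero), continuing to zero under super-stall loads (backward slip at up to
  *k_back·L*);
- **Bell detachment**: *k_detach(F)* = *k_detach⁰*·e^{|F|/F_detach}; DDB is
  an ideal bond (load-independent off-rate);
- detaching snaps the cargo to the remaining motor; a detached motor
  reattaches at the cargo, at rate *k_reattach*.

The bundled parameter table (`motorpair.reference_params()`) covers kinesin-1,
-2, -3 and DDB. For analysis, the cargo path is averaged into 286 ms camera
frames and velocities are computed over ~1 s windows, exactly as for
experimental traces.

The analysis pipeline segments each trace into constant-velocity pieces
(exact penalized change-point detection; every segment ≥ 3 frames, adjacent
segments ≥ 10 nm/s apart), calls pauses (segments moving less than one 73 nm
pixel), counts directional switches, computes duration-weighted velocity
distributions, and fits dwell-time distributions with a single exponential
plus a nonparametric bootstrap 95% CI.

## Worked example

```python
import numpy as np
from motorpair import reference_params, pair_velocity_pool, distribution_peak

params = reference_params()
v = pair_velocity_pool(params["Kin1"], params["DDB"], seed=7, n_runs=200)
print(f"windows: {v.size}")
print(f"KDE peak: {distribution_peak(v):.1f} nm/s")
print(f"median:   {np.median(v):.1f} nm/s")

kin_slow = params["Kin1"].with_overrides(k_reattach=5.0)
v5 = pair_velocity_pool(kin_slow, params["DDB"], seed=7, n_runs=200)
print(f"slow-reattach peak: {distribution_peak(v5):.1f} nm/s")
```

prints

```
windows: 6822
KDE peak: 4.3 nm/s
median:   4.0 nm/s
slow-reattach peak: -40.1 nm/s
```

With the reference parameters the DDB–kinesin-1 pair's instantaneous
velocity distribution peaks a few nm/s to the plus side of zero: the two
motors mostly hold each other near stall, and the kinesin's fast (100 s⁻¹)
reattachment keeps DDB excursions short. Dropping the reattachment rate to
the classical 5 s⁻¹ figure lets DDB run free for ~0.2 s after every kinesin
detachment, broadening the distribution and shifting its center tens of
nm/s toward the minus end — the signature that fast rebinding is what lets
load-sensitive kinesins compete with dynein.

The same workflows are available from the shell:

```bash
motorpair simulate --kinesin Kin1 --n-runs 100 --t-max 50 --seed 1 --out sim/
motorpair synth --n-traces 50 --seed 1 --out-dir data/
motorpair analyze --manifest data/manifest.csv --seed 1 --out results/
motorpair reproduce-distributions --seed 1 --out dist/
```

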