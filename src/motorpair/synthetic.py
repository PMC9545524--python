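"""Synthetic position-time traces with TIRF-tracking statistics and ground truth.

Emulates the features of single-particle kymograph data that the analysis
pipeline must handle -- 3.5 frames/s sampling over at most 100 s, 73 nm
pixels, Gaussian localization noise, piecewise-constant velocity segments
including pauses with exponential dwells, a DDB processive/stuck state
structure spending roughly a quarter of the time stuck, and a fast/slow
two-population mixture of trace velocities -- while recording the full
generating truth so recovery can be scored exactly.

What it does NOT emulate: photophysics (blinking, bleaching), two-channel
registration error, microtubule geometry, or tracking outliers; noise is
i.i.d. Gaussian per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from motorpair.trace_analysis import (
    FRAME_DT,
    PIXEL_NM,
    SampledTrace,
    SegmentSet,
    _build_segment_set,
)

__all__ = [
    "TraceSpec",
    "DDBStateModel",
    "PopulationConfig",
    "StateTruth",
    "gen_segmented_trace",
    "gen_ddb_state_trace",
    "gen_population",
]

#: default localization noise s.d. (nm); a conservative figure for
#: single-fluorophore TIRF tracking at video rate
DEFAULT_NOISE_NM = 20.0
#: imaging window (s): 3.5 fps for 100 s
MAX_IMAGING_S = 100.0


@dataclass
class TraceSpec:
    """Plan for one synthetic trace: velocity segments plus sampling/noise."""

    plan: list[tuple[float, float]]  # (velocity nm/s, duration s)
    frame_dt: float = FRAME_DT
    pixel: float = PIXEL_NM
    noise_sigma: float = DEFAULT_NOISE_NM
    max_duration: float = MAX_IMAGING_S

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.plan):
            raise ValueError("segment durations must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class DDBStateModel:
    """Two-state (processive/stuck) kinetic model of DDB motility.

    Sojourn durations are exponential with the given means; each processive
    sojourn draws its velocity from a normal distribution (nm/s, lab frame),
    stuck sojourns have zero velocity.  The long-run stuck-time fraction of
    the alternating renewal process is ``dwell_stuck / (dwell_processive +
    dwell_stuck)``.  An optional third, purely diffusive state (zero drift)
    is available but off by default.
    """

    dwell_processive: float = 7.969
    dwell_stuck: float = 2.8
    v_processive_mean: float = -360.0
    v_processive_sd: float = 100.0
    p_stuck: float = 1.0
    p_diffusive: float = 0.0
    dwell_diffusive: float = 1.0
    diffusion_coeff: float = 0.0  # nm^2/s, used only for the diffusive state

    def __post_init__(self) -> None:
        if not (self.dwell_processive > 0 and self.dwell_stuck > 0):
            raise ValueError("dwell means must be strictly positive")
        if not 0 <= self.p_stuck <= 1:
            raise ValueError("p_stuck must be in [0, 1]")
        if not 0 <= self.p_diffusive < 1:
            raise ValueError("p_diffusive must be in [0, 1)")

    @property
    def stuck_fraction(self) -> float:
        """Long-run fraction of time in the stuck state (diffusive state excluded).

        After each processive sojourn the motor enters the stuck state with
        probability ``p_stuck`` (otherwise it starts a fresh processive
        sojourn), giving an alternating renewal fraction
        ``p_stuck * dwell_stuck / (dwell_processive + p_stuck * dwell_stuck)``.
        """
        ps = self.p_stuck * self.dwell_stuck
        return ps / (self.dwell_processive + ps)

    @classmethod
    def from_stuck_fraction(
        cls, stuck_fraction: float, dwell_stuck: float = 2.8, **kwargs
    ) -> "DDBStateModel":
        """Build a model whose long-run stuck-time fraction equals the target."""
        if not 0 < stuck_fraction < 1:
            raise ValueError("stuck_fraction must be in (0, 1)")
        dwell_processive = dwell_stuck * (1 - stuck_fraction) / stuck_fraction
        return cls(dwell_processive=dwell_processive, dwell_stuck=dwell_stuck, **kwargs)


@dataclass
class StateTruth:
    """Generating truth for one state-model trace."""

    sojourns: list[tuple[str, float, float]]  # (state, duration s, velocity nm/s)
    stuck_time_fraction: float

    @property
    def pause_durations(self) -> np.ndarray:
        return np.asarray([d for s, d, _ in self.sojourns if s == "stuck"])


def _sample_plan(
    plan: Sequence[tuple[float, float]],
    frame_dt: float,
    noise_sigma: float,
    max_duration: float,
    rng: np.random.Generator,
) -> tuple[SampledTrace, list[int], np.ndarray]:
    """Sample a piecewise-linear latent path at frame times, with noise.

    Returns the noisy trace, the truth breakpoints quantized to frames, and
    the noiseless frame positions.
    """
    vels = np.asarray([v for v, _ in plan], dtype=float)
    durs = np.asarray([d for _, d in plan], dtype=float)
    edges = np.concatenate(([0.0], np.cumsum(durs)))
    total = min(edges[-1], max_duration)
    n_frames = int(np.floor(total / frame_dt + 1e-9)) + 1
    if n_frames < 2:
        raise ValueError("plan shorter than two frames at this frame_dt")
    t = np.arange(n_frames) * frame_dt
    # latent position: integral of the piecewise-constant velocity
    pos_at_edges = np.concatenate(([0.0], np.cumsum(vels * durs)))
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(vels) - 1)
    latent = pos_at_edges[idx] + vels[idx] * (t - edges[idx])
    noisy = latent + rng.normal(0.0, noise_sigma, size=n_frames)
    # truth block ends on the frame grid: the last frame sampled from each
    # plan segment (deduplicated; zero-frame segments are absorbed)
    ends: list[int] = []
    for edge in edges[1:]:
        e = min(int(np.floor(edge / frame_dt + 1e-9)), n_frames - 1)
        if e >= 0 and (not ends or e > ends[-1]):
            ends.append(e)
    if not ends or ends[-1] != n_frames - 1:
        ends.append(n_frames - 1)
    trace = SampledTrace(noisy, frame_dt=frame_dt, origin="synthetic")
    return trace, ends, latent


def gen_segmented_trace(
    spec: TraceSpec, rng: np.random.Generator
) -> tuple[SampledTrace, SegmentSet]:
    """Generate one trace from an explicit segment plan, with truth segments.

    The truth :class:`SegmentSet` is built on the noiseless latent path with
    breakpoints quantized to the frame grid, so its velocities equal the plan
    velocities up to frame quantization.
    """
    if not spec.plan:
        raise ValueError("empty segment plan")
    trace, ends, latent = _sample_plan(
        spec.plan, spec.frame_dt, spec.noise_sigma, spec.max_duration, rng
    )
    latent_trace = SampledTrace(latent, frame_dt=spec.frame_dt, origin="synthetic")
    truth = _build_segment_set(latent_trace, ends, spec.pixel)
    return trace, truth


def gen_ddb_state_trace(
    model: DDBStateModel,
    duration: float,
    rng: np.random.Generator,
    frame_dt: float = FRAME_DT,
    noise_sigma: float = DEFAULT_NOISE_NM,
) -> tuple[SampledTrace, StateTruth]:
    """Generate a trace from the processive/stuck (optionally diffusive) model.

    A continuous-time alternating renewal process: exponential sojourns with
    the model's means, a fresh processive velocity per sojourn, zero velocity
    while stuck.  The initial state is drawn from the stationary distribution.
    The diffusive state, when enabled, interleaves after processive sojourns
    with probability ``p_diffusive`` and contributes zero drift (its Brownian
    wiggle is folded into the frame noise for simplicity).
    """
    if not duration > 0:
        raise ValueError("duration must be strictly positive")
    sojourns: list[tuple[str, float, float]] = []
    t = 0.0
    stuck = rng.random() < model.stuck_fraction
    while t < duration:
        if stuck:
            d = rng.exponential(model.dwell_stuck)
            v = 0.0
            state = "stuck"
        else:
            if model.p_diffusive > 0 and rng.random() < model.p_diffusive:
                d = rng.exponential(model.dwell_diffusive)
                v = 0.0
                state = "diffusive"
            else:
                d = rng.exponential(model.dwell_processive)
                v = rng.normal(model.v_processive_mean, model.v_processive_sd)
                state = "processive"
        d = min(d, duration - t)
        sojourns.append((state, d, v))
        t += d
        stuck = (not stuck) and rng.random() < model.p_stuck
    stuck_time = sum(d for s, d, _ in sojourns if s == "stuck")
    truth = StateTruth(sojourns=sojourns, stuck_time_fraction=stuck_time / duration)
    plan = [(v, d) for s, d, v in sojourns]
    trace, _, _ = _sample_plan(plan, frame_dt, noise_sigma, duration, rng)
    return trace, truth


@dataclass
class PopulationConfig:
    """Mixture of fast (kinesin-only) and slow (both-engaged) traces.

    Defaults emulate the DDB-Kin1 condition: 52% of traces above the fast
    threshold moving near the unloaded kinesin-1 velocity with short
    durations, and 48% slow traces from the processive/stuck DDB model with
    long (mean 22 s) durations and a 26% stuck-time fraction.
    """

    n_traces: int = 100
    fast_weight: float = 0.52
    fast_velocity_mean: float = 586.0
    fast_velocity_sd: float = 80.0
    fast_duration_mean: float = 5.0
    slow_duration_mean: float = 22.2
    slow_model: DDBStateModel = field(
        default_factory=lambda: DDBStateModel.from_stuck_fraction(
            0.26, dwell_stuck=2.8, v_processive_mean=-60.0, v_processive_sd=80.0
        )
    )
    frame_dt: float = FRAME_DT
    noise_sigma: float = DEFAULT_NOISE_NM
    max_duration: float = MAX_IMAGING_S

    def __post_init__(self) -> None:
        if not 0 <= self.fast_weight <= 1:
            raise ValueError("fast_weight must be in [0, 1]")


def gen_population(
    config: PopulationConfig, rng: np.random.Generator
) -> tuple[list[SampledTrace], pd.DataFrame]:
    """Generate a trace population with a per-trace truth table.

    Truth columns: trace_id, label (fast/slow), true_velocity (nm/s; the
    drawn constant velocity for fast traces, NaN for slow state-model
    traces), duration_s, censored (truncated at the imaging window), and for
    slow traces the realized stuck-time fraction.
    """
    traces: list[SampledTrace] = []
    rows = []
    min_duration = 3 * config.frame_dt
    for i in range(config.n_traces):
        fast = rng.random() < config.fast_weight
        if fast:
            dur = rng.exponential(config.fast_duration_mean)
        else:
            dur = rng.exponential(config.slow_duration_mean)
        censored = dur > config.max_duration
        dur = float(np.clip(dur, min_duration, config.max_duration))
        if fast:
            v = rng.normal(config.fast_velocity_mean, config.fast_velocity_sd)
            trace, _ = gen_segmented_trace(
                TraceSpec(
                    plan=[(v, dur)],
                    frame_dt=config.frame_dt,
                    noise_sigma=config.noise_sigma,
                    max_duration=config.max_duration,
                ),
                rng,
            )
            stuck_frac = np.nan
        else:
            v = np.nan
            trace, truth = gen_ddb_state_trace(
                config.slow_model,
                dur,
                rng,
                frame_dt=config.frame_dt,
                noise_sigma=config.noise_sigma,
            )
            stuck_frac = truth.stuck_time_fraction
        traces.append(trace)
        rows.append(
            {
                "trace_id": i,
                "label": "fast" if fast else "slow",
                "true_velocity": v,
                "duration_s": dur,
                "censored": censored,
                "stuck_time_fraction": stuck_frac,
            }
        )
    return traces, pd.DataFrame(rows)
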