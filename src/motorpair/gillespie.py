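"""Exact stochastic simulation of a kinesin-DDB pair on a 1-D microtubule lattice.

One plus-end-directed kinesin and one minus-end-directed DDB complex are
coupled through linear springs of identical stiffness to a zero-mass,
zero-volume cargo.  Each motor can step forward, step backward, detach from
the microtubule, and reattach after detachment; rates come from
:mod:`motorpair.motor_model` evaluated at the instantaneous linkage tension.
Because the cargo is massless, it sits at the stiffness-weighted mean of the
attached motor positions (the force-balance point), so while both motors are
attached the spring forces on them are equal and opposite.

When one motor detaches the cargo snaps to the remaining attached motor;
a detached motor reattaches at the current cargo position.  A run ends at
``t_max`` or as soon as both motors are detached.

The simulation is an exact Gillespie SSA: between events the state (and
hence every rate) is constant, so waiting times are exponential in the total
rate and the event is chosen proportionally to its rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from motorpair.motor_model import (
    MotorParams,
    detach_rate_under_load,
    forward_rate_under_load,
)

__all__ = [
    "EVENTS",
    "PairState",
    "Trajectory",
    "cargo_position",
    "event_rates",
    "draw_event",
    "apply_event",
    "simulate",
    "simulate_ensemble",
    "iter_ensemble",
    "simulate_single_motor",
]

#: event labels, kinesin first; order fixes the integer codes in Trajectory.events
EVENTS = (
    "forward_k",
    "back_k",
    "detach_k",
    "reattach_k",
    "forward_d",
    "back_d",
    "detach_d",
    "reattach_d",
)
_EVENT_INDEX = {name: i for i, name in enumerate(EVENTS)}


@dataclass(frozen=True)
class PairState:
    """Instantaneous state of the two-motor complex (lab frame, nm, s)."""

    t: float
    pos_k: float
    pos_d: float
    attached_k: bool
    attached_d: bool
    cargo: float


@dataclass
class Trajectory:
    """Event-resolved simulation output.

    ``times``, ``cargo_path``, ``pos_k``, ``pos_d``, ``attached_k``,
    ``attached_d`` have one entry per event plus the initial state (and a
    final entry at ``t_max`` when the run reached it); ``events`` holds one
    integer code per applied event (see :data:`EVENTS`).  The cargo path is
    piecewise constant between successive times.
    """

    times: np.ndarray
    cargo_path: np.ndarray
    pos_k: np.ndarray
    pos_d: np.ndarray
    attached_k: np.ndarray
    attached_d: np.ndarray
    events: np.ndarray
    terminated_early: bool

    @property
    def event_labels(self) -> list[str]:
        return [EVENTS[i] for i in self.events]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def cargo_position(state: PairState, params: tuple[MotorParams, MotorParams]) -> float:
    """Force-balance cargo position (nm) for the current attachment pattern.

    Both motors attached: stiffness-weighted mean of their positions (the
    midpoint for equal stiffness).  One attached: that motor's position.
    Neither attached: the state is terminal and has no cargo position.
    """
    kin, ddb = params
    if state.attached_k and state.attached_d:
        w_k, w_d = kin.stiffness, ddb.stiffness
        return (w_k * state.pos_k + w_d * state.pos_d) / (w_k + w_d)
    if state.attached_k:
        return state.pos_k
    if state.attached_d:
        return state.pos_d
    raise ValueError("both motors detached: terminal state has no cargo position")


def event_rates(
    state: PairState, params: tuple[MotorParams, MotorParams]
) -> dict[str, float]:
    """The eight propensities (1/s) in the current state, keyed by event label.

    An attached motor steps forward at the load-dependent rate, steps back at
    its constant backstepping rate, and detaches at the Bell-model rate; its
    reattachment propensity is zero.  A detached motor has only its
    reattachment propensity.
    """
    kin, ddb = params
    rates = dict.fromkeys(EVENTS, 0.0)
    cargo = cargo_position(state, params)
    if state.attached_k:
        load = kin.direction * kin.stiffness * (cargo - state.pos_k)
        rates["forward_k"] = forward_rate_under_load(load, kin)
        rates["back_k"] = kin.k_backstep
        rates["detach_k"] = detach_rate_under_load(load, kin)
    else:
        rates["reattach_k"] = kin.k_reattach
    if state.attached_d:
        load = ddb.direction * ddb.stiffness * (cargo - state.pos_d)
        rates["forward_d"] = forward_rate_under_load(load, ddb)
        rates["back_d"] = ddb.k_backstep
        rates["detach_d"] = detach_rate_under_load(load, ddb)
    else:
        rates["reattach_d"] = ddb.k_reattach
    return rates


def draw_event(
    rates: Mapping[str, float] | Sequence[float], rng: np.random.Generator
) -> tuple[str | int, float]:
    """Draw (event, waiting time) from the current propensities.

    The waiting time is Exponential(total rate); the event is chosen with
    probability proportional to its rate.  Returns the event label when
    ``rates`` is a mapping, otherwise the index.
    """
    if isinstance(rates, Mapping):
        keys = list(rates)
        values = np.asarray([rates[k] for k in keys], dtype=float)
    else:
        keys = None
        values = np.asarray(rates, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative propensity")
    total = values.sum()
    if not total > 0:
        raise ValueError("total propensity is zero: no event can occur")
    wait = rng.exponential(1.0 / total)
    idx = int(np.searchsorted(np.cumsum(values), rng.random() * total, side="right"))
    idx = min(idx, len(values) - 1)
    return (keys[idx] if keys is not None else idx), wait


def apply_event(
    state: PairState,
    event: str,
    params: tuple[MotorParams, MotorParams],
    wait: float = 0.0,
) -> PairState:
    """Apply one event and return the new state (cargo recomputed).

    Stepping moves the motor one step along its own direction (forward) or
    against it (back); detaching clears the attachment flag and snaps the
    cargo to the remaining motor; reattaching places the motor at the current
    cargo position.
    """
    kin, ddb = params
    t = state.t + wait
    pos_k, pos_d = state.pos_k, state.pos_d
    att_k, att_d = state.attached_k, state.attached_d
    if event == "forward_k":
        _require(att_k, event)
        pos_k += kin.direction * kin.step_size
    elif event == "back_k":
        _require(att_k, event)
        pos_k -= kin.direction * kin.step_size
    elif event == "detach_k":
        _require(att_k, event)
        att_k = False
    elif event == "reattach_k":
        _require(not att_k, event)
        att_k = True
        pos_k = cargo_position(state, params)
    elif event == "forward_d":
        _require(att_d, event)
        pos_d += ddb.direction * ddb.step_size
    elif event == "back_d":
        _require(att_d, event)
        pos_d -= ddb.direction * ddb.step_size
    elif event == "detach_d":
        _require(att_d, event)
        att_d = False
    elif event == "reattach_d":
        _require(not att_d, event)
        att_d = True
        pos_d = cargo_position(state, params)
    else:
        raise ValueError(f"unknown event {event!r}")
    new = PairState(t, pos_k, pos_d, att_k, att_d, cargo=0.0)
    if att_k or att_d:
        new = replace(new, cargo=cargo_position(new, params))
    return new


def _require(ok: bool, event: str) -> None:
    if not ok:
        raise ValueError(f"event {event!r} infeasible in current state")


def simulate(
    params: tuple[MotorParams, MotorParams],
    t_max: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one run of the coupled pair for ``t_max`` seconds.

    Both motors start attached at position 0 (zero initial tension).  The run
    ends at ``t_max`` or as soon as both motors detach, whichever comes
    first; ``terminated_early`` marks the latter.

    The inner loop is hand-inlined for speed (a 50 s run produces thousands
    of events); the rate laws themselves are the functions from
    :mod:`motorpair.motor_model`, so the loop and :func:`event_rates` cannot
    drift apart on the physics.
    """
    if not t_max > 0:
        raise ValueError("t_max must be strictly positive")
    kin, ddb = params
    step_k = kin.direction * kin.step_size
    step_d = ddb.direction * ddb.step_size
    w_k, w_d = kin.stiffness, ddb.stiffness
    w_sum = w_k + w_d

    t = 0.0
    pos_k = pos_d = cargo = 0.0
    att_k = att_d = True

    times = [0.0]
    cargo_log = [0.0]
    pos_k_log = [0.0]
    pos_d_log = [0.0]
    att_k_log = [True]
    att_d_log = [True]
    events: list[int] = []
    terminated_early = False

    exp = rng.exponential
    uni = rng.random

    while True:
        # propensities at the current state
        if att_k:
            load_k = kin.direction * w_k * (cargo - pos_k)
            r0 = forward_rate_under_load(load_k, kin)
            r1 = kin.k_backstep
            r2 = detach_rate_under_load(load_k, kin)
            r3 = 0.0
        else:
            r0 = r1 = r2 = 0.0
            r3 = kin.k_reattach
        if att_d:
            load_d = ddb.direction * w_d * (cargo - pos_d)
            r4 = forward_rate_under_load(load_d, ddb)
            r5 = ddb.k_backstep
            r6 = detach_rate_under_load(load_d, ddb)
            r7 = 0.0
        else:
            r4 = r5 = r6 = 0.0
            r7 = ddb.k_reattach

        total = r0 + r1 + r2 + r3 + r4 + r5 + r6 + r7
        wait = exp(1.0 / total)
        if t + wait > t_max:
            # run reached the recording horizon; close the piecewise path at t_max
            times.append(t_max)
            cargo_log.append(cargo)
            pos_k_log.append(pos_k)
            pos_d_log.append(pos_d)
            att_k_log.append(att_k)
            att_d_log.append(att_d)
            break
        t += wait

        u = uni() * total
        if u < r0:
            ev = 0
            pos_k += step_k
        elif u < r0 + r1:
            ev = 1
            pos_k -= step_k
        elif u < r0 + r1 + r2:
            ev = 2
            att_k = False
        elif u < r0 + r1 + r2 + r3:
            ev = 3
            att_k = True
            pos_k = cargo
        elif u < r0 + r1 + r2 + r3 + r4:
            ev = 4
            pos_d += step_d
        elif u < r0 + r1 + r2 + r3 + r4 + r5:
            ev = 5
            pos_d -= step_d
        elif u < total - r7:
            ev = 6
            att_d = False
        else:
            ev = 7
            att_d = True
            pos_d = cargo

        # cargo re-equilibrates instantly after every event
        if att_k and att_d:
            cargo = (w_k * pos_k + w_d * pos_d) / w_sum
        elif att_k:
            cargo = pos_k
        elif att_d:
            cargo = pos_d

        events.append(ev)
        times.append(t)
        pos_k_log.append(pos_k)
        pos_d_log.append(pos_d)
        att_k_log.append(att_k)
        att_d_log.append(att_d)
        cargo_log.append(cargo if (att_k or att_d) else cargo_log[-1])

        if not att_k and not att_d:
            terminated_early = True
            break

    return Trajectory(
        times=np.asarray(times),
        cargo_path=np.asarray(cargo_log),
        pos_k=np.asarray(pos_k_log),
        pos_d=np.asarray(pos_d_log),
        attached_k=np.asarray(att_k_log, dtype=bool),
        attached_d=np.asarray(att_d_log, dtype=bool),
        events=np.asarray(events, dtype=np.int8),
        terminated_early=terminated_early,
    )


def iter_ensemble(
    params: tuple[MotorParams, MotorParams],
    n_runs: int,
    t_max: float,
    master_seed: int,
) -> Iterator[Trajectory]:
    """Yield ``n_runs`` independent runs from per-run substreams of ``master_seed``.

    Substreams come from ``np.random.SeedSequence(master_seed).spawn``, so the
    ensemble is bitwise reproducible given (master_seed, n_runs, params) and
    independent of consumption order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    for child in np.random.SeedSequence(master_seed).spawn(n_runs):
        yield simulate(params, t_max, np.random.Generator(np.random.PCG64(child)))


def simulate_ensemble(
    params: tuple[MotorParams, MotorParams],
    n_runs: int,
    t_max: float,
    master_seed: int,
) -> list[Trajectory]:
    """Materialized form of :func:`iter_ensemble`."""
    return list(iter_ensemble(params, n_runs, t_max, master_seed))


def simulate_single_motor(
    p: MotorParams,
    rng: np.random.Generator,
    t_max: float = math.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one unloaded motor until it detaches (or ``t_max``).

    Returns (times, positions) of the stepping path, ending at the detachment
    event (position unchanged by detachment).  Useful as a closed-form
    benchmark: mean velocity is ``(k_forward0 - k_backstep) * step_size`` and
    mean run length ``v / k_detach0``.
    """
    t, pos = 0.0, 0.0
    times, positions = [0.0], [0.0]
    total = p.k_forward0 + p.k_backstep + p.k_detach0
    while True:
        wait = rng.exponential(1.0 / total)
        if t + wait > t_max:
            times.append(t_max)
            positions.append(pos)
            break
        t += wait
        u = rng.random() * total
        if u < p.k_forward0:
            pos += p.direction * p.step_size
        elif u < p.k_forward0 + p.k_backstep:
            pos -= p.direction * p.step_size
        else:
            times.append(t)
            positions.append(pos)
            break
        times.append(t)
        positions.append(pos)
    return np.asarray(times), np.asarray(positions)
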