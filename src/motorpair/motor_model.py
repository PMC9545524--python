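"""Motor parameter sets and closed-form rate laws for the stepping model.

Each motor species (kinesin-1/-2/-3, or the dynein-dynactin-BicD2 complex,
"DDB") is described by a :class:`MotorParams` record holding its unloaded
kinetics and its mechanical response to load:

- a linear force-velocity relation: the forward stepping rate interpolates
  from ``k_forward0`` at zero load down to the backstepping rate at the stall
  force, so the net stepping velocity is zero at stall;
- Bell-model detachment ``k_detach(F) = k_detach0 * exp(|F| / F_detach)``,
  with ``F_detach = k_B T / delta``; an infinite ``f_detach`` encodes an
  ideal bond whose off-rate is load independent (used for DDB);
- a Hookean linkage of stiffness ``stiffness`` (pN/nm) connecting the motor
  to the shared cargo.

Sign convention: all positions and forces live in a single lab frame with
the microtubule plus-end positive.  ``direction`` is +1 for plus-end-directed
motors and -1 for minus-end-directed motors; a lab-frame force ``F`` on a
motor is assisting when ``F * direction > 0`` and hindering otherwise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "MotorParams",
    "PhysicalConstants",
    "ParameterWarning",
    "derive_forward_rate",
    "derive_unloaded_detach_rate",
    "derive_detach_force",
    "derive_reattach_rate",
    "derive_linkage_stiffness",
    "forward_rate_under_load",
    "detach_rate_under_load",
    "linkage_force",
    "load_params",
    "reference_params",
]

#: sentinel accepted in config files for an ideal (load-independent) bond
_IDEAL_TOKENS = {"ideal", "inf", "infinity", "ideal bond", "ideal_bond"}


class ParameterWarning(UserWarning):
    """A motor parameter set is internally inconsistent but still usable."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the assay. ``thermal_energy`` is k_B*T in pN*nm."""

    thermal_energy: float = 4.1

    def __post_init__(self) -> None:
        if not self.thermal_energy > 0:
            raise ValueError("thermal_energy must be strictly positive")


@dataclass(frozen=True)
class MotorParams:
    """Kinetic and mechanical parameters of one motor species.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"Kin1"``, ``"DDB"``).
    direction : int
        +1 for plus-end-directed (kinesin), -1 for minus-end-directed (DDB).
    v0 : float
        Unloaded velocity (nm/s).
    step_size : float
        Step size L_step (nm); 8 nm for both kinesin and DDB here.
    k_forward0 : float
        Unloaded forward stepping rate (1/s).
    k_backstep : float
        Backstepping rate (1/s), load independent.
    k_detach0 : float
        Unloaded detachment rate (1/s).
    f_stall : float
        Stall force (pN): hindering load at which net stepping velocity is 0.
    f_detach : float
        Bell detachment force parameter (pN); ``math.inf`` means ideal bond.
    k_reattach : float
        First-order reattachment rate of the detached, cargo-tethered motor (1/s).
    stiffness : float
        Motor-cargo linkage stiffness (pN/nm).
    run_length0 : float or None
        Unloaded run length (nm), if known; used only for consistency checks.
    """

    name: str
    direction: int
    v0: float
    step_size: float
    k_forward0: float
    k_backstep: float
    k_detach0: float
    f_stall: float
    f_detach: float
    k_reattach: float
    stiffness: float
    run_length0: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        for field in ("v0", "k_forward0", "k_backstep", "k_detach0", "k_reattach"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        for field in ("step_size", "f_stall", "stiffness"):
            if not getattr(self, field) > 0:
                raise ValueError(f"{field} must be strictly positive")
        if not self.f_detach > 0:  # inf is allowed (ideal bond)
            raise ValueError("f_detach must be positive or infinite (ideal bond)")
        if self.run_length0 is not None and not self.run_length0 > 0:
            raise ValueError("run_length0 must be strictly positive when given")

    @property
    def ideal_bond(self) -> bool:
        """True when detachment is load independent."""
        return math.isinf(self.f_detach)

    def validate_consistency(self, tol_rate: float = 0.5) -> list[str]:
        """Check derived-vs-stated parameter consistency.

        Returns a list of human-readable inconsistency messages (empty when
        consistent).  ``k_forward0`` is compared with ``v0/step_size +
        k_backstep`` and, when ``run_length0`` is given, ``k_detach0`` with
        ``v0/run_length0``.  Inconsistencies are warnings, not errors: stated
        values win (they may encode measurements the derivation cannot).
        """
        messages = []
        derived_fwd = derive_forward_rate(self.v0, self.step_size, self.k_backstep)
        if abs(derived_fwd - self.k_forward0) > tol_rate:
            messages.append(
                f"{self.name}: k_forward0 {self.k_forward0:g} != "
                f"v0/step_size + k_backstep = {derived_fwd:g}"
            )
        if self.run_length0 is not None:
            derived_det = derive_unloaded_detach_rate(self.v0, self.run_length0)
            if abs(derived_det - self.k_detach0) > 0.05 * max(self.k_detach0, derived_det):
                messages.append(
                    f"{self.name}: k_detach0 {self.k_detach0:g} != "
                    f"v0/run_length0 = {derived_det:g}"
                )
        return messages

    def with_overrides(self, **kwargs) -> "MotorParams":
        """Return a copy with the given fields replaced (e.g. ``k_reattach=5``)."""
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MotorParams":
        d = dict(d)
        f_detach = d.get("f_detach")
        if isinstance(f_detach, str):
            if f_detach.strip().lower() in _IDEAL_TOKENS:
                d["f_detach"] = math.inf
            else:
                d["f_detach"] = float(f_detach)
        return cls(**d)


# ---------------------------------------------------------------------------
# Closed-form parameter derivations
# ---------------------------------------------------------------------------

def derive_forward_rate(v0: float, step_size: float, k_backstep: float) -> float:
    """Unloaded forward stepping rate k_forward0 = v0/L_step + k_back (1/s).

    The unloaded velocity reflects the *net* of forward and backward steps,
    so the forward rate must exceed v0/L_step by the backstepping rate.
    """
    if not step_size > 0:
        raise ValueError("step_size must be strictly positive")
    if v0 < 0 or k_backstep < 0:
        raise ValueError("v0 and k_backstep must be non-negative")
    return v0 / step_size + k_backstep


def derive_unloaded_detach_rate(v0: float, run_length0: float) -> float:
    """Unloaded detachment rate k_detach0 = v0 / RL0 (1/s)."""
    if not run_length0 > 0:
        raise ValueError("run_length0 must be strictly positive")
    if v0 < 0:
        raise ValueError("v0 must be non-negative")
    return v0 / run_length0


def derive_detach_force(thermal_energy: float, delta: float) -> float:
    """Detachment force parameter F_detach = k_B*T / delta (pN).

    ``delta`` is the Bell distance parameter (nm) reported by optical-tweezer
    studies; smaller delta means a less load-sensitive bond.
    """
    if not thermal_energy > 0 or not delta > 0:
        raise ValueError("thermal_energy and delta must be strictly positive")
    return thermal_energy / delta


def derive_reattach_rate(on_rate_constant: float, tubulin_conc: float) -> float:
    """First-order reattachment rate k_reattach = k_on^Mt * [tubulin] (1/s).

    ``on_rate_constant`` in 1/(uM*s); ``tubulin_conc`` is the effective local
    tubulin concentration (uM) seen by a tethered motor.
    """
    if on_rate_constant < 0 or tubulin_conc < 0:
        raise ValueError("inputs must be non-negative")
    return on_rate_constant * tubulin_conc


def derive_linkage_stiffness(force: float, extension: float) -> float:
    """Linkage stiffness kappa = force / extension (pN/nm)."""
    if not extension > 0:
        raise ValueError("extension must be strictly positive")
    if force < 0:
        raise ValueError("force must be non-negative")
    return force / extension


# ---------------------------------------------------------------------------
# Load-dependent rate laws
# ---------------------------------------------------------------------------

def forward_rate_under_load(
    load: float, p: MotorParams, superstall_anchor: bool = False
) -> float:
    """Forward stepping rate (1/s) at a given load in the motor's own convention.

    ``load`` is signed per-motor: positive assisting, negative hindering
    (convert a lab-frame force F with ``load = F * p.direction``).  Assisting
    or zero load leaves the rate at ``k_forward0``.  A hindering load of
    magnitude m follows the linear force-velocity law: the rate interpolates
    from ``k_forward0`` at m = 0 through ``k_backstep`` at the stall force
    (net stepping velocity exactly zero at stall) and continues along the
    same line under super-stall loads, floored at zero -- so a super-stalled
    motor slips backward at up to ``k_backstep * step_size`` per second.
    With ``superstall_anchor=True`` the rate is instead clamped at
    ``k_backstep`` beyond stall (the motor holds its ground; exposed for
    sensitivity analysis).
    """
    if load >= 0:
        return p.k_forward0
    m = -load
    rate = p.k_forward0 + (p.k_backstep - p.k_forward0) * m / p.f_stall
    if superstall_anchor:
        return max(rate, p.k_backstep)
    return max(rate, 0.0)


def detach_rate_under_load(load: float, p: MotorParams) -> float:
    """Bell-model detachment rate k_detach0 * exp(|load| / F_detach) (1/s).

    Ideal-bond species (``f_detach`` infinite) detach at ``k_detach0``
    regardless of load.  The exponent uses the magnitude of linkage tension
    for assisting and hindering load alike (symmetric slip bond).
    """
    if p.ideal_bond:
        return p.k_detach0
    return p.k_detach0 * math.exp(abs(load) / p.f_detach)


def linkage_force(motor_pos: float, cargo_pos: float, stiffness: float) -> float:
    """Lab-frame spring force (pN) on the motor; pulls the motor toward the cargo.

    Positive when the cargo is plus-end-ward of the motor.
    """
    if not stiffness > 0:
        raise ValueError("stiffness must be strictly positive")
    return stiffness * (cargo_pos - motor_pos)


# ---------------------------------------------------------------------------
# Parameter serialization
# ---------------------------------------------------------------------------

def load_params(path: str | Path, warn: bool = True) -> dict[str, MotorParams]:
    """Load motor parameter sets from a JSON config file.

    The file maps species names to blocks whose keys are the
    :class:`MotorParams` field names; ``f_detach`` may be the string
    ``"ideal"`` for a load-independent bond.  Consistency between stated and
    derivable rates is checked and reported via :class:`ParameterWarning`
    (stated values are kept).
    """
    with open(path) as fh:
        raw = json.load(fh)
    return _params_from_mapping(raw, warn=warn)


def _params_from_mapping(raw: dict, warn: bool) -> dict[str, MotorParams]:
    out: dict[str, MotorParams] = {}
    for name, block in raw.items():
        block = dict(block)
        block.setdefault("name", name)
        try:
            p = MotorParams.from_dict(block)
        except TypeError as exc:
            raise ValueError(f"species {name!r}: bad or missing keys ({exc})") from exc
        if warn:
            for msg in p.validate_consistency():
                warnings.warn(msg, ParameterWarning, stacklevel=3)
        out[name] = p
    return out


def reference_params(warn: bool = False) -> dict[str, MotorParams]:
    """The bundled reference parameter table for Kin1, Kin2, Kin3 and DDB.

    The DDB ``k_forward0`` of 60 1/s is the stated value and is knowingly
    larger than ``v0/step_size + k_backstep`` = 50 1/s; with ``warn=True``
    the inconsistency is surfaced as a :class:`ParameterWarning`.
    """
    ref = resources.files("motorpair").joinpath("data/reference_params.json")
    raw = json.loads(ref.read_text())
    return _params_from_mapping(raw, warn=warn)
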