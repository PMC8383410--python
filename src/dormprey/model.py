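"""Four-compartment predator-prey model with prey dormancy.

The community holds two competing prey and one predator.  The perennially
active (PA) prey ``p`` grows fast but has no refuge from predation.  The
dormitive prey exists in two interconvertible forms: an active form ``y1``
that reproduces, and a dormant form ``y2`` that is sterile, exempt from
crowding, and poorly detected by the predator.  The predator ``z`` consumes
all three prey compartments through saturating Holling type-II responses.

Reproduction by the active form is split between active and dormant
offspring by a decreasing sigmoid of predator density, ``mu(z)``: under few
predators almost all energy goes to active offspring, under many predators
most goes into dormancy.  Dormant individuals re-activate at a constant
termination rate ``alpha``.

State densities are in mg L^-1 and rates in day^-1 throughout.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ParameterSet",
    "State",
    "ParameterError",
    "holling_response",
    "dormancy_switch",
    "derivatives",
    "validate_params",
    "DEFAULT_INITIAL_STATE",
]

#: Exponent clamp for the switching sigmoid; beyond this ``exp`` would
#: overflow double precision and the sigmoid is flat to machine precision.
_EXP_CLAMP = 700.0

#: Field order used when packing parameters into a flat vector for the
#: compiled integrator kernels.  Do not reorder.
PARAM_ORDER = (
    "r_p", "r_y", "K", "d_z", "alpha",
    "k_p", "k_y1", "k_y2",
    "c_p", "c_y1", "c_y2",
    "h_p", "h_y1", "h_y2",
    "eta", "sigma", "chi", "phi",
)

SPECIES = ("p", "y1", "y2", "z")


class ParameterError(ValueError):
    """A parameter set violates a model invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """Immutable record of all model parameters.

    Defaults are the reference parameterisation drawn from zooplankton
    predator-prey data; every simulation in the package starts from these
    unless overridden.

    Parameters
    ----------
    r_p, r_y
        Maximum growth rates of the PA prey and the dormitive prey
        (day^-1).  The PA prey is the intrinsically superior competitor,
        ``r_p > r_y``.
    K
        Shared prey carrying capacity (mg L^-1).  Crowding is exerted by
        ``p`` and ``y1`` only; the dormant form does not count.
    d_z
        Predator per-capita death rate (day^-1), density independent.
    alpha
        Dormancy termination rate (day^-1): per-capita rate at which
        dormant individuals re-activate.
    k_p, k_y1, k_y2
        Predator growth efficiencies from each prey compartment
        (dimensionless yield factors).
    c_p, c_y1, c_y2
        Predator foraging efficiencies (day^-1 mg^-1 L).  The dormant
        form is harder to find, hence ``c_y2`` is smallest.
    h_p, h_y1, h_y2
        Predator handling times (day); bound consumption at ``1/h``.
    eta, sigma
        Threshold and width (mg L^-1) of the dormancy switching sigmoid.
    chi, phi
        Lower bound and range of the switching function (dimensionless);
        ``mu(z)`` spans ``[chi, chi + phi]`` and ``0 <= chi <= chi + phi
        <= 1`` is required so that ``mu`` is a valid fraction.
    """

    r_p: float = 0.55
    r_y: float = 0.5
    K: float = 11.0
    d_z: float = 0.2
    alpha: float = 0.05
    k_p: float = 0.5
    k_y1: float = 0.5
    k_y2: float = 0.25
    c_p: float = 1.0
    c_y1: float = 1.0
    c_y2: float = 0.4
    h_p: float = 0.5
    h_y1: float = 0.5
    h_y2: float = 0.5
    eta: float = 1.0
    sigma: float = 0.1
    chi: float = 0.2
    phi: float = 0.75

    def __post_init__(self) -> None:
        validate_params(self)

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields overridden (re-validated)."""
        unknown = set(overrides) - set(PARAM_ORDER)
        if unknown:
            raise ParameterError(
                f"unknown parameter(s): {sorted(unknown)}; "
                f"valid names are {list(PARAM_ORDER)}"
            )
        return dataclasses.replace(self, **overrides)

    def to_vector(self) -> np.ndarray:
        """Pack into a float vector in :data:`PARAM_ORDER` order."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_ORDER}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        """Build from a flat mapping; unknown keys are an error (catches typos)."""
        unknown = set(mapping) - set(PARAM_ORDER)
        if unknown:
            raise ParameterError(
                f"unknown parameter(s): {sorted(unknown)}; "
                f"valid names are {list(PARAM_ORDER)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class State:
    """Instantaneous densities (mg L^-1) of the four compartments."""

    p: float = 2.0
    y1: float = 2.0
    y2: float = 0.0
    z: float = 1.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"state density {name} must be finite and >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([self.p, self.y1, self.y2, self.z], dtype=np.float64)

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "State":
        vals = [float(v) for v in values]
        if len(vals) != 4:
            raise ValueError(f"a state needs exactly 4 densities (p, y1, y2, z), got {len(vals)}")
        return cls(*vals)


#: Reference initial community: equal PA and active dormitive prey, no
#: dormant stock, one unit of predator.
DEFAULT_INITIAL_STATE = State(2.0, 2.0, 0.0, 1.0)


def validate_params(params: ParameterSet) -> ParameterSet:
    """Check every model invariant; return the set unchanged if valid.

    Raises
    ------
    ParameterError
        Naming each violated invariant.  In particular ``chi + phi > 1``
        is rejected because the switching fraction ``mu(z)`` must stay in
        ``[0, 1]``.
    """
    problems: list[str] = []
    for name in PARAM_ORDER:
        v = getattr(params, name)
        if not math.isfinite(v):
            problems.append(f"{name} must be finite, got {v}")
        elif v < 0:
            problems.append(f"{name} must be >= 0, got {v}")
    if params.K <= 0:
        problems.append(f"K must be > 0, got {params.K}")
    if params.sigma <= 0:
        problems.append(f"sigma must be > 0 (switching width), got {params.sigma}")
    for name in ("h_p", "h_y1", "h_y2"):
        if getattr(params, name) <= 0:
            problems.append(f"{name} must be > 0 (handling time), got {getattr(params, name)}")
    # small slack so grid values that sum to 1 up to rounding are not rejected
    if params.chi + params.phi > 1.0 + 1e-9:
        problems.append(
            f"chi + phi = {params.chi + params.phi} exceeds 1: the switching "
            "function mu(z) = chi + phi/(1 + exp((z - eta)/sigma)) must stay in [0, 1]"
        )
    if problems:
        raise ParameterError("; ".join(problems))
    return params


def holling_response(q, c_q: float, h_q: float):
    """Holling type-II per-predator consumption rate ``c q / (1 + c h q)``.

    Linear (``c_q * q``) at low prey density and saturating at ``1/h_q``
    as prey becomes abundant.  Accepts scalar or array prey density ``q``.
    """
    if c_q < 0:
        raise ValueError(f"foraging efficiency c_q must be >= 0, got {c_q}")
    if h_q <= 0:
        raise ValueError(f"handling time h_q must be > 0, got {h_q}")
    q = np.asarray(q, dtype=np.float64)
    if np.any(q < 0):
        raise ValueError("prey density q must be >= 0")
    out = c_q * q / (1.0 + c_q * h_q * q)
    return float(out) if out.ndim == 0 else out


def dormancy_switch(z, params: ParameterSet):
    """Fraction ``mu(z)`` of dormitive-prey reproduction allocated to
    active offspring.

    ``mu(z) = chi + phi / (1 + exp((z - eta) / sigma))`` — a decreasing
    sigmoid of predator density ``z``, ranging from ``chi + phi`` (no
    predators) down to ``chi`` (predator-saturated).  The exponent is
    clamped at +/-700 so extreme densities return the limits exactly
    instead of overflowing.  Accepts scalar or array ``z``.
    """
    z = np.asarray(z, dtype=np.float64)
    x = np.clip((z - params.eta) / params.sigma, -_EXP_CLAMP, _EXP_CLAMP)
    out = params.chi + params.phi / (1.0 + np.exp(x))
    return float(out) if out.ndim == 0 else out


def derivatives(state, params: ParameterSet) -> np.ndarray:
    """Right-hand side of the model: rates of change of (p, y1, y2, z).

    The two growing prey share one logistic crowding factor
    ``1 - (p + y1)/K`` (the dormant stock exerts no crowding).  Active
    dormitive reproduction is split ``mu(z) : 1 - mu(z)`` between active
    and dormant offspring; the dormant pool feeds back into the active one
    at rate ``alpha``.  Each prey compartment loses ``f_q(q) z`` to
    predation and the predator converts those captures with efficiencies
    ``k_q`` while dying at constant rate ``d_z``.

    Tiny negative densities from solver undershoot (magnitude below the
    absolute tolerance) are treated as zero inside the response and
    crowding terms, keeping the vector field smooth without mutating the
    state itself.
    """
    validate_params(params)
    s = state.to_array() if isinstance(state, State) else np.asarray(state, dtype=np.float64)
    if s.shape != (4,):
        raise ValueError(f"state must have 4 components (p, y1, y2, z), got shape {s.shape}")
    p, y1, y2, z = s
    pc, y1c, y2c = max(p, 0.0), max(y1, 0.0), max(y2, 0.0)

    f_p = holling_response(pc, params.c_p, params.h_p)
    f_y1 = holling_response(y1c, params.c_y1, params.h_y1)
    f_y2 = holling_response(y2c, params.c_y2, params.h_y2)
    mu = dormancy_switch(z, params)
    crowd = 1.0 - (pc + y1c) / params.K

    dp = params.r_p * crowd * p - f_p * z
    dy1 = params.r_y * crowd * mu * y1 + params.alpha * y2 - f_y1 * z
    dy2 = params.r_y * crowd * (1.0 - mu) * y1 - params.alpha * y2 - f_y2 * z
    dz = (
        params.k_p * f_p * z
        + params.k_y1 * f_y1 * z
        + params.k_y2 * f_y2 * z
        - params.d_z * z
    )
    return np.array([dp, dy1, dy2, dz])
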