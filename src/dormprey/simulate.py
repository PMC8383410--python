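"""Time integration of the dormancy model.

The default integrator is the package's compiled Bogacki-Shampine (2,3)
pair at rtol = atol = 1e-8 — the embedded explicit Runge-Kutta pair
classically used for this model family — with dense output sampled every
0.1 day.  Any scipy ``solve_ivp`` method name (``"RK23"``, ``"RK45"``,
``"DOP853"``, ...) can be requested instead through
``SolverSettings.method``; the test suite uses those as independent
cross-checks of the compiled core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _bs23
from .model import (
    DEFAULT_INITIAL_STATE,
    ParameterSet,
    State,
    validate_params,
)

__all__ = [
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "rm_reference",
    "DEFAULT_T_END",
]

#: Default integration horizon (days): long enough to cover the stable
#: competition window [2800, 3000] used by the parameter sweeps.
DEFAULT_T_END = 3000.0


class IntegrationError(RuntimeError):
    """The solver failed; ``t_fail`` records when."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (at t = {t_fail:g} days)")
        self.t_fail = t_fail


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.

    ``method="bs23"`` selects the compiled Bogacki-Shampine pair; any
    other value is passed through to :func:`scipy.integrate.solve_ivp`.
    ``output_dt`` only controls the dense-output sampling grid — the
    adaptive step controller is driven by the tolerances alone, so
    refining it does not change the solution.
    """

    rtol: float = 1e-8
    atol: float = 1e-8
    method: str = "bs23"
    output_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be positive")

    def to_dict(self) -> dict:
        return {
            "rtol": self.rtol,
            "atol": self.atol,
            "method": self.method,
            "output_dt": self.output_dt,
        }


DEFAULT_SETTINGS = SolverSettings()


@dataclass(frozen=True)
class Trajectory:
    """A dense solution: sample times, state matrix and full provenance."""

    times: np.ndarray          # (n,) strictly increasing, days
    states: np.ndarray         # (n, 4) columns p, y1, y2, z, mg L^-1
    params: ParameterSet
    settings: SolverSettings

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y1(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def y2(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 3]

    def species(self, label: str) -> np.ndarray:
        """Density series for one of ``p``, ``y1``, ``y2``, ``z``."""
        try:
            col = ("p", "y1", "y2", "z").index(label)
        except ValueError:
            raise ValueError(
                f"unknown species {label!r}; expected one of 'p', 'y1', 'y2', 'z'"
            ) from None
        return self.states[:, col]

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        """Tidy table with columns time, p, y1, y2, z."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "p": self.p,
                "y1": self.y1,
                "y2": self.y2,
                "z": self.z,
            }
        )


def _output_grid(t_start: float, t_end: float, dt: float) -> np.ndarray:
    """Uniform grid with spacing ``dt`` from ``t_start``; ``t_end`` is
    always included (appended if the span is not a whole number of steps)."""
    n = int(np.floor((t_end - t_start) / dt + 1e-9))
    grid = t_start + dt * np.arange(n + 1)
    if grid[-1] < t_end - 1e-9 * max(1.0, abs(t_end)):
        grid = np.append(grid, t_end)
    else:
        grid[-1] = t_end
    return grid


def _run(
    model_id: int,
    params: ParameterSet,
    y0: np.ndarray,
    t_span: tuple[float, float],
    settings: SolverSettings,
) -> Trajectory:
    t_start, t_end = float(t_span[0]), float(t_span[1])
    if not (t_end > t_start >= 0):
        raise ValueError(f"need t_end > t_start >= 0, got span ({t_start}, {t_end})")
    validate_params(params)
    t_out = _output_grid(t_start, t_end, settings.output_dt)

    if settings.method == "bs23":
        status, t_fail, states = _bs23.integrate_bs23(
            model_id,
            params.to_vector(),
            y0,
            t_start,
            t_end,
            settings.rtol,
            settings.atol,
            t_out,
        )
        if status == _bs23.STEP_TOO_SMALL:
            raise IntegrationError("step size underflow", t_fail)
        if status == _bs23.NONFINITE:
            raise IntegrationError("non-finite state encountered", t_fail)
    else:
        from scipy.integrate import solve_ivp

        if model_id == _bs23.MODEL_RM:
            def rhs(t, y, pv=params.to_vector()):
                out = np.empty(4)
                _bs23._rhs(_bs23.MODEL_RM, y, pv, out)
                return out
        else:
            from .model import derivatives

            def rhs(t, y, pr=params):
                return derivatives(y, pr)

        sol = solve_ivp(
            rhs,
            (t_start, t_end),
            y0,
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            t_eval=t_out,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else t_start)
        states = sol.y.T.copy()

    if np.any(states < -1e-6):
        worst = float(states.min())
        raise IntegrationError(
            f"stored density undershoot {worst:g} below -1e-6 signals solver failure",
            t_start,
        )
    return Trajectory(times=t_out, states=states, params=params, settings=settings)


def integrate(
    params: ParameterSet | None = None,
    initial: State | Sequence[float] | None = None,
    t_span: tuple[float, float] = (0.0, DEFAULT_T_END),
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> Trajectory:
    """Integrate the full four-compartment model over ``t_span``.

    Parameters default to the reference parameterisation and the reference
    initial community (2, 2, 0, 1) mg L^-1.  The run is deterministic:
    identical inputs give bit-identical trajectories.
    """
    params = params if params is not None else ParameterSet()
    if initial is None:
        initial = DEFAULT_INITIAL_STATE
    state = initial if isinstance(initial, State) else State.from_iterable(initial)
    return _run(_bs23.MODEL_FULL, params, state.to_array(), t_span, settings)


def rm_reference(
    params: ParameterSet | None = None,
    initial: Sequence[float] = (2.0, 1.0),
    t_span: tuple[float, float] = (0.0, 500.0),
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> Trajectory:
    """Integrate the two-species Rosenzweig-MacArthur reduction.

    Only the PA prey and the predator are present; the right-hand side is
    coded independently of the full model (classic logistic prey +
    type-II predation + linear predator mortality) and serves as the
    oracle for the reduction property: the full model started from
    ``y1 = y2 = 0`` must reproduce it exactly.

    ``initial`` is the (p, z) pair; the returned trajectory keeps the
    four-column layout with ``y1`` and ``y2`` identically zero.
    """
    params = params if params is not None else ParameterSet()
    p0, z0 = (float(v) for v in initial)
    if p0 < 0 or z0 < 0:
        raise ValueError("initial densities must be >= 0")
    y0 = np.array([p0, 0.0, 0.0, z0])
    return _run(_bs23.MODEL_RM, params, y0, t_span, settings)
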