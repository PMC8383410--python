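"""Two-parameter sweeps of the competition outcome.

Each sweep varies two parameters over a grid, integrates the full model
from the reference initial community for every feasible cell, and
records who wins over the stable late-time window.  Cells whose
parameter combination violates a joint constraint (e.g. ``chi + phi >
1``, or a dormant-form foraging efficiency exceeding the active forms')
are masked infeasible rather than raising, so the grid keeps its shape
for plotting.

The six canonical panels pair (K, alpha), (K, d_z), (chi, phi),
(eta, sigma), growth efficiencies and foraging efficiencies; in the last
two the PA-prey and active-form parameters vary together on one tied
axis, reflecting that both active prey are equally visible to the
predator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import DEFAULT_INITIAL_STATE, PARAM_ORDER, ParameterError, ParameterSet, State
from .metrics import STABLE_WINDOW, CompetitionOutcome, classify_winner
from .simulate import DEFAULT_SETTINGS, SolverSettings, integrate

__all__ = ["AxisSpec", "SweepGrid", "run_grid", "figure3_panels", "PANEL_NAMES"]


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a parameter (or several tied together) and its grid.

    ``parameter`` may be a single field name or a tuple of field names
    that all receive the axis value (tied axis, e.g. ``("k_p", "k_y1")``).
    """

    parameter: str | tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        names = self.names
        for name in names:
            if name not in PARAM_ORDER:
                raise ValueError(
                    f"unknown parameter {name!r}; valid names are {list(PARAM_ORDER)}"
                )
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise ValueError("axis needs at least one grid value")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"axis values must be finite, got {vals}")
        object.__setattr__(self, "values", vals)

    @property
    def names(self) -> tuple[str, ...]:
        return (self.parameter,) if isinstance(self.parameter, str) else tuple(self.parameter)

    @property
    def label(self) -> str:
        return "=".join(self.names)

    @staticmethod
    def linspace(parameter, lo: float, hi: float, n: int) -> "AxisSpec":
        return AxisSpec(parameter, tuple(np.linspace(lo, hi, n)))


@dataclass(frozen=True)
class SweepGrid:
    """Winner map over a 2-D parameter grid (axis1-major layout).

    ``winners`` holds ``"PA" | "dormitive" | "none"`` per feasible cell
    and ``""`` where ``feasible`` is False; ``pa_max`` / ``y1_max`` carry
    the window maxima (NaN when infeasible).
    """

    axis1: AxisSpec
    axis2: AxisSpec
    window: tuple[float, float]
    base: ParameterSet
    winners: np.ndarray    # (n1, n2) unicode
    pa_max: np.ndarray     # (n1, n2) float
    y1_max: np.ndarray     # (n1, n2) float
    feasible: np.ndarray   # (n1, n2) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.winners.shape

    def outcome(self, i: int, j: int) -> CompetitionOutcome | None:
        if not self.feasible[i, j]:
            return None
        return CompetitionOutcome(
            winner=str(self.winners[i, j]),
            window=self.window,
            pa_max=float(self.pa_max[i, j]),
            y1_max=float(self.y1_max[i, j]),
        )

    def to_frame(self):
        """Long-format table: one row per grid cell."""
        import pandas as pd

        n1, n2 = self.shape
        i, j = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        return pd.DataFrame(
            {
                f"{self.axis1.label}": np.asarray(self.axis1.values)[i.ravel()],
                f"{self.axis2.label}": np.asarray(self.axis2.values)[j.ravel()],
                "winner": self.winners.ravel(),
                "pa_max": self.pa_max.ravel(),
                "y1_max": self.y1_max.ravel(),
                "feasible": self.feasible.ravel(),
            }
        )


def _cell_params(
    base: ParameterSet, axis1: AxisSpec, axis2: AxisSpec, v1: float, v2: float
) -> ParameterSet | None:
    """Parameter set for one cell, or None if it violates a constraint."""
    overrides = {name: v1 for name in axis1.names}
    overrides.update({name: v2 for name in axis2.names})
    try:
        return base.replace(**overrides)
    except ParameterError:
        return None


def _evaluate_cell(
    params: ParameterSet,
    initial: State,
    window: tuple[float, float],
    settings: SolverSettings,
    threshold: float,
) -> CompetitionOutcome:
    traj = integrate(params, initial, (0.0, window[1]), settings)
    return classify_winner(traj, window, threshold)


def run_grid(
    base: ParameterSet | None = None,
    axis1: AxisSpec | None = None,
    axis2: AxisSpec | None = None,
    window: tuple[float, float] = STABLE_WINDOW,
    initial: State = DEFAULT_INITIAL_STATE,
    settings: SolverSettings = DEFAULT_SETTINGS,
    threshold: float = 1e-3,
    constraint: Callable[[ParameterSet], bool] | None = None,
    n_jobs: int = 1,
) -> SweepGrid:
    """Winner map over the product of two axis grids.

    Every feasible cell is an independent integration from ``initial`` to
    the end of ``window`` followed by winner classification; cells are
    embarrassingly parallel and ``n_jobs > 1`` distributes them with
    joblib, with results identical to serial execution.  ``constraint``
    optionally marks additional cells infeasible (it receives the
    validated per-cell parameter set and returns False to mask).
    """
    base = base if base is not None else ParameterSet()
    if axis1 is None or axis2 is None:
        raise ValueError("both sweep axes must be given")
    if set(axis1.names) & set(axis2.names):
        raise ValueError(
            f"axes must vary distinct parameters; both touch {set(axis1.names) & set(axis2.names)}"
        )
    n1, n2 = len(axis1.values), len(axis2.values)
    winners = np.full((n1, n2), "", dtype="U9")
    pa_max = np.full((n1, n2), np.nan)
    y1_max = np.full((n1, n2), np.nan)
    feasible = np.zeros((n1, n2), dtype=bool)

    cells: list[tuple[int, int, ParameterSet]] = []
    for i, v1 in enumerate(axis1.values):
        for j, v2 in enumerate(axis2.values):
            params = _cell_params(base, axis1, axis2, v1, v2)
            if params is None or (constraint is not None and not constraint(params)):
                continue
            cells.append((i, j, params))

    if n_jobs == 1:
        results = [
            _evaluate_cell(p, initial, window, settings, threshold) for _, _, p in cells
        ]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_cell)(p, initial, window, settings, threshold)
            for _, _, p in cells
        )

    for (i, j, _), out in zip(cells, results):
        feasible[i, j] = True
        winners[i, j] = out.winner
        pa_max[i, j] = out.pa_max
        y1_max[i, j] = out.y1_max
    return SweepGrid(
        axis1=axis1,
        axis2=axis2,
        window=window,
        base=base,
        winners=winners,
        pa_max=pa_max,
        y1_max=y1_max,
        feasible=feasible,
    )


#: Default axis ranges for the six canonical panels: chosen to bracket the
#: reference values and the regime shifts (PA-favoured low K, dormitive-
#: favoured high K, the chi + phi <= 1 wedge, sharp-vs-smooth switching).
PANEL_AXES: dict[str, tuple[tuple, tuple]] = {
    "A": (("K", 5.0, 25.0), ("alpha", 0.0, 1.0)),
    "B": (("K", 5.0, 25.0), ("d_z", 0.05, 0.5)),
    "C": (("chi", 0.0, 1.0), ("phi", 0.0, 1.0)),
    "D": (("eta", 0.2, 3.0), ("sigma", 0.01, 1.0)),
    "E": ((("k_p", "k_y1"), 0.1, 0.9), ("k_y2", 0.1, 0.9)),
    "F": ((("c_p", "c_y1"), 0.2, 2.0), ("c_y2", 0.2, 2.0)),
}

PANEL_NAMES = tuple(PANEL_AXES)


def _panel_constraint(panel: str) -> Callable[[ParameterSet], bool] | None:
    if panel == "F":
        # the dormant form cannot be easier to find than the active prey
        return lambda p: p.c_y2 <= p.c_p and p.c_y2 <= p.c_y1
    return None


def figure3_panels(
    resolution: int = 21,
    window: tuple[float, float] = STABLE_WINDOW,
    base: ParameterSet | None = None,
    panels: Sequence[str] = PANEL_NAMES,
    settings: SolverSettings = DEFAULT_SETTINGS,
    n_jobs: int = 1,
    untie: bool = False,
) -> dict[str, SweepGrid]:
    """Run the six canonical paired scans at the given per-axis resolution.

    Panels E and F tie the PA-prey and active-form parameters together on
    axis 1 (``k_p = k_y1``, ``c_p = c_y1``); ``untie=True`` varies only
    the PA-prey parameter instead.  Returns a dict keyed by panel letter.
    """
    if resolution < 5:
        raise ValueError("resolution must be at least 5 per axis")
    base = base if base is not None else ParameterSet()
    out: dict[str, SweepGrid] = {}
    for panel in panels:
        panel = panel.upper()
        if panel not in PANEL_AXES:
            raise ValueError(f"unknown panel {panel!r}; expected one of {list(PANEL_AXES)}")
        (p1, lo1, hi1), (p2, lo2, hi2) = PANEL_AXES[panel]
        if untie and isinstance(p1, tuple):
            p1 = p1[0]
        axis1 = AxisSpec.linspace(p1, lo1, hi1, resolution)
        axis2 = AxisSpec.linspace(p2, lo2, hi2, resolution)
        out[panel] = run_grid(
            base,
            axis1,
            axis2,
            window=window,
            settings=settings,
            constraint=_panel_constraint(panel),
            n_jobs=n_jobs,
        )
    return out
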