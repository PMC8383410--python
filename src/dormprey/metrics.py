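"""Summary statistics of competition trajectories.

The competition between the PA prey and the dormitive prey is read off a
trajectory through a handful of scalar diagnostics:

* cycle **peaks** of each compartment (local maxima of the sampled
  series, refined by quadratic interpolation);
* **extinction time** — when a density falls below a threshold for good;
* **reversal time** ``T_w`` — the first moment a peak of the active
  dormitive form exceeds the PA prey's most recent peak, i.e. when the
  intrinsically disadvantaged prey overtakes;
* the **winner** over a late "stable competition" window, decided by
  which competitor attains the higher maximum density there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .model import ParameterSet, State
from .simulate import SolverSettings, Trajectory, integrate, DEFAULT_SETTINGS

__all__ = [
    "PeakSeries",
    "CompetitionOutcome",
    "find_peaks",
    "extinction_time",
    "reversal_time",
    "classify_winner",
    "reversal_curve",
    "EXTINCTION_THRESHOLD",
    "PEAK_FLOOR",
    "STABLE_WINDOW",
]

#: Default density (mg L^-1) below which a population counts as extinct —
#: three orders of magnitude below the reference initial densities.
EXTINCTION_THRESHOLD = 1e-3

#: Peaks below this density are ignored: solver-scale ripple on a
#: near-extinct series is not a population cycle.
PEAK_FLOOR = 1e-6

#: Late-time window (days) over which maximum densities decide the winner
#: of the competition ("stable competition" window).
STABLE_WINDOW = (2800.0, 3000.0)


@dataclass(frozen=True)
class PeakSeries:
    """Ordered local maxima (time, density) of one compartment's series."""

    species: str
    times: np.ndarray    # (k,) days, strictly increasing
    values: np.ndarray   # (k,) mg L^-1

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self):
        return iter(zip(self.times, self.values))


@dataclass(frozen=True)
class CompetitionOutcome:
    """Who wins the prey competition over a stable late-time window.

    ``winner`` is ``"PA"`` if the PA prey's window maximum strictly
    exceeds the active dormitive form's (and clears the extinction
    threshold), ``"dormitive"`` in the mirror case, and ``"none"`` when
    both are extinct or the maxima tie to machine resolution.
    """

    winner: str
    window: tuple[float, float]
    pa_max: float
    y1_max: float


def find_peaks(
    trajectory: Trajectory,
    species: str,
    floor: float = PEAK_FLOOR,
    refine: bool = True,
) -> PeakSeries:
    """Interior local maxima of one compartment's sampled series.

    A peak is a sample strictly greater than both neighbours; flat-topped
    peaks count once, at the plateau midpoint.  Endpoints are never
    peaks.  Peaks below ``floor`` are dropped.  With ``refine`` (default)
    each strict peak's time and value are sharpened by fitting a parabola
    through the three surrounding samples, so peak times resolve below
    the output sampling interval.
    """
    if len(trajectory) < 3:
        raise ValueError("need at least 3 samples to locate interior peaks")
    v = trajectory.species(species)
    t = trajectory.times
    idx, props = scipy.signal.find_peaks(v, height=floor, plateau_size=1)
    times = t[idx].astype(float)
    values = v[idx].astype(float)

    if refine:
        strict = props["plateau_sizes"] == 1
        for j in np.flatnonzero(strict):
            i = idx[j]
            ym, y0, yp = v[i - 1], v[i], v[i + 1]
            denom = ym - 2.0 * y0 + yp
            if denom >= 0.0:  # degenerate curvature; keep the sample
                continue
            off = 0.5 * (ym - yp) / denom
            dt_l = t[i] - t[i - 1]
            times[j] = t[i] + off * dt_l
            values[j] = y0 - 0.25 * (ym - yp) * off
    return PeakSeries(species=species, times=times, values=values)


def extinction_time(
    trajectory: Trajectory,
    species: str,
    threshold: float = EXTINCTION_THRESHOLD,
) -> float | None:
    """First sample time after which the density stays below ``threshold``
    for the remainder of the trajectory, or ``None`` if the population is
    above threshold at (or recovers by) the final sample.

    Transient sub-threshold dips followed by recovery do not count; the
    returned time is the start of the *permanent* sub-threshold phase.
    """
    if threshold <= 0:
        raise ValueError("extinction threshold must be positive")
    v = trajectory.species(species)
    above = np.flatnonzero(v >= threshold)
    if above.size == 0:
        return float(trajectory.times[0])
    last = above[-1]
    if last == v.size - 1:
        return None
    return float(trajectory.times[last + 1])


def reversal_time(
    trajectory: Trajectory,
    floor: float = PEAK_FLOOR,
) -> float | None:
    """Reversal time ``T_w``: when the disadvantaged prey overtakes.

    Defined as the time of the first local peak of the active dormitive
    form ``y1`` whose density strictly exceeds the density of the most
    recent *preceding* PA-prey peak.  Early ``y1`` peaks arriving before
    any PA peak exists are skipped; once the PA prey is extinct its last
    recorded peak remains the standard of comparison.  ``None`` if no
    such peak occurs within the trajectory.
    """
    pa = find_peaks(trajectory, "p", floor=floor)
    y1 = find_peaks(trajectory, "y1", floor=floor)
    for t_y, v_y in y1:
        prior = np.flatnonzero(pa.times < t_y)
        if prior.size == 0:
            continue
        if v_y > pa.values[prior[-1]]:
            return float(t_y)
    return None


def classify_winner(
    trajectory: Trajectory,
    window: tuple[float, float] = STABLE_WINDOW,
    threshold: float = EXTINCTION_THRESHOLD,
) -> CompetitionOutcome:
    """Decide the competition over a late-time window.

    Compares the maximum sampled densities of ``p`` and ``y1`` over
    ``window``.  A competitor wins only if its maximum both exceeds the
    other's and clears the extinction threshold; if both are below the
    threshold — or the maxima tie exactly — the outcome is ``"none"``.
    """
    lo, hi = float(window[0]), float(window[1])
    t0, t1 = trajectory.t_span
    if lo < t0 - 1e-9 or hi > t1 + 1e-9 or hi <= lo:
        raise ValueError(
            f"window ({lo}, {hi}) outside trajectory span ({t0}, {t1})"
        )
    mask = (trajectory.times >= lo) & (trajectory.times <= hi)
    pa_max = float(trajectory.p[mask].max())
    y1_max = float(trajectory.y1[mask].max())
    if pa_max > y1_max and pa_max >= threshold:
        winner = "PA"
    elif y1_max > pa_max and y1_max >= threshold:
        winner = "dormitive"
    else:
        winner = "none"
    return CompetitionOutcome(winner=winner, window=(lo, hi), pa_max=pa_max, y1_max=y1_max)


def reversal_curve(
    params: ParameterSet | None = None,
    K_values=(),
    initial: State | None = None,
    t_span: tuple[float, float] = (0.0, 1000.0),
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> list[tuple[float, float | None]]:
    """Reversal time as a function of carrying capacity.

    One integration per ``K`` (identical solver settings), returning
    ``(K, T_w)`` pairs with ``None`` where no reversal occurs — e.g. at
    low capacity, where the PA prey keeps the upper hand.
    """
    params = params if params is not None else ParameterSet()
    out: list[tuple[float, float | None]] = []
    for K in K_values:
        K = float(K)
        if K <= 0:
            raise ValueError(f"carrying capacity must be positive, got {K}")
        traj = integrate(params.replace(K=K), initial, t_span, settings)
        out.append((K, reversal_time(traj)))
    return out
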