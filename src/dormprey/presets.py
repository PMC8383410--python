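"""Named scenario presets.

Each preset is one of the reference competition experiments: the
single-form contests (only the active, or only the dormant, form of the
dormitive prey faces the PA prey), the full contest at the default
carrying capacity, and the carrying-capacity variations around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import DEFAULT_INITIAL_STATE, ParameterSet, State
from .simulate import SolverSettings, Trajectory, integrate, DEFAULT_SETTINGS

__all__ = ["ScenarioPreset", "PRESETS", "get_preset", "run_preset"]


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified simulation scenario."""

    name: str
    params: ParameterSet
    initial: State
    t_span: tuple[float, float]
    notes: str

    def run(self, settings: SolverSettings = DEFAULT_SETTINGS) -> Trajectory:
        return integrate(self.params, self.initial, self.t_span, settings)


_DEF = ParameterSet()

#: The reference scenarios.  ``fig1a``: active form only — permanent full
#: allocation to active offspring (chi=1, phi=0) and instant dormancy
#: termination make y2 a pure pass-through that stays empty.  ``fig1b``:
#: dormant form only — no active offspring (chi=phi=0) and no termination
#: (alpha=0) strand the dormitive prey in its sterile form.  ``fig1c``:
#: the full switching contest at the default capacity.  ``fig2a/b/c``:
#: the same contest at K = 13, 20 and 9.
PRESETS: dict[str, ScenarioPreset] = {
    "fig1a": ScenarioPreset(
        name="fig1a",
        params=_DEF.replace(alpha=1.0, chi=1.0, phi=0.0),
        initial=State(2.0, 2.0, 0.0, 1.0),
        t_span=(0.0, 500.0),
        notes="single-form contest: active dormitive form only (mu == 1)",
    ),
    "fig1b": ScenarioPreset(
        name="fig1b",
        params=_DEF.replace(alpha=0.0, chi=0.0, phi=0.0),
        initial=State(2.0, 0.0, 2.0, 1.0),
        t_span=(0.0, 500.0),
        notes="single-form contest: dormant form only (sterile, no termination)",
    ),
    "fig1c": ScenarioPreset(
        name="fig1c",
        params=_DEF,
        initial=DEFAULT_INITIAL_STATE,
        t_span=(0.0, 1000.0),
        notes="full contest with dormancy switching at default K = 11",
    ),
    "fig2a": ScenarioPreset(
        name="fig2a",
        params=_DEF.replace(K=13.0),
        initial=DEFAULT_INITIAL_STATE,
        t_span=(0.0, 1000.0),
        notes="full contest at raised carrying capacity K = 13",
    ),
    "fig2b": ScenarioPreset(
        name="fig2b",
        params=_DEF.replace(K=20.0),
        initial=DEFAULT_INITIAL_STATE,
        t_span=(0.0, 1000.0),
        notes="full contest at high carrying capacity K = 20",
    ),
    "fig2c": ScenarioPreset(
        name="fig2c",
        params=_DEF.replace(K=9.0),
        initial=DEFAULT_INITIAL_STATE,
        t_span=(0.0, 3000.0),
        notes="full contest at low carrying capacity K = 9 (PA prey persists)",
    ),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def run_preset(name: str, settings: SolverSettings = DEFAULT_SETTINGS) -> Trajectory:
    """Integrate a named scenario and return its trajectory."""
    return get_preset(name).run(settings)
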