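"""Peak detection, extinction, reversal time and winner classification."""

import numpy as np
import pytest

from dormprey import (
    ParameterSet,
    SolverSettings,
    Trajectory,
    classify_winner,
    extinction_time,
    find_peaks,
    reversal_curve,
    reversal_time,
)

SETTINGS = SolverSettings()


def make_traj(times, p=None, y1=None, y2=None, z=None) -> Trajectory:
    """Hand-built trajectory for metric unit tests."""
    times = np.asarray(times, dtype=float)
    n = times.size
    cols = [np.zeros(n) if c is None else np.asarray(c, dtype=float) for c in (p, y1, y2, z)]
    return Trajectory(times=times, states=np.column_stack(cols), params=ParameterSet(), settings=SETTINGS)


def brute_force_peaks(t, v, floor=1e-6):
    """Independent reference: scan every interior sample."""
    out = []
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= floor:
            out.append(t[i])
    return out


class TestFindPeaks:
    def test_constant_series_has_no_peaks(self):
        traj = make_traj(np.arange(50) * 0.1, p=np.full(50, 2.0))
        assert len(find_peaks(traj, "p")) == 0

    def test_sine_two_peaks_at_analytic_maxima(self):
        t = np.arange(0.0, 4 * np.pi, 0.1)
        traj = make_traj(t, p=np.sin(t) + 1.0)  # shift above the floor
        peaks = find_peaks(traj, "p")
        assert len(peaks) == 2
        assert peaks.times == pytest.approx([np.pi / 2, 5 * np.pi / 2], abs=0.01)
        assert peaks.values == pytest.approx([2.0, 2.0], abs=1e-3)

    def test_agrees_with_brute_force_on_random_smooth_signals(self, rng):
        t = np.linspace(0.0, 20.0, 400)
        for _ in range(200):
            coeffs = rng.normal(size=4)
            freqs = rng.uniform(0.3, 2.0, size=4)
            phases = rng.uniform(0, 2 * np.pi, size=4)
            v = 2.0 + np.sum(
                [c * np.sin(2 * np.pi * f * t + ph) for c, f, ph in zip(coeffs, freqs, phases)],
                axis=0,
            )
            traj = make_traj(t, p=np.clip(v, 0.0, None))
            got = find_peaks(traj, "p", refine=False).times
            assert list(got) == pytest.approx(brute_force_peaks(t, np.clip(v, 0.0, None)))

    def test_plateau_counted_once_at_midpoint(self):
        v = np.array([0.0, 1.0, 3.0, 3.0, 3.0, 1.0, 0.0, 2.0, 0.0])
        traj = make_traj(np.arange(9.0), p=v)
        peaks = find_peaks(traj, "p", refine=False)
        assert list(peaks.times) == [3.0, 7.0]

    def test_endpoints_never_peaks(self):
        traj = make_traj(np.arange(5.0), p=[5.0, 1.0, 0.5, 1.0, 6.0])
        assert len(find_peaks(traj, "p")) == 0

    def test_floor_suppresses_solver_ripple(self):
        v = np.array([0.0, 1e-8, 0.0, 1.0, 0.0])
        traj = make_traj(np.arange(5.0), p=v)
        assert list(find_peaks(traj, "p", refine=False).times) == [3.0]

    def test_refinement_beats_sampling_resolution(self):
        # parabola peaking between samples: refinement must recover it
        t = np.arange(0.0, 2.0, 0.1)
        v = 1.0 - (t - 0.9500001) ** 2
        traj = make_traj(t, p=v)
        peaks = find_peaks(traj, "p")
        assert peaks.times[0] == pytest.approx(0.95, abs=1e-4)
        assert peaks.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_unknown_species_rejected(self, traj_default_1000):
        with pytest.raises(ValueError, match="unknown species"):
            find_peaks(traj_default_1000, "q")

    def test_cycle_peak_order_y1_then_y2_then_z(self, traj_default_1000):
        """Within one late cycle of the default contest the active form
        peaks first, the dormant form next, the predator last."""
        window = (traj_default_1000.times >= 400) & (traj_default_1000.times <= 450)
        sub = Trajectory(
            times=traj_default_1000.times[window],
            states=traj_default_1000.states[window],
            params=traj_default_1000.params,
            settings=traj_default_1000.settings,
        )
        z_peaks = find_peaks(sub, "z", floor=1e-3)
        y1_peaks = find_peaks(sub, "y1", floor=1e-3)
        y2_peaks = find_peaks(sub, "y2", floor=1e-3)
        assert len(z_peaks) == 1
        assert len(y1_peaks) == 1
        # y2 rises in two humps (reproduction slows, then dormancy influx
        # surges as predators climb); its dominant peak sits between the
        # y1 and z peaks
        y2_main = y2_peaks.times[np.argmax(y2_peaks.values)]
        assert y1_peaks.times[0] < y2_main < z_peaks.times[0]


class TestExtinctionTime:
    def test_never_below_threshold_is_absent(self):
        traj = make_traj(np.arange(10.0), p=np.full(10, 2.0))
        assert extinction_time(traj, "p") is None

    def test_transient_dips_do_not_count(self):
        v = [2.0, 1e-5, 2.0, 1e-5, 1e-5, 1e-5]
        traj = make_traj(np.arange(6.0), p=v)
        assert extinction_time(traj, "p") == 3.0

    def test_monotone_in_threshold(self, traj_default_1000):
        # a larger threshold never yields a later extinction time
        times = []
        for th in (1e-4, 1e-3, 1e-2, 1e-1):
            t = extinction_time(traj_default_1000, "p", threshold=th)
            times.append(np.inf if t is None else t)
        assert all(a >= b for a, b in zip(times, times[1:]))

    def test_threshold_must_be_positive(self, traj_default_1000):
        with pytest.raises(ValueError):
            extinction_time(traj_default_1000, "p", threshold=0.0)

    def test_single_form_contest_loses_by_day_40(self, traj_fig1a):
        # active-form-only dormitive prey goes extinct around t = 40
        t_ext = extinction_time(traj_fig1a, "y1")
        assert t_ext is not None
        assert round(t_ext, -1) == 40

    def test_default_contest_pa_extinction(self, traj_default_1000):
        # permanent sub-threshold phase of the PA prey at the reference
        # parameters starts at t = 420.6 (a last small recovery bump at
        # t ~ 416 postpones it past the final large peak at t ~ 369)
        t_ext = extinction_time(traj_default_1000, "p")
        assert t_ext == pytest.approx(420.6, abs=1.0)


class TestReversalTime:
    def test_pairing_rule_on_synthetic_peaks(self):
        # y1 peaks at t=2 (below the preceding p peak) and t=6 (above it):
        # the reversal is the second one
        t = np.arange(0.0, 9.0, 1.0)
        p = [0.0, 3.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        y1 = [0.0, 0.0, 2.5, 0.0, 0.0, 0.0, 2.8, 0.0, 0.0]
        traj = make_traj(t, p=p, y1=y1)
        assert reversal_time(traj) == pytest.approx(6.0)

    def test_y1_peaks_before_any_pa_peak_are_skipped(self):
        t = np.arange(0.0, 8.0, 1.0)
        p = [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0]
        y1 = [0.0, 5.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0]
        traj = make_traj(t, p=p, y1=y1)
        assert reversal_time(traj) == pytest.approx(6.0)

    def test_no_reversal_is_absent(self):
        t = np.arange(0.0, 6.0, 1.0)
        traj = make_traj(t, p=[0, 4, 0, 4, 0, 4], y1=[0, 1, 0, 1, 0, 1])
        assert reversal_time(traj) is None

    def test_reference_values_at_k13_and_k20(self, traj_k13, traj_k20):
        # the dormitive prey overtakes at T_w = 195.1 for K = 13 and
        # T_w = 89.2 for K = 20
        assert reversal_time(traj_k13) == pytest.approx(195.1, abs=5.0)
        assert reversal_time(traj_k20) == pytest.approx(89.2, abs=5.0)

    def test_absent_at_low_capacity(self, traj_k9_3000):
        assert reversal_time(traj_k9_3000) is None

    def test_reversal_and_winner_co_occur(self, traj_k9_3000, traj_default_3000):
        # no reversal <-> PA wins; reversal <-> dormitive wins
        assert reversal_time(traj_k9_3000) is None
        assert classify_winner(traj_k9_3000).winner == "PA"
        assert reversal_time(traj_default_3000) is not None
        assert classify_winner(traj_default_3000).winner == "dormitive"


class TestClassifyWinner:
    def test_default_contest_goes_to_dormitive_prey(self, traj_default_3000):
        out = classify_winner(traj_default_3000)
        assert out.winner == "dormitive"
        assert out.y1_max > out.pa_max

    def test_both_extinct_is_none(self):
        t = np.arange(0.0, 11.0)
        traj = make_traj(t)
        assert classify_winner(traj, window=(5.0, 10.0)).winner == "none"

    def test_exact_tie_is_none(self):
        t = np.arange(0.0, 11.0)
        traj = make_traj(t, p=np.full(11, 2.0), y1=np.full(11, 2.0))
        assert classify_winner(traj, window=(5.0, 10.0)).winner == "none"

    def test_window_outside_span_rejected(self, traj_default_1000):
        with pytest.raises(ValueError, match="window"):
            classify_winner(traj_default_1000, window=(900.0, 1100.0))


class TestReversalCurve:
    def test_shortens_with_capacity_then_plateaus(self, defaults):
        """Richer environments flip the contest sooner: T_w(13) > T_w(20),
        no reversal at K = 9, and a high-K plateau."""
        curve = dict(reversal_curve(defaults, K_values=(9.0, 13.0, 20.0, 25.0, 30.0)))
        assert curve[9.0] is None
        assert curve[13.0] > curve[20.0]
        assert abs(curve[25.0] - curve[30.0]) / curve[30.0] < 0.10

    def test_rejects_nonpositive_capacity(self, defaults):
        with pytest.raises(ValueError):
            reversal_curve(defaults, K_values=(0.0,))
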