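"""Concentration profiles, protocol timings and master-equation integration."""

import numpy as np
import pytest

import p2x3kin as pk
from p2x3kin.protocols import ConcentrationProfile, make_time_grid, peak_amplitude


class TestConcentrationProfile:
    def test_zero_tau_gives_rectangular_steps(self):
        prof = ConcentrationProfile(((1.0, 10.0), (3.0, 0.0)), tau=0.0)
        assert prof.value(0.5) == 0.0
        assert prof.value(1.0) == 10.0
        assert prof.value(2.999) == 10.0
        assert prof.value(3.0) == 0.0

    def test_single_exponential_wash_in(self):
        prof = ConcentrationProfile(((0.0, 10.0),), tau=0.05)
        assert prof.value(0.05) == pytest.approx(10.0 * (1 - np.exp(-1)))
        assert prof.value(0.0) == pytest.approx(0.0)
        assert prof.value(1.0) == pytest.approx(10.0, rel=1e-8)

    def test_continuity_across_consecutive_switches(self):
        prof = ConcentrationProfile(((0.0, 10.0), (0.08, 2.0)), tau=0.05)
        # value approached from the first segment at the switch instant
        c_left = 10.0 + (0.0 - 10.0) * np.exp(-0.08 / 0.05)
        assert prof.value(0.08) == pytest.approx(c_left)
        eps = 1e-9
        assert prof.value(0.08 + eps) == pytest.approx(c_left, rel=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ConcentrationProfile(((1.0, 1.0), (1.0, 0.0)))
        with pytest.raises(ValueError, match="non-negative"):
            ConcentrationProfile(((0.0, -1.0),))

    def test_concentration_at_wrapper(self):
        prof = ConcentrationProfile(((0.0, 10.0),), tau=0.05)
        assert pk.concentration_at(prof, 0.05) == pytest.approx(6.321, abs=1e-3)


class TestProtocolTimings:
    def test_steady_state_pulse_schedule(self):
        prot = pk.make_steady_state_protocol(10.0, 0.03)
        on_times = [t for t, c in prot.agonist_profile.steps if c > 0]
        off_times = [t for t, c in prot.agonist_profile.steps if c == 0]
        assert on_times == [28.0, 32.0, 94.0]
        assert all(off - on == pytest.approx(2.0) for on, off in zip(on_times, off_times))
        # 2-s and 60-s gaps between consecutive pulses
        assert on_times[1] - off_times[0] == pytest.approx(2.0)
        assert on_times[2] - off_times[1] == pytest.approx(60.0)
        assert prot.antagonist_profile.steps[0] == (0.0, 0.03)

    def test_steady_state_control_run_has_no_antagonist(self):
        prot = pk.make_steady_state_protocol(10.0, 0.0)
        assert prot.antagonist_profile.max_target == 0.0

    def test_washout_delay_schedule(self):
        prot = pk.make_washout_protocol(10.0, 0.03, delay=15.0)
        assert prot.antagonist_profile.steps == ((0.0, 0.03), (20.0, 0.0))
        ag_on, ag_off = prot.agonist_profile.steps
        assert ag_on == (35.0, 10.0)
        assert ag_off[0] - ag_on[0] == pytest.approx(10.0)
        # zero delay: agonist starts the instant the antagonist target drops
        prot0 = pk.make_washout_protocol(10.0, 0.03, delay=0.0)
        assert prot0.agonist_profile.steps[0][0] == pytest.approx(20.0)

    def test_dynamic_pulse_train(self):
        prot = pk.make_dynamic_protocol(10.0, 0.03)
        on_times = [t for t, c in prot.agonist_profile.steps if c > 0]
        assert len(on_times) == 25
        assert np.allclose(np.diff(on_times), 60.0)
        b_on, b_off = prot.antagonist_profile.steps
        assert b_on[0] == pytest.approx(7 * 60.0)       # start of 8th pulse
        assert b_off[0] == pytest.approx(12 * 60.0 + 1)  # end of 13th pulse

    def test_protection_points(self):
        prot = pk.make_protection_protocol(10.0, 400.0)
        on_times = [t for t, c in prot.agonist_profile.steps if c > 0]
        assert on_times == [0.0, 300.0, 600.0, 900.0, 1200.0, 1800.0]  # S1-S5, S7
        ant_on = [t for t, c in prot.antagonist_profile.steps if c > 0]
        assert ant_on == [602.0, 1500.0]  # right after S3; at S6
        assert len(prot.sweeps) == 6

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pk.make_steady_state_protocol(-1.0, 0.0)


class TestSimulation:
    def test_zero_concentrations_leave_occupancy_constant(self, wt):
        prot = pk.make_steady_state_protocol(0.0, 0.0)
        t, P = pk.simulate_occupancy(wt, prot, np.linspace(0, 100, 50))
        assert np.allclose(P[:, 0], 1.0, atol=1e-9)

    def test_probability_conserved_during_agonist_pulse(self, wt):
        prot = pk.make_washout_protocol(10.0, 0.03, delay=0.0)
        t, P = pk.simulate_occupancy(wt, prot)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-6
        assert P.min() > -1e-9

    def test_desensitization_off_plateau_matches_equilibrium(self, wt):
        """Without desensitization the open probability rises to the
        stationary value of the generator at the applied concentration."""
        prof = ConcentrationProfile(((0.0, 10.0),), tau=0.0)
        prot = pk.ApplicationProtocol("step", prof,
                                      ConcentrationProfile((), tau=0.0),
                                      ((0.0, 5.0),), 5.0, 10.0, 0.0)
        t, P = pk.simulate_occupancy(wt, prot, np.linspace(0, 5, 200),
                                     desensitization_on=False)
        po = pk.protocols.open_probability(P)
        gm = pk.build_generator(wt, 10.0, 0.0, desensitization_on=False)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = pk.equilibrium_distribution(gm)
        eq_open = pk.protocols.open_probability(eq[None, :])[0]
        assert po[-1] == pytest.approx(eq_open, rel=1e-6)
        # monotone rise to the plateau (no desensitization, no overshoot)
        assert np.all(np.diff(po) > -1e-9)

    def test_desensitization_on_peaks_then_decays(self, wt):
        prof = ConcentrationProfile(((0.0, 10.0),), tau=0.0)
        prot = pk.ApplicationProtocol("step", prof,
                                      ConcentrationProfile((), tau=0.0),
                                      ((0.0, 10.0),), 10.0, 10.0, 0.0)
        t, P = pk.simulate_occupancy(wt, prot, np.linspace(0, 10, 400))
        po = pk.protocols.open_probability(P)
        i_peak = np.argmax(po)
        assert 0 < i_peak < po.size - 1
        assert po[-1] < 0.1 * po[i_peak]
        # receptors end up desensitized
        desens = P[-1, [i for i, s in enumerate(pk.enumerate_states())
                        if s.mode == "desensitized"]].sum()
        assert desens > 0.8

    def test_rectangular_limit_matches_matrix_exponential(self, wt):
        """τ→0 integration agrees with piecewise-constant expm propagation."""
        from scipy.linalg import expm

        prof = ConcentrationProfile(((0.0, 10.0), (1.0, 0.0)), tau=0.0)
        prot = pk.ApplicationProtocol("step", prof,
                                      ConcentrationProfile((), tau=0.0),
                                      ((0.0, 2.0),), 2.0, 10.0, 0.0)
        grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        t, P = pk.simulate_occupancy(wt, prot, grid)
        parts = pk.build_generator_parts(wt)
        p0 = np.zeros(23)
        p0[0] = 1.0
        QT_on = parts.at(10.0, 0.0).T
        QT_off = parts.at(0.0, 0.0).T
        exact = {
            0.5: expm(QT_on * 0.5) @ p0,
            1.0: expm(QT_on * 1.0) @ p0,
        }
        exact[1.5] = expm(QT_off * 0.5) @ exact[1.0]
        exact[2.0] = expm(QT_off * 1.0) @ exact[1.0]
        for i, tt in enumerate(grid[1:], start=1):
            assert np.abs(P[i] - exact[tt]).max() < 1e-7

    def test_protocol_neutrality_without_antagonist(self, wt):
        """Zero-antagonist steady-state runs are identical across 'levels'."""
        grid = None
        refs = []
        for _ in range(2):
            prot = pk.make_steady_state_protocol(10.0, 0.0)
            if grid is None:
                grid = make_time_grid(prot, 200.0)
            t, P = pk.simulate_occupancy(wt, prot, grid)
            refs.append(P)
        assert np.array_equal(refs[0], refs[1])

    def test_sequence_carries_state_across_runs(self, wt):
        prots = [pk.make_steady_state_protocol(10.0, 0.0) for _ in range(2)]
        grids = [make_time_grid(p, 100.0) for p in prots]
        res = pk.simulate_protocol_sequence(wt, prots, t_grids=grids, gap=300.0)
        peaks = [pk.sweep_peaks(pk.occupancy_to_current(t, P, 1.0), pr.sweeps)[0]
                 for (t, P), pr in zip(res, prots)]
        # 5 min is not enough for complete recovery: second run is smaller
        assert peaks[1] < peaks[0]
        assert peaks[1] > 0.1 * peaks[0]


class TestCurrentReadout:
    def test_zero_open_occupancy_gives_flat_zero(self):
        P = np.zeros((5, 23))
        P[:, 0] = 1.0
        tr = pk.occupancy_to_current(np.arange(5.0), P, 2.0)
        assert np.all(tr.I == 0)

    def test_scale_linearity_and_sign(self, wt):
        prot = pk.make_washout_protocol(10.0, 0.0, delay=0.0)
        t, P = pk.simulate_occupancy(wt, prot, make_time_grid(prot, 200.0))
        tr1 = pk.occupancy_to_current(t, P, 1.0)
        tr2 = pk.occupancy_to_current(t, P, 2.0)
        assert np.allclose(tr2.I, 2.0 * tr1.I)
        assert tr1.I.min() < 0  # inward current is negative

    def test_peak_equals_scale_times_max_open_probability(self, wt):
        prot = pk.make_washout_protocol(10.0, 0.0, delay=0.0)
        t, P = pk.simulate_occupancy(wt, prot, make_time_grid(prot, 500.0))
        tr = pk.occupancy_to_current(t, P, 3.0)
        w = prot.sweeps[0]
        mask = (t >= w[0]) & (t <= w[1])
        assert peak_amplitude(tr, w) == pytest.approx(
            3.0 * pk.protocols.open_probability(P)[mask].max()
        )

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            pk.CurrentTrace(np.array([0.0, 1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            pk.CurrentTrace(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
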