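"""Mass-action ODE and stochastic simulators against the closed form."""

import numpy as np
import pytest

from mase import (
    ExchangePoint,
    LysateComposition,
    LysateLabel,
    MixingProtocol,
    RateConstants,
    SimulationError,
    Trajectory,
    extract_R,
    predict_R,
    simulate_exchange,
    simulate_exchange_stochastic,
    stochastic_ensemble_R,
    verify_propositions,
)


def curve(traj):
    return np.array([p.R for p in extract_R(traj)])


class TestDeterministic:
    def test_matches_closed_form(self, equivalent_protocol, hour_grid):
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-4), hour_grid)
        assert np.max(np.abs(curve(traj) - predict_R(1e-4, hour_grid))) < 1e-6

    def test_mass_conservation(self, equivalent_protocol, hour_grid):
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-4), hour_grid)
        dev_a, dev_b = traj.conservation_deviation()
        assert dev_a < 1e-8 and dev_b < 1e-8

    def test_extract_R_zero_at_mixing_and_equilibrium(self, equivalent_protocol):
        t = np.arange(0.0, 7201.0, 600.0)
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-3), t)
        pts = extract_R(traj)
        assert pts[0].R == 0.0
        assert round(pts[-1].R, 2) == 1.00  # fast complex equilibrated by 2 h
        R = [p.R for p in pts]
        assert all(b >= a - 1e-12 for a, b in zip(R, R[1:]))  # monotone

    def test_dilution_cancels_out(self, hour_grid):
        rates = RateConstants(1e6, 1e-4)
        base = simulate_exchange(MixingProtocol.equivalent(1.0), rates, hour_grid)
        half = simulate_exchange(MixingProtocol.equivalent(0.5), rates, hour_grid)
        assert np.max(np.abs(curve(base) - curve(half))) < 1e-8

    def test_label_and_tag_symmetry(self, equivalent_protocol, hour_grid):
        # Tagging subunit B instead of A tracks [A_L.B_U]/[A_TU.B_U]:
        # same progress curve by symmetry of equivalent lysates.
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-4), hour_grid)
        r_tag_a = curve(traj)
        r_tag_b = traj.species("A_L_B_U") / traj.species("A_TU_B_U")
        assert np.max(np.abs(r_tag_a - r_tag_b)) < 1e-9

    def test_invariant_under_tolerance_tightening(self, equivalent_protocol, hour_grid):
        rates = RateConstants(1e6, 1e-4)
        loose = simulate_exchange(equivalent_protocol, rates, hour_grid,
                                  rtol=1e-9, atol=1e-12)
        tight = simulate_exchange(equivalent_protocol, rates, hour_grid,
                                  rtol=1e-10, atol=1e-13)
        assert np.max(np.abs(curve(loose) - curve(tight))) < 1e-8

    def test_unequilibrated_start_runs_and_conserves(self, hour_grid):
        protocol = MixingProtocol.equivalent(1.0, equilibrate=False)
        traj = simulate_exchange(protocol, RateConstants(1e6, 1e-4), hour_grid)
        dev_a, dev_b = traj.conservation_deviation()
        assert dev_a < 1e-8 and dev_b < 1e-8

    def test_grid_must_start_at_zero(self, equivalent_protocol):
        with pytest.raises(ValueError):
            simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-4),
                              [100.0, 200.0])


class TestPropositions:
    def test_equivalent_lysates_pass(self, equivalent_protocol):
        k_off = 1e-4
        t = np.linspace(0.0, 15.0 / k_off, 31)
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, k_off), t)
        rep = verify_propositions(traj, tol=1e-5)
        assert rep.free_subunits_constant
        assert rep.tagged_total_constant
        assert rep.equilibrium_reached is True

    def test_unequal_b_breaks_free_subunit_constancy(self, unequal_b_protocol):
        k_off = 1e-4
        t = np.linspace(0.0, 15.0 / k_off, 31)
        traj = simulate_exchange(unequal_b_protocol, RateConstants(1e6, k_off), t)
        rep = verify_propositions(traj, tol=1e-5)
        assert not rep.free_subunits_constant
        # final ratio no longer relaxes to 1
        assert abs(extract_R(traj)[-1].R - 1.0) > 0.1

    def test_short_horizon_reported_not_assessed(self, equivalent_protocol):
        k_off = 1e-5
        t = np.linspace(0.0, 0.5 / k_off, 11)
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, k_off), t)
        rep = verify_propositions(traj, tol=1e-5)
        assert rep.equilibrium_reached is None
        assert rep.horizon < rep.required_horizon
        assert "not yet assessable" in rep.summary()


class TestStochastic:
    def test_same_seed_identical_trajectory(self, equivalent_protocol):
        rates = RateConstants(0.01, 1e-3)
        vs = 1000.0 / equivalent_protocol.initial_state(rates)[4]
        t = np.array([0.0, 600.0, 1800.0, 3600.0])
        a = simulate_exchange_stochastic(equivalent_protocol, rates, vs, t, seed=7)
        b = simulate_exchange_stochastic(equivalent_protocol, rates, vs, t, seed=7)
        assert np.array_equal(a.conc, b.conc)
        c = simulate_exchange_stochastic(equivalent_protocol, rates, vs, t, seed=8)
        assert not np.array_equal(a.conc, c.conc)

    def test_copy_number_conservation_exact(self, equivalent_protocol):
        rates = RateConstants(0.01, 1e-3)
        vs = 500.0 / equivalent_protocol.initial_state(rates)[4]
        t = np.linspace(0.0, 3600.0, 13)
        traj = simulate_exchange_stochastic(equivalent_protocol, rates, vs, t, seed=3)
        assert np.all(traj.total_A() == traj.total_A()[0])
        assert np.all(traj.total_B() == traj.total_B()[0])
        assert np.all(traj.conc == np.rint(traj.conc))  # integer copies

    def test_zero_tagged_complex_rejected(self, equivalent_protocol):
        rates = RateConstants(0.01, 1e-3)
        with pytest.raises(ValueError, match="tagged complex"):
            simulate_exchange_stochastic(equivalent_protocol, rates, 0.5,
                                         np.array([0.0, 10.0]), seed=1)

    def test_ensemble_mean_tracks_closed_form(self, equivalent_protocol):
        # light version of the consistency study: 40 replicates, 3 points
        rates = RateConstants(0.01, 1e-3)
        vs = 1000.0 / equivalent_protocol.initial_state(rates)[4]
        t = np.array([0.0, 1800.0, 3600.0, 7200.0])
        mean, se, _ = stochastic_ensemble_R(equivalent_protocol, rates, vs, t,
                                            n_rep=40, seed=11)
        z = np.abs(mean[1:] - predict_R(1e-3, t[1:])) / se[1:]
        assert np.max(z) < 4.0


class TestTrajectoryContainer:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0]), np.zeros((2, 8)))

    def test_tidy_export_shape(self, equivalent_protocol):
        t = np.array([0.0, 100.0, 200.0])
        traj = simulate_exchange(equivalent_protocol, RateConstants(1e6, 1e-4), t)
        df = traj.to_frame()
        assert list(df.columns) == ["t_seconds", "species", "concentration"]
        assert len(df) == 3 * 8
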