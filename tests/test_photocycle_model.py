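"""Photocycle kinetics: analytic populations, predicted DAS, transient
occupancy (the kinetic-invisibility argument) and the blue-light shunt."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

import prflash as pf
from conftest import TRUE_LIFETIMES, chain_scheme, two_state_scheme


class TestSpectralBand:
    def test_peak_value_and_fwhm(self):
        band = pf.SpectralBand(524.0, 100.0, 50_000.0)
        assert band.extinction([524.0])[0] == pytest.approx(50_000.0)
        np.testing.assert_allclose(band.extinction([474.0, 574.0]), 25_000.0, rtol=1e-12)

    def test_skew_shifts_half_maximum_points(self):
        band = pf.SpectralBand(500.0, 100.0, 1.0, skew=0.5)
        # blue half-width 25 nm, red half-width 75 nm
        assert band.extinction([475.0])[0] == pytest.approx(0.5)
        assert band.extinction([575.0])[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("kwargs", [
        dict(center=-1, width=10, peak_extinction=1),
        dict(center=500, width=0, peak_extinction=1),
        dict(center=500, width=10, peak_extinction=-1),
        dict(center=500, width=10, peak_extinction=1, skew=1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pf.SpectralBand(**kwargs)


class TestSchemeValidation:
    def test_mass_conserving_diagonal_enforced(self):
        states = two_state_scheme(1.0).states
        K = np.array([[-1.0, 0.0], [0.5, 0.0]])  # column does not conserve
        with pytest.raises(ValueError, match="column sum"):
            pf.PhotocycleScheme(states, K, np.array([1.0, 0.0]))

    def test_exactly_one_ground_state(self):
        s = two_state_scheme(1.0)
        states = [pf.PhotocycleState(st.name, st.band, True) for st in s.states]
        with pytest.raises(ValueError, match="ground"):
            pf.PhotocycleScheme(states, s.rate_matrix, s.initial_populations)


class TestSimulatePopulations:
    def test_zero_rate_state_is_constant(self):
        traj = pf.simulate_populations(two_state_scheme(0.0), np.linspace(0, 10, 7))
        np.testing.assert_allclose(traj["E"], 1.0, atol=1e-12)

    def test_equal_rate_chain_closed_form(self):
        # A -> B -> C with k1 = k2 = k is the textbook k*t*exp(-k*t), but an
        # exactly defective matrix is rejected; perturbing k2 by 1e-9
        # reproduces the closed form to ~1e-8.
        k = 100.0
        scheme = chain_scheme(k, k * (1 + 1e-9))
        t = np.linspace(0, 5 / k, 50)
        traj = pf.simulate_populations(scheme, t)
        np.testing.assert_allclose(traj["B"], k * t * np.exp(-k * t), atol=1e-6)
        assert traj["B"].max() == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_exactly_defective_matrix_rejected(self):
        with pytest.raises(ValueError, match="diagonalizable"):
            pf.simulate_populations(chain_scheme(100.0, 100.0), [0.0, 0.01])

    def test_default_scheme_matches_ode_oracle(self, default_scheme):
        times = np.logspace(-7, 0, 60)
        traj = pf.simulate_populations(default_scheme, times)
        sol = solve_ivp(
            lambda t, y: default_scheme.rate_matrix @ y,
            (0.0, times[-1]),
            default_scheme.initial_populations,
            t_eval=times, rtol=1e-10, atol=1e-13, method="LSODA",
        )
        assert np.abs(sol.y - traj.populations).max() < 1e-8

    def test_mass_conserved_and_populations_in_range(self, default_scheme):
        traj = pf.simulate_populations(default_scheme, np.logspace(-8, 1, 200))
        np.testing.assert_allclose(traj.populations.sum(axis=0), 1.0, atol=1e-10)
        assert traj.populations.min() > -1e-12
        assert traj.populations.max() < 1 + 1e-12


class TestPredictDas:
    def test_single_intermediate_das_is_delta_extinction(self):
        scheme = two_state_scheme(10.0)
        taus, das = pf.predict_das(
            scheme, [560.0], excited_fraction=1.0, concentration=1.0, pathlength=1.0
        )
        expected = scheme.delta_extinction([560.0])[0, 0]
        assert taus[0] == pytest.approx(0.1)
        assert das[0, 0] == pytest.approx(expected)

    def test_default_scheme_yields_the_four_lifetimes(self, default_scheme):
        taus, das = pf.predict_das(default_scheme, pf.PROBE_WAVELENGTHS)
        np.testing.assert_allclose(taus, TRUE_LIFETIMES, rtol=1e-9)
        assert das.shape == (4, 14)

    def test_das_sum_reconstructs_initial_bleach(self, default_scheme):
        # at t -> 0+ only P1 is populated: sum of DAS = scaled delta-eps of P1
        wl = np.array(pf.PROBE_WAVELENGTHS, dtype=float)
        taus, das = pf.predict_das(default_scheme, wl)
        expected = pf.noiseless_delta_absorbance(default_scheme, wl, [0.0])[:, 0]
        np.testing.assert_allclose(das.sum(axis=0), expected, rtol=1e-8)

    def test_three_state_roundtrip_with_global_fit(self):
        scheme = chain_scheme(1e4, 50.0)
        wl = np.array(pf.PROBE_WAVELENGTHS, dtype=float)
        taus_pred, das_pred = pf.predict_das(scheme, wl)
        acq = pf.AcquisitionConfig(seed=0, noise_sd=0.0, n_samples_per_scope=4096)
        fast, slow = pf.make_photocycle_dataset(scheme, acq)
        merged = pf.merge_traces(pf.reduce_log_blocks(fast), pf.reduce_log_blocks(slow))
        res = pf.fit_global(merged, 2)
        np.testing.assert_allclose(res.lifetimes, taus_pred, rtol=1e-3)
        np.testing.assert_allclose(res.das, das_pred, atol=5e-3 * np.abs(das_pred).max())


class TestMaxTransientOccupancy:
    def test_fast_formation_limit_approaches_one(self):
        assert pf.max_transient_occupancy(1e6, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_matched_rates_give_one_over_e(self):
        assert pf.max_transient_occupancy(2.0, 2.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_decay_twice_formation_gives_quarter(self):
        assert pf.max_transient_occupancy(1.0, 2.0) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("ratio", np.logspace(-3, 3, 13).tolist())
    def test_matches_simulated_peak_over_rate_ratios(self, ratio):
        k1, k2 = 100.0 * ratio, 100.0
        if abs(k1 - k2) < 1e-9:
            k2 *= 1 + 1e-7  # keep the matrix numerically diagonalizable
        scheme = chain_scheme(k1, k2)

        def neg_b(t):
            return -pf.simulate_populations(scheme, [t]).populations[1, 0]

        t_scale = 1.0 / min(k1, k2)
        peak = -minimize_scalar(neg_b, bounds=(1e-9 * t_scale, 50 * t_scale),
                                method="bounded", options={"xatol": 1e-14}).fun
        assert pf.max_transient_occupancy(k1, k2) == pytest.approx(peak, abs=1e-6)

    def test_rejects_non_positive_rates(self):
        with pytest.raises(ValueError):
            pf.max_transient_occupancy(0.0, 1.0)


class TestSteadyStateCurrent:
    def test_no_blue_light_normalizes_to_one(self, default_scheme):
        assert pf.steady_state_current(default_scheme, 10.0, 0.0) == pytest.approx(1.0)

    def test_blue_light_reduces_current(self, default_scheme):
        assert pf.steady_state_current(default_scheme, 10.0, 5e4, 1.0) < 1.0

    def test_monotone_non_increasing_in_blue_rate(self, default_scheme):
        rates = np.logspace(0, 6, 13)
        currents = [pf.steady_state_current(default_scheme, 10.0, b) for b in rates]
        assert np.all(np.diff(currents) < 0)

    def test_two_state_pump_closed_form(self):
        # ground -g-> E, E -b-> ground (pumping); blue shunt s: E -> ground.
        # Photostationary pumped flux b*g/(g+b+s); relative = (g+b)/(g+b+s).
        g, b, s = 3.0, 7.0, 2.0
        scheme = two_state_scheme(b, excited_name="M")
        rel = pf.steady_state_current(scheme, g, s, 1.0)
        assert rel == pytest.approx((g + b) / (g + b + s), abs=1e-10)

    def test_requires_green_excitation(self, default_scheme):
        with pytest.raises(ValueError, match="excitation"):
            pf.steady_state_current(default_scheme, 0.0, 1.0)
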