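"""Unit tests for the Fokker-Planck solvers.

Oracles: the classical first-passage (Siegert) quadrature for the LIF
steady rate, closed-form limits, inter-solver consistency, and the
direct PDE transient for the spectral quantities.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx

from synchrate import (NeuronParams, steady_state, isi_cv, eigenvalue,
                       eigenvalue_lif, eigenvalue_eif, eigenvalue_qif,
                       spiking_linear_response, build_operating_table,
                       calibrate_operating_point, pde_rate_transient,
                       fit_damped_cosine)
from synchrate.fokker_planck import (mean_rate_from_moments,
                                     qif_stationary_fourier)


def siegert_rate_hz(params, mu, sigma):
    """Independent oracle: the LIF mean-first-passage-time double
    integral, reduced to a single integral of exp(u^2)(1+erf u)."""
    sb = sigma * math.sqrt(2.0)  # our convention: stationary variance sigma^2
    lo = (params.v_reset - mu) / sb
    hi = (params.v_th - mu) / sb

    def f(u):
        return 2 * math.exp(u * u) - erfcx(u) if u >= 0 else erfcx(-u)

    t, _ = quad(f, lo, hi, limit=200)
    t *= params.tau_m * math.sqrt(math.pi)
    return 1000.0 / (t + params.tau_ref)


class TestSteadyState:
    @pytest.mark.parametrize("mu,sigma", [(25.0, 2.0), (22.0, 1.0),
                                          (15.0, 4.0), (10.0, 6.0)])
    def test_lif_rate_matches_siegert_integral(self, lif, mu, sigma):
        got = steady_state(lif, mu, sigma).rate_hz
        assert got == pytest.approx(siegert_rate_hz(lif, mu, sigma),
                                    rel=2e-3)

    @pytest.mark.parametrize("kind,mu,sigma", [
        ("lif", 22.0, 2.0), ("eif", 13.0, 1.0), ("eif", 9.0, 4.0),
        ("qif", 6.0, 2.0)])
    def test_density_invariants(self, kind, mu, sigma):
        sol = steady_state(NeuronParams.preset(kind), mu, sigma)
        assert sol.density[-1] == pytest.approx(0.0, abs=1e-12)  # absorbing
        assert np.all(sol.density >= 0)
        assert sol.normalization == pytest.approx(1.0, abs=2e-3)
        # flux equals the rate above the reset, and jumps there
        assert sol.flux[-1] * 1000.0 == pytest.approx(sol.rate_hz)

    def test_rate_agrees_with_first_passage_moments(self, eif):
        r1 = steady_state(eif, 12.0, 1.5).rate_hz
        r2 = mean_rate_from_moments(eif, 12.0, 1.5)
        assert r1 == pytest.approx(r2, rel=2e-3)

    def test_qif_threshold_integration_matches_theta_fourier(self, qif):
        r1 = steady_state(qif, 5.0, 2.0).rate_hz
        _, r2 = qif_stationary_fourier(qif, 5.0, 2.0)
        assert r1 == pytest.approx(r2, rel=2e-3)

    def test_deep_subthreshold_rate_vanishes(self, lif):
        assert steady_state(lif, 8.0, 1.2).rate_hz < 1e-3

    def test_sigma_zero_rejected(self, lif):
        with pytest.raises(ValueError, match="deterministic"):
            steady_state(lif, 25.0, 0.0)

    def test_grid_refinement_converged(self, eif):
        r1 = steady_state(eif, 13.0, 1.0, dv=1 / 16).rate_hz
        r2 = steady_state(eif, 13.0, 1.0, dv=1 / 32).rate_hz
        assert abs(r1 - r2) / r2 < 5e-4


class TestIsiCv:
    def test_mean_dominated_limit_is_clocklike(self, lif):
        assert isi_cv(lif, 30.0, 0.3) < 0.05

    def test_noise_dominated_subthreshold_is_poisson_like(self, lif):
        assert 0.8 < isi_cv(lif, 10.0, 6.0) < 1.2

    def test_cv_increases_with_noise(self, eif):
        cvs = [isi_cv(eif, 13.0, s) for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(cvs, cvs[1:]))


class TestEigenvalues:
    @pytest.mark.parametrize("kind,mu,sigma", [
        ("lif", 25.0, 2.0), ("eif", 13.0, 1.0), ("qif", 10.0, 2.0),
        ("eif", 15.0, 2.0), ("lif", 22.0, 1.0)])
    def test_real_part_negative_everywhere(self, kind, mu, sigma):
        ev = eigenvalue(NeuronParams.preset(kind), mu, sigma)
        assert ev.value.real < 0
        assert ev.value.imag >= 0  # reported with the positive-Im convention

    def test_eif_baseline_oscillates_at_the_firing_rate(self, eif,
                                                        eif_baseline):
        """At the 50 Hz / CV 0.1 baseline, Im(lambda)/2pi sits at the
        firing rate; cross-checked against the PDE-transient oracle."""
        mu, sigma = eif_baseline
        ev = eigenvalue_eif(eif, mu, sigma)
        assert ev.frequency_hz == pytest.approx(50.0, rel=0.10)
        t, r = pde_rate_transient(eif, 0.99 * mu, mu, sigma)
        alpha, omega = fit_damped_cosine(t, r)
        assert omega == pytest.approx(ev.value.imag, rel=0.10)
        assert alpha == pytest.approx(ev.value.real, rel=0.15)

    def test_lif_agrees_with_eif_in_sharpness_limit(self, lif):
        """EIF -> LIF as Delta_T -> 0 with matched threshold and reset."""
        ev_lif = eigenvalue_lif(lif, 25.0, 2.0)
        eif_like = NeuronParams(model_kind="eif", v_th=math.inf,
                                v_reset=10.0, e_l=0.0, v_t=20.0,
                                delta_t=0.01, tau_m=10.0, tau_ref=0.0,
                                v_max=21.0, v_min=-40.0)
        ev = eigenvalue_eif(eif_like, 25.0, 2.0)
        assert ev.value == pytest.approx(ev_lif.value, rel=0.05)

    def test_qif_eigenvalue_always_complex(self, qif):
        for mu in (2.0, 6.0, 12.0):
            for sigma in (1.0, 3.0, 6.0):
                ev = eigenvalue_qif(qif, mu, sigma)
                assert ev.value.imag > 0

    def test_qif_truncation_converged(self, qif):
        a = eigenvalue_qif(qif, 8.0, 2.0, n_fourier=100).value
        b = eigenvalue_qif(qif, 8.0, 2.0, n_fourier=200).value
        assert abs(a - b) / abs(b) < 5e-3

    def test_qif_small_truncation_rejected(self, qif):
        with pytest.raises(ValueError, match="n_fourier"):
            eigenvalue_qif(qif, 8.0, 2.0, n_fourier=8)

    def test_decay_rate_grows_with_noise_at_fixed_rate(self, eif):
        """|Re lambda| increases with CV at (approximately) fixed rate."""
        pts = [calibrate_operating_point(eif, 50.0, cv)
               for cv in (0.1, 0.3, 0.5)]
        res = [-eigenvalue_eif(eif, mu, s).value.real for mu, s in pts]
        assert res[0] < res[1] < res[2]


class TestLinearResponse:
    @pytest.mark.parametrize("kind,mu,sigma", [
        ("lif", 25.0, 2.0), ("eif", 13.0, 1.5), ("qif", 8.0, 2.0)])
    def test_dc_limit_equals_rate_slope(self, kind, mu, sigma):
        p = NeuronParams.preset(kind)
        gain, phase = spiking_linear_response(p, mu, sigma, [1e-3])
        fd = (steady_state(p, mu + 0.05, sigma).rate_hz
              - steady_state(p, mu - 0.05, sigma).rate_hz) / 0.1
        assert gain[0] == pytest.approx(fd, rel=0.01)
        assert phase[0] == pytest.approx(0.0, abs=1e-3)

    def test_eif_low_noise_resonates_at_firing_rate(self, eif,
                                                    eif_baseline):
        mu, sigma = eif_baseline
        freqs = np.arange(30.0, 80.0)
        gain, _ = spiking_linear_response(eif, mu, sigma, freqs)
        k = int(np.argmax(gain))
        assert freqs[k] == pytest.approx(50.0, abs=1.0)
        assert 0 < k < len(freqs) - 1  # a genuine local maximum

    def test_high_noise_resonance_absent(self, eif):
        mu, sigma = calibrate_operating_point(eif, 50.0, 0.7)
        freqs = np.arange(10.0, 120.0, 2.0)
        gain, _ = spiking_linear_response(eif, mu, sigma, freqs)
        # no interior peak above the low-frequency response
        assert gain.max() <= gain[0] * 1.02


class TestOperatingTable:
    def test_interpolation_matches_direct_solve_at_midpoints(self, eif):
        table = build_operating_table(eif, np.linspace(11.0, 15.0, 5),
                                      np.array([0.8, 1.0, 1.2, 1.5]),
                                      with_eigenvalues=False)
        for mu, sg in [(11.5, 0.9), (13.5, 1.1), (14.5, 1.35)]:
            r, cv, _ = table.lookup(mu, sg)
            assert r == pytest.approx(steady_state(eif, mu, sg).rate_hz,
                                      rel=0.01)
            assert cv == pytest.approx(isi_cv(eif, mu, sg), rel=0.02)

    def test_rate_monotone_in_mu_at_fixed_sigma(self, eif_step_table):
        r = eif_step_table.rate_hz
        assert np.all(np.diff(r, axis=0) > 0)

    def test_round_trip_inverse(self, eif_step_table):
        mu, sg = 13.0, 1.0
        r, cv, _ = eif_step_table.lookup(mu, sg)
        mu2, sg2 = eif_step_table.inverse(r, cv)
        assert mu2 == pytest.approx(mu, rel=0.01)
        assert sg2 == pytest.approx(sg, rel=0.01)

    def test_out_of_hull_query_rejected(self, eif_step_table):
        with pytest.raises(ValueError, match="outside"):
            eif_step_table.lookup(100.0, 1.0)

    def test_hdf5_round_trip(self, tmp_path, eif_step_table):
        path = tmp_path / "table.h5"
        eif_step_table.to_hdf5(path)
        from synchrate import OperatingTable
        back = OperatingTable.from_hdf5(path)
        assert np.array_equal(back.rate_hz, eif_step_table.rate_hz)
        assert back.params.model_kind == "eif"


class TestCalibration:
    @pytest.mark.parametrize("kind", ["lif", "qif", "eif"])
    def test_baseline_calibration_verifies_by_direct_solvers(self, kind):
        p = NeuronParams.preset(kind)
        mu, sigma = calibrate_operating_point(p, 50.0, 0.1)
        assert steady_state(p, mu, sigma).rate_hz == pytest.approx(50.0,
                                                                   rel=5e-3)
        assert isi_cv(p, mu, sigma) == pytest.approx(0.1, rel=5e-3)

    def test_table_node_recovered(self, eif, eif_step_table):
        r, cv, _ = eif_step_table.lookup(13.0, 1.0)
        mu, sigma = calibrate_operating_point(eif, r, cv,
                                              table=eif_step_table)
        assert mu == pytest.approx(13.0, abs=0.05)
        assert sigma == pytest.approx(1.0, abs=0.02)

    def test_unreachable_target_rejected(self, eif):
        with pytest.raises(ValueError, match="unreachable|hull"):
            calibrate_operating_point(eif, 2000.0, 0.01)
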