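"""Unit tests for the excitatory-inhibitory network (spiking and rate)."""

import numpy as np
import pytest

from synchrate import (NeuronParams, NetworkWeights, build_spiking_network,
                       simulate_spiking_network, coupled_drive,
                       simulate_rate_network, find_fixed_point, stability_at,
                       scan_stability_map, oscillation_verdict,
                       measure_synaptic_input, LambdaFit)


@pytest.fixture(scope="module")
def baseline_external(eif_baseline):
    return eif_baseline  # (mu_x, sigma_x) for 50 Hz / CV 0.1


class TestConnectivity:
    def test_in_degree_is_a_point_mass_at_k(self):
        w = NetworkWeights.from_scan(0.2, 0.2, k=20, n_e=120, n_i=120)
        conn = build_spiking_network(w, seed=0)
        deg_e, deg_i = conn.in_degrees()
        assert np.all(deg_e == 20) and np.all(deg_i == 20)

    def test_no_self_connections(self):
        w = NetworkWeights.from_scan(0.2, 0.2, k=15, n_e=60, n_i=60)
        conn = build_spiking_network(w, seed=1)
        for src in range(conn.n):
            tgts = conn.out_idx[conn.out_ptr[src]:conn.out_ptr[src + 1]]
            assert src not in tgts

    def test_seeds_give_different_adjacency_same_degrees(self):
        w = NetworkWeights.from_scan(0.2, 0.2, k=10, n_e=50, n_i=50)
        a = build_spiking_network(w, seed=2)
        b = build_spiking_network(w, seed=3)
        assert not np.array_equal(a.out_idx, b.out_idx)
        assert np.all(a.in_degrees()[0] == b.in_degrees()[0])

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError, match="K"):
            NetworkWeights.from_scan(0.1, 0.1, k=100, n_e=50, n_i=50)


class TestCoupledDrive:
    def test_silent_network_leaves_external_drive(self):
        w = NetworkWeights.from_scan(0.3, 0.2, k=100, n_e=1000, n_i=1000)
        d = coupled_drive((0.0, 0.0), w, (12.0, 0.5))
        assert d.mu_e == d.mu_i == 12.0
        assert d.var_e == d.var_i == pytest.approx(0.25)

    def test_recurrent_terms_linear_in_rates(self):
        w = NetworkWeights.from_scan(0.3, 0.2, k=100, n_e=1000, n_i=1000)
        ext = (12.0, 0.5)
        d1 = coupled_drive((30.0, 40.0), w, ext)
        d2 = coupled_drive((60.0, 80.0), w, ext)
        assert d2.mu_e - ext[0] == pytest.approx(2 * (d1.mu_e - ext[0]))
        assert d2.var_i - 0.25 == pytest.approx(2 * (d1.var_i - 0.25))

    def test_inhibition_enters_negatively(self):
        w = NetworkWeights.from_scan(0.0, 0.4, k=100, n_e=1000, n_i=1000)
        d = coupled_drive((0.0, 50.0), w, (10.0, 0.5))
        assert d.mu_e < 10.0 and d.var_e > 0.25

    def test_variances_never_below_external(self):
        w = NetworkWeights.from_scan(0.3, 0.2, k=100, n_e=1000, n_i=1000)
        d = coupled_drive((20.0, 70.0), w, (12.0, 0.5))
        assert d.var_e >= 0.25 and d.var_i >= 0.25

    def test_spiking_network_input_statistics_match_mean_field(
            self, eif, baseline_external):
        """Direct accumulation of synaptic increments reproduces the
        mean-field drive equations within 5%."""
        w = NetworkWeights.from_scan(0.15, 0.3, g=0.5, k=200, n_e=1200,
                                     n_i=1200)
        conn = build_spiking_network(w, seed=4)
        raster, pe, pi = simulate_spiking_network(conn, w, eif,
                                                  baseline_external,
                                                  duration=1200.0, seed=5)
        r_e = pe.rate_hz[300:].mean()
        r_i = pi.rate_hz[300:].mean()
        (me, ve), (mi, vi) = measure_synaptic_input(raster, conn, w, eif,
                                                    (300.0, 1200.0))
        d = coupled_drive((r_e, r_i), w, (0.0, 0.0), eif.tau_m)
        assert me == pytest.approx(d.mu_e, rel=0.05)
        assert mi == pytest.approx(d.mu_i, rel=0.05)
        assert ve == pytest.approx(d.var_e, rel=0.05)
        assert vi == pytest.approx(d.var_i, rel=0.05)


class TestSpikingNetwork:
    def test_zero_weights_recover_uncoupled_baseline(self, eif,
                                                     baseline_external):
        w = NetworkWeights.from_scan(0.0, 0.0, k=50, n_e=600, n_i=600)
        conn = build_spiking_network(w, seed=6)
        _, pe, pi = simulate_spiking_network(conn, w, eif, baseline_external,
                                             duration=2500.0, seed=7)
        for pr in (pe, pi):
            mean = pr.rate_hz[500:].mean()
            se = pr.rate_hz[500:].std() / np.sqrt(len(pr.rate_hz) - 500)
            assert abs(mean - 50.0) < max(3 * se, 0.01 * 50.0 + 3 * se)


class TestRateNetwork:
    def test_zero_weights_settle_at_baseline(self, eif_network_table,
                                             baseline_external):
        w = NetworkWeights.from_scan(0.0, 0.0, k=500)
        se, si = simulate_rate_network(w, baseline_external,
                                       eif_network_table, eif_network_table,
                                       duration=600.0)
        assert se.rate_hz[-1] == pytest.approx(50.0, rel=0.01)
        assert abs(se.imag_hz[-1]) < 0.5

    def test_fixed_point_at_zero_weights_is_baseline(self,
                                                     eif_network_table,
                                                     baseline_external):
        w = NetworkWeights.from_scan(0.0, 0.0, k=500)
        r_e, r_i, drive = find_fixed_point(w, baseline_external,
                                           eif_network_table,
                                           eif_network_table)
        assert r_e == pytest.approx(50.0, rel=0.01)
        assert r_i == pytest.approx(50.0, rel=0.01)
        assert drive.mu_e == pytest.approx(baseline_external[0])

    def test_fixed_point_definition_self_consistent(self, eif_network_table,
                                                    baseline_external):
        w = NetworkWeights.from_scan(0.2, 0.25, k=500)
        r_e, r_i, drive = find_fixed_point(w, baseline_external,
                                           eif_network_table,
                                           eif_network_table)
        r_back, _, _ = eif_network_table.lookup(drive.mu_e, drive.sigma_e)
        assert r_back == pytest.approx(r_e, abs=1e-6)

    def test_decoupled_jacobian_eigenvalues_are_lambda_pair(
            self, eif_network_table, baseline_external):
        w = NetworkWeights.from_scan(0.0, 0.0, k=500)
        fit = LambdaFit()
        ev, stable = stability_at(w, (50.0, 50.0), baseline_external,
                                  eif_network_table, eif_network_table, fit)
        assert stable
        r, cv, _ = eif_network_table.lookup(*baseline_external)
        lam = fit.lam(r, cv)
        got = np.sort_complex(ev)
        want = np.sort_complex(np.array([lam, np.conj(lam)] * 2))
        assert np.allclose(got, want, rtol=0.02)

    def test_stable_cell_average_matches_fixed_point(self,
                                                     eif_network_table,
                                                     baseline_external):
        w = NetworkWeights.from_scan(0.1, 0.2, k=500)
        r_e, r_i, _ = find_fixed_point(w, baseline_external,
                                       eif_network_table, eif_network_table)
        se, si = simulate_rate_network(w, baseline_external,
                                       eif_network_table, eif_network_table,
                                       duration=800.0)
        assert se.rate_hz[4000:].mean() == pytest.approx(r_e, rel=0.01)
        assert si.rate_hz[4000:].mean() == pytest.approx(r_i, rel=0.01)


@pytest.fixture(scope="module")
def small_map(eif_network_table, baseline_external):
    return scan_stability_map(np.arange(0.0, 0.31, 0.05),
                              np.arange(0.0, 0.31, 0.05),
                              baseline_external, eif_network_table,
                              eif_network_table, g=0.5, k=500)


class TestStabilityMap:
    def test_zero_weight_cell_stable(self, small_map):
        assert small_map.stable[0, 0] and not small_map.failed[0, 0]

    def test_pure_excitation_row_entirely_stable(self, small_map):
        assert np.all(small_map.stable[:, 0] & ~small_map.failed[:, 0])

    def test_increasing_excitation_crosses_into_limit_cycle(self, small_map):
        j = 2  # w_i = 0.10
        col_osc = ~small_map.stable[:, j] & ~small_map.failed[:, j]
        assert col_osc.any()
        first = int(np.argmax(col_osc))
        assert np.all(small_map.stable[:first, j])

    def test_verdict_matches_jacobian_sign(self, small_map):
        ok = ~small_map.failed
        assert np.array_equal(small_map.stable[ok],
                              small_map.max_re_eig[ok] < 0)

    def test_csv_export(self, small_map, tmp_path):
        import pandas as pd
        path = tmp_path / "map.csv"
        small_map.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == small_map.stable.size
        assert set(df["verdict"]) <= {"stable", "limit_cycle", "failed"}


class TestOscillationVerdict:
    def test_sine_plus_noise_detected(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 3000.0, 0.5)
        x = 50 + 10 * np.sin(2 * np.pi * 50e-3 * t) \
            + 0.5 * rng.standard_normal(len(t))
        osc, f = oscillation_verdict(x, 0.5)
        assert osc and f == pytest.approx(50.0, abs=2.0)

    def test_pure_noise_not_detected(self):
        rng = np.random.default_rng(12)
        x = 50 + 0.5 * rng.standard_normal(8000)
        osc, _ = oscillation_verdict(x, 0.5)
        assert not osc
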