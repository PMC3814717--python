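"""Coupled excitatory-inhibitory networks: spiking and rate descriptions.

The spiking network is a sparse random network of N_E excitatory and
N_I inhibitory integrate-and-fire neurons.  Every neuron receives
exactly K excitatory and K inhibitory synapses; a presynaptic spike
instantaneously kicks the postsynaptic membrane by J/tau_m mV, where J
(mV*ms) is the integral of the synaptic current.  Synaptic strengths
are J_EE, J_EI (onto excitatory cells) and J_IE, J_II (onto inhibitory
cells); scans parameterize them as w_E = J_EE, w_I = J_EI with the
weights onto inhibitory cells scaled by a fixed ratio g: J_IE = g w_E,
J_II = g w_I.

Under the diffusion approximation the recurrent input adds, per
population a in {E, I},

    mu_a      = mu_x + K (J_aE r_E - J_aI r_I)
    sigma_a^2 = sigma_x^2 + K (J_aE^2 r_E + J_aI^2 r_I) / (2 tau_m)

with rates in 1/ms.  The rate-network twin describes each population by
one complex-valued rate unit whose (r_inf, CV) are looked up from an
operating table at the instantaneous (mu_a, sigma_a) and whose lambda
comes from the universal (r_inf, CV) parameterization.  Stability of
the asynchronous fixed point is decided by the eigenvalues of the 4x4
Jacobian over the real and imaginary parts of the two complex rates;
a positive real part marks the transition to a limit cycle (partial
spike synchronization at roughly the baseline firing rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .neurons import NeuronParams
from .fokker_planck import OperatingTable
from .population_sim import SpikeRaster, estimate_rate
from .rate_models import ComplexRateState, LambdaFit

__all__ = ["NetworkWeights", "CoupledDrive", "StabilityMap",
           "build_spiking_network", "simulate_spiking_network",
           "coupled_drive", "simulate_rate_network", "find_fixed_point",
           "stability_at", "scan_stability_map", "oscillation_verdict",
           "measure_synaptic_input", "Connectivity"]


@dataclass(frozen=True)
class NetworkWeights:
    """Synaptic strengths (mV*ms), in-degree and population sizes."""

    j_ee: float
    j_ei: float
    j_ie: float
    j_ii: float
    k: int = 500
    n_e: int = 5000
    n_i: int = 5000

    def __post_init__(self):
        if min(self.j_ee, self.j_ei, self.j_ie, self.j_ii) < 0:
            raise ValueError("weights are magnitudes; inhibition enters "
                             "with its sign in the drive equations")
        if self.k >= min(self.n_e, self.n_i):
            raise ValueError("in-degree K must be below both population sizes")

    @classmethod
    def from_scan(cls, w_e: float, w_i: float, g: float = 0.5,
                  k: int = 500, n_e: int = 5000, n_i: int = 5000
                  ) -> "NetworkWeights":
        """Scan parameterization: (w_E, w_I) onto excitatory cells, the
        weights onto inhibitory cells scaled by the fixed ratio g."""
        return cls(j_ee=w_e, j_ei=w_i, j_ie=g * w_e, j_ii=g * w_i,
                   k=k, n_e=n_e, n_i=n_i)


@dataclass(frozen=True)
class CoupledDrive:
    """Mean (mV) and variance (mV^2) of the input to each population."""

    mu_e: float
    mu_i: float
    var_e: float
    var_i: float
    mu_x: float
    var_x: float

    @property
    def sigma_e(self) -> float:
        return math.sqrt(self.var_e)

    @property
    def sigma_i(self) -> float:
        return math.sqrt(self.var_i)


def coupled_drive(rates_hz, weights: NetworkWeights, external,
                  tau_m: float = 10.0) -> CoupledDrive:
    """Mean-field input statistics given population rates (Hz).

    ``external`` is (mu_x, sigma_x) in mV.  Means are linear in the
    rates with signed weights; variances add K J^2 r / (2 tau_m) per
    synapse class (Poisson shot noise under the diffusion
    approximation, in the sqrt(2 tau_m) white-noise convention).
    """
    r_e, r_i = (max(float(r), 0.0) / 1000.0 for r in rates_hz)  # 1/ms
    mu_x, sigma_x = external
    w = weights
    mu_e = mu_x + w.k * (w.j_ee * r_e - w.j_ei * r_i)
    mu_i = mu_x + w.k * (w.j_ie * r_e - w.j_ii * r_i)
    var_e = sigma_x ** 2 + w.k * (w.j_ee ** 2 * r_e + w.j_ei ** 2 * r_i) \
        / (2.0 * tau_m)
    var_i = sigma_x ** 2 + w.k * (w.j_ie ** 2 * r_e + w.j_ii ** 2 * r_i) \
        / (2.0 * tau_m)
    return CoupledDrive(mu_e=mu_e, mu_i=mu_i, var_e=var_e, var_i=var_i,
                        mu_x=mu_x, var_x=sigma_x ** 2)


# ----------------------------------------------------------------------
# spiking network
# ----------------------------------------------------------------------

@dataclass
class Connectivity:
    """Fixed in-degree random connectivity in outgoing CSR form."""

    out_ptr: np.ndarray     # len N+1
    out_idx: np.ndarray     # targets, len N*2K (on average)
    n_e: int
    n_i: int
    k: int

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def in_degrees(self):
        """(exc_in_degree, inh_in_degree) per neuron, recomputed from the
        outgoing lists."""
        n = self.n
        deg_e = np.zeros(n, dtype=np.int64)
        deg_i = np.zeros(n, dtype=np.int64)
        for src in range(n):
            tgts = self.out_idx[self.out_ptr[src]:self.out_ptr[src + 1]]
            if src < self.n_e:
                np.add.at(deg_e, tgts, 1)
            else:
                np.add.at(deg_i, tgts, 1)
        return deg_e, deg_i


def build_spiking_network(weights: NetworkWeights, seed: int = 0
                          ) -> Connectivity:
    """Draw K excitatory and K inhibitory presynaptic partners per neuron,
    uniformly without replacement, excluding self-connections."""
    n_e, n_i, k = weights.n_e, weights.n_i, weights.k
    n = n_e + n_i
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE1]))
    # in-lists: sources for each target
    counts = np.zeros(n, dtype=np.int64)  # out-degree per source
    src_lists = np.empty((n, 2 * k), dtype=np.int64)
    for tgt in range(n):
        exc = rng.choice(n_e - 1 if tgt < n_e else n_e, size=k, replace=False)
        if tgt < n_e:
            exc = exc + (exc >= tgt)  # skip self
        inh = rng.choice(n_i - 1 if tgt >= n_e else n_i, size=k,
                         replace=False)
        if tgt >= n_e:
            inh = inh + (inh >= (tgt - n_e))
        inh = inh + n_e
        src_lists[tgt, :k] = exc
        src_lists[tgt, k:] = inh
        np.add.at(counts, src_lists[tgt], 1)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=out_ptr[1:])
    out_idx = np.empty(out_ptr[-1], dtype=np.int64)
    fill = out_ptr[:-1].copy()
    for tgt in range(n):
        for src in src_lists[tgt]:
            out_idx[fill[src]] = tgt
            fill[src] += 1
    return Connectivity(out_ptr=out_ptr, out_idx=out_idx, n_e=n_e, n_i=n_i,
                        k=k)


@njit(cache=True)
def _net_chunk(v, hold_until, pending, kind, e_l, v_t, delta_t, tau_m,
               tau_ref, v_thr_eff, v_reset_eff, v_min, transit_spike,
               transit_total, n_e, out_ptr, out_idx, amp_from_e, amp_from_i,
               mu_x, sigma_x, noise, dt, t0, spike_t, spike_i, count):
    n_neurons, n_steps = noise.shape
    namp = np.sqrt(2.0 / tau_m)
    for k in range(n_steps):
        t = t0 + k * dt
        n_spk_this = 0
        for i in range(n_neurons):
            if t < hold_until[i]:
                pending[i] = 0.0  # refractory neurons ignore input
                continue
            vi = v[i] + pending[i]
            pending[i] = 0.0
            if kind == 0:
                f = -(vi - e_l)
            elif kind == 1:
                f = (vi - v_t) * (vi - v_t) / delta_t
            else:
                arg = (vi - v_t) / delta_t
                if arg > 30.0:
                    arg = 30.0
                f = -(vi - e_l) + delta_t * np.exp(arg)
            vi = vi + (f + mu_x) * dt / tau_m + sigma_x * namp * noise[i, k]
            if not np.isfinite(vi):
                return -1, count
            if vi >= v_thr_eff:
                if count >= spike_t.shape[0]:
                    return -2, count
                spike_t[count] = t + dt + transit_spike
                spike_i[count] = i
                count += 1
                n_spk_this += 1
                v[i] = v_reset_eff
                hold_until[i] = t + dt + transit_total + tau_ref
                # deliver at the next step
                a = amp_from_e if i < n_e else amp_from_i
                for p in range(out_ptr[i], out_ptr[i + 1]):
                    tgt = out_idx[p]
                    if tgt < n_e:
                        pending[tgt] += a[0]
                    else:
                        pending[tgt] += a[1]
            else:
                if vi < v_min:
                    vi = v_min
                v[i] = vi
    return 0, count


def simulate_spiking_network(conn: Connectivity, weights: NetworkWeights,
                             params: NeuronParams, external,
                             duration: float, dt: float | None = None,
                             seed: int = 0, bin_ms: float = 1.0,
                             chunk_steps: int = 4000):
    """Euler-Maruyama simulation of the coupled spiking network.

    ``external`` is the white-noise background (mu_x, sigma_x) in mV.
    Spike-triggered jumps of J/tau_m mV are applied at the integration
    step after the presynaptic spike.  Aborts if the population rate
    runs away (sustained > 1 kHz per neuron).

    Returns ``(raster, rate_e, rate_i)``.
    """
    dt = dt or {"lif": 0.05, "qif": 0.02, "eif": 0.02}[params.model_kind]
    mu_x, sigma_x = external
    n = conn.n
    n_steps = int(round(duration / dt))
    v = np.full(n, params.effective_reset, dtype=float)
    hold = np.full(n, -1.0)
    pending = np.zeros(n)
    kind = {"lif": 0, "qif": 1, "eif": 2}[params.model_kind]
    if params.model_kind == "qif":
        transit_spike = params.tau_m * params.delta_t / params.v_max
        transit_total = transit_spike + params.tau_m * params.delta_t \
            / abs(params.v_min)
    else:
        transit_spike = transit_total = 0.0
    # voltage jumps per presynaptic class, [onto E, onto I]
    amp_from_e = np.array([weights.j_ee, weights.j_ie]) / params.tau_m
    amp_from_i = -np.array([weights.j_ei, weights.j_ii]) / params.tau_m
    cap = int(n * duration * 1.0) + 1024
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)
    count = 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    sqdt = math.sqrt(dt)
    for start in range(0, n_steps, chunk_steps):
        stop = min(start + chunk_steps, n_steps)
        noise = rng.standard_normal((n, stop - start)) * sqdt
        status, count = _net_chunk(
            v, hold, pending, kind, params.e_l, params.v_t,
            max(params.delta_t, 1e-12), params.tau_m, params.tau_ref,
            params.effective_threshold, params.effective_reset, params.v_min,
            transit_spike, transit_total, conn.n_e, conn.out_ptr,
            conn.out_idx, amp_from_e, amp_from_i, mu_x, sigma_x, noise, dt,
            start * dt, spike_t, spike_i, count)
        if status == -1:
            raise FloatingPointError("non-finite membrane potential in "
                                     "network simulation (dt too large?)")
        if status == -2:
            raise RuntimeError("runaway network: population rate exceeded "
                               "1 kHz per neuron")
    sel = spike_t[:count] <= duration
    times, ids = spike_t[:count][sel], spike_i[:count][sel]
    raster = SpikeRaster(times=times, neuron_ids=ids, n_neurons=n,
                         duration=duration)
    is_e = raster.neuron_ids < conn.n_e
    raster_e = SpikeRaster(times=raster.times[is_e],
                           neuron_ids=raster.neuron_ids[is_e],
                           n_neurons=conn.n_e, duration=duration)
    raster_i = SpikeRaster(times=raster.times[~is_e],
                           neuron_ids=raster.neuron_ids[~is_e] - conn.n_e,
                           n_neurons=conn.n_i, duration=duration)
    return raster, estimate_rate(raster_e, bin_ms), estimate_rate(raster_i,
                                                                  bin_ms)


def measure_synaptic_input(raster: SpikeRaster, conn: Connectivity,
                           weights: NetworkWeights, params: NeuronParams,
                           window: tuple):
    """Empirical mean (mV) and variance rate (mV^2) of the recurrent input
    per target population over a time window, from voltage-free
    accumulation of the synaptic increments; oracle for ``coupled_drive``.
    """
    t0, t1 = window
    dur = t1 - t0
    sel = (raster.times >= t0) & (raster.times < t1)
    ids = raster.neuron_ids[sel]
    n = conn.n
    kicks_sum = np.zeros(n)
    kicks_sq = np.zeros(n)
    amp_from = {True: np.array([weights.j_ee, weights.j_ie]) / params.tau_m,
                False: -np.array([weights.j_ei, weights.j_ii]) / params.tau_m}
    for src in ids:
        a = amp_from[src < conn.n_e]
        tgts = conn.out_idx[conn.out_ptr[src]:conn.out_ptr[src + 1]]
        e_t = tgts[tgts < conn.n_e]
        i_t = tgts[tgts >= conn.n_e]
        kicks_sum[e_t] += a[0]
        kicks_sq[e_t] += a[0] ** 2
        kicks_sum[i_t] += a[1]
        kicks_sq[i_t] += a[1] ** 2
    # mean drive in mV: tau_m * (jump rate * jump size)
    mu_e = params.tau_m * kicks_sum[:conn.n_e].mean() / dur
    mu_i = params.tau_m * kicks_sum[conn.n_e:].mean() / dur
    # variance in the sqrt(2 tau_m) convention: sigma^2 = tau_m/2 * var rate
    var_e = 0.5 * params.tau_m * kicks_sq[:conn.n_e].mean() / dur
    var_i = 0.5 * params.tau_m * kicks_sq[conn.n_e:].mean() / dur
    return (mu_e, var_e), (mu_i, var_i)


# ----------------------------------------------------------------------
# rate network
# ----------------------------------------------------------------------

def simulate_rate_network(weights: NetworkWeights, external,
                          table_e: OperatingTable, table_i: OperatingTable,
                          fit: LambdaFit | None = None,
                          duration: float = 1000.0, dt: float = 0.1,
                          r_hat0=None, perturb_hz: float = 1.0):
    """Forward-integrate the two-unit complex rate network.

    Each step floors the real rates at zero, recomputes the coupled
    drive, looks up (r_inf, CV) per population, maps to lambda, and
    advances each complex rate exactly over dt.  ``r_hat0`` defaults to
    the uncoupled baseline plus a small perturbation so that unstable
    fixed points reveal their limit cycle.

    Returns ``(state_e, state_i)``.
    """
    fit = fit or LambdaFit()
    tau_m = table_e.params.tau_m
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if r_hat0 is None:
        mu_x, sigma_x = external
        r0, _, _ = table_e.lookup(mu_x, sigma_x)
        r_e = complex(r0 + perturb_hz)
        r_i = complex(r0 - perturb_hz)
    else:
        r_e, r_i = complex(r_hat0[0]), complex(r_hat0[1])
    out_e = np.empty(n, dtype=complex)
    out_i = np.empty(n, dtype=complex)
    for k in range(n):
        out_e[k], out_i[k] = r_e, r_i
        drive = coupled_drive((r_e.real, r_i.real), weights, external, tau_m)
        try:
            re_inf, cv_e, _ = table_e.lookup(drive.mu_e, drive.sigma_e)
            ri_inf, cv_i, _ = table_i.lookup(drive.mu_i, drive.sigma_i)
        except ValueError as err:
            raise ValueError(f"drive left the operating table at "
                             f"t={t[k]:.1f} ms: {err}") from err
        lam_e = fit.lam(max(re_inf, 1e-6), max(cv_e, 1e-4))
        lam_i = fit.lam(max(ri_inf, 1e-6), max(cv_i, 1e-4))
        r_e = re_inf + (r_e - re_inf) * np.exp(lam_e * dt)
        r_i = ri_inf + (r_i - ri_inf) * np.exp(lam_i * dt)
    return ComplexRateState(t=t, r_hat=out_e), ComplexRateState(t=t,
                                                                r_hat=out_i)


def find_fixed_point(weights: NetworkWeights, external,
                     table_e: OperatingTable, table_i: OperatingTable,
                     fit: LambdaFit | None = None):
    """Self-consistent rates r_a = r_inf(mu_a(r), sigma_a(r)).

    Returns ``(r_e, r_i, drive)`` in Hz; raises on non-convergence from
    all starts (candidate runaway regime).
    """
    from scipy import optimize as opt
    tau_m = table_e.params.tau_m
    mu_x, sigma_x = external
    r_base, _, _ = table_e.lookup(mu_x, sigma_x)

    def resid(x):
        drive = coupled_drive((x[0], x[1]), weights, external, tau_m)
        try:
            re_inf, _, _ = table_e.lookup(drive.mu_e, drive.sigma_e)
            ri_inf, _, _ = table_i.lookup(drive.mu_i, drive.sigma_i)
        except ValueError:
            return [1e3 + x[0], 1e3 + x[1]]
        return [re_inf - x[0], ri_inf - x[1]]

    starts = [(r_base, r_base), (0.5 * r_base, 0.5 * r_base),
              (1.5 * r_base, 1.5 * r_base), (5.0, 5.0)]
    for x0 in starts:
        sol = opt.root(resid, x0, method="hybr", tol=1e-12)
        if sol.success and np.max(np.abs(sol.fun)) < 1e-8:
            r_e, r_i = float(sol.x[0]), float(sol.x[1])
            drive = coupled_drive((r_e, r_i), weights, external, tau_m)
            return r_e, r_i, drive
    raise RuntimeError("no self-consistent fixed point found "
                       "(candidate runaway regime)")


def _vector_field(state, weights, external, table_e, table_i, fit, tau_m):
    """Real 4-vector field over (x_E, y_E, x_I, y_I), rates in Hz."""
    x_e, y_e, x_i, y_i = state
    drive = coupled_drive((x_e, x_i), weights, external, tau_m)
    re_inf, cv_e, _ = table_e.lookup(drive.mu_e, drive.sigma_e)
    ri_inf, cv_i, _ = table_i.lookup(drive.mu_i, drive.sigma_i)
    lam_e = fit.lam(max(re_inf, 1e-6), max(cv_e, 1e-4))
    lam_i = fit.lam(max(ri_inf, 1e-6), max(cv_i, 1e-4))
    de = lam_e * (complex(x_e, y_e) - re_inf)
    di = lam_i * (complex(x_i, y_i) - ri_inf)
    return np.array([de.real, de.imag, di.real, di.imag])


def stability_at(weights: NetworkWeights, fixed_point, external,
                 table_e: OperatingTable, table_i: OperatingTable,
                 fit: LambdaFit | None = None, rel_step: float = 1e-4):
    """Jacobian eigenvalues of the rate network at a fixed point and the
    stable/limit-cycle verdict.

    Central finite differences over the four real state components; the
    verdict is ``limit_cycle`` iff the largest real part is positive.
    Returns ``(eigenvalues, verdict_is_stable)``.
    """
    fit = fit or LambdaFit()
    tau_m = table_e.params.tau_m
    r_e, r_i = fixed_point[0], fixed_point[1]
    x0 = np.array([r_e, 0.0, r_i, 0.0])
    jac = np.empty((4, 4))
    for j in range(4):
        h = rel_step * max(abs(x0[j]), 1.0)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = _vector_field(xp, weights, external, table_e, table_i, fit,
                           tau_m)
        fm = _vector_field(xm, weights, external, table_e, table_i, fit,
                           tau_m)
        jac[:, j] = (fp - fm) / (2 * h)
    ev = np.linalg.eigvals(jac)
    return ev, bool(np.max(ev.real) < 0)


@dataclass
class StabilityMap:
    """Grid of fixed-point stability verdicts over (w_E, w_I)."""

    w_e_grid: np.ndarray
    w_i_grid: np.ndarray
    rate_e: np.ndarray        # fixed-point rates, Hz (nan where failed)
    rate_i: np.ndarray
    max_re_eig: np.ndarray    # 1/ms
    stable: np.ndarray        # bool; False = limit cycle
    failed: np.ndarray        # bool; fixed point not found
    g: float

    def to_csv(self, path):
        import pandas as pd
        we, wi = np.meshgrid(self.w_e_grid, self.w_i_grid, indexing="ij")
        pd.DataFrame({
            "w_e": we.ravel(), "w_i": wi.ravel(),
            "rate_e_hz": self.rate_e.ravel(),
            "rate_i_hz": self.rate_i.ravel(),
            "max_re_eig_per_ms": self.max_re_eig.ravel(),
            "verdict": np.where(self.failed.ravel(), "failed",
                                np.where(self.stable.ravel(), "stable",
                                         "limit_cycle")),
        }).to_csv(path, index=False)


def scan_stability_map(w_e_grid, w_i_grid, external,
                       table_e: OperatingTable, table_i: OperatingTable,
                       g: float = 0.5, k: int = 500, n_e: int = 5000,
                       n_i: int = 5000,
                       fit: LambdaFit | None = None) -> StabilityMap:
    """Fixed point + Jacobian verdict on every (w_E, w_I) cell.

    Per-cell failures are recorded in ``failed`` rather than raised.
    """
    fit = fit or LambdaFit()
    w_e_grid = np.asarray(w_e_grid, dtype=float)
    w_i_grid = np.asarray(w_i_grid, dtype=float)
    shape = (len(w_e_grid), len(w_i_grid))
    rate_e = np.full(shape, np.nan)
    rate_i = np.full(shape, np.nan)
    max_re = np.full(shape, np.nan)
    stable = np.zeros(shape, dtype=bool)
    failed = np.zeros(shape, dtype=bool)
    for i, w_e in enumerate(w_e_grid):
        for j, w_i in enumerate(w_i_grid):
            weights = NetworkWeights.from_scan(w_e, w_i, g=g, k=k,
                                               n_e=n_e, n_i=n_i)
            try:
                r_e, r_i, _ = find_fixed_point(weights, external, table_e,
                                               table_i, fit)
                ev, ok = stability_at(weights, (r_e, r_i), external,
                                      table_e, table_i, fit)
            except (RuntimeError, ValueError):
                failed[i, j] = True
                continue
            rate_e[i, j], rate_i[i, j] = r_e, r_i
            max_re[i, j] = float(np.max(ev.real))
            stable[i, j] = ok
    return StabilityMap(w_e_grid=w_e_grid, w_i_grid=w_i_grid, rate_e=rate_e,
                        rate_i=rate_i, max_re_eig=max_re, stable=stable,
                        failed=failed, g=g)


def oscillation_verdict(rate_hz, dt_ms: float, discard_frac: float = 0.2,
                        prominence: float = 10.0, min_std_hz: float = 0.1):
    """Operational limit-cycle detector for forward runs: Welch spectrum
    over the last (1 - discard_frac) of the series; oscillatory if the
    peak exceeds ``prominence`` times the median spectral floor and the
    tail fluctuates by at least ``min_std_hz`` (guards against decayed
    transients in noiseless rate trajectories, whose spectral floor is
    machine noise).

    Returns ``(is_oscillatory, peak_freq_hz)``.
    """
    from .metrics import power_spectrum
    rate_hz = np.asarray(rate_hz, dtype=float)
    tail = rate_hz[int(discard_frac * len(rate_hz)):]
    seg = min(256.0, len(tail) * dt_ms / 4.0)
    f, p = power_spectrum(tail, dt_ms, segment_ms=seg)
    floor = np.median(p[1:])
    k = 1 + int(np.argmax(p[1:]))
    if floor <= 0 or tail.std() < min_std_hz:
        return False, 0.0
    return bool(p[k] > prominence * floor), float(f[k])
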