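"""Fokker-Planck solvers for integrate-and-fire populations.

Under the diffusion approximation the membrane-potential density P(V,t)
of a population described by ``tau_m dV/dt = f(V) + I0 + sigma
sqrt(2 tau_m) eta(t)`` obeys

    dP/dt = -dJ/dV,      J(V) = a(V) P - D dP/dV,

with drift ``a(V) = (f(V) + mu)/tau_m`` and diffusion ``D =
sigma^2/tau_m``.  The threshold is absorbing (P = 0 there), the firing
rate is the flux through threshold, and the reset re-injects that flux
(after the refractory period) as a flux discontinuity at V_reset.

This module computes, for the LIF, QIF and EIF models:

* the stationary density, flux and steady rate ``r_inf`` (threshold
  integration, integrating the scaled flux/density system downward from
  threshold);
* the interspike-interval CV from the first two first-passage-time
  moments (backward-equation integration on the same grid);
* the dominant nonzero eigenvalue ``lambda_1`` of the Fokker-Planck
  operator — by complex shooting on the eigenfunction ODE for the LIF
  and EIF, and by Fourier expansion of the equivalent theta (phase)
  model for the QIF, whose reset at -infinity maps onto periodic
  boundary conditions;
* the first-order linear response (gain and phase) to sinusoidal
  modulation of the input mean;
* an operating table mapping (mu, sigma) <-> (r_inf, CV, lambda_1) with
  forward interpolation and inverse lookup, plus calibration of (mu,
  sigma) to a target (rate, CV);
* a direct time-stepping integrator for the full PDE
  (Scharfetter-Gummel flux discretization, Crank-Nicolson in time) used
  as an independent oracle for the spectral solvers.

Internal units: mV, ms; rates in the public API are Hz, eigenvalues and
angular frequencies are 1/ms unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .neurons import NeuronParams

__all__ = [
    "StationarySolution", "ComplexEigenvalue", "OperatingPoint",
    "OperatingTable", "steady_state", "isi_cv", "eigenvalue",
    "eigenvalue_lif", "eigenvalue_eif", "eigenvalue_qif",
    "spiking_linear_response", "build_operating_table",
    "calibrate_operating_point", "pde_rate_transient", "fit_damped_cosine",
]

_DEFAULT_DV = 1.0 / 16.0  # mV; Richardson-style grid spacing
_QIF_N_THETA = 4000
_QIF_V_BIG = 800.0  # mV; half-width of the QIF voltage window


# ----------------------------------------------------------------------
# grids
# ----------------------------------------------------------------------

def _grid(params: NeuronParams, mu: float, sigma: float,
          dv: float = _DEFAULT_DV, n_theta: int = _QIF_N_THETA):
    """Ascending voltage grid from the numerical floor to the threshold.

    Contains the effective reset exactly.  For the QIF the grid is
    uniform in the theta (phase) variable, which concentrates points
    around the soft threshold and stretches them into the 1/V^2 tails.
    Returns ``(v, reset_idx)``; ``reset_idx < 0`` means the reset lies
    below the window (QIF).
    """
    if params.model_kind == "qif":
        th_max = 2.0 * math.atan(2.0 * _QIF_V_BIG / params.delta_t)
        theta = np.linspace(-th_max, th_max, n_theta)
        v = params.v_t + 0.5 * params.delta_t * np.tan(0.5 * theta)
        return v, -1
    v_th = params.effective_threshold
    v_reset = params.effective_reset
    # floor low enough that the stationary density there is negligible
    v_lb = min(params.v_min, v_reset - 8.0 * sigma, mu - 8.0 * sigma)
    # resolve the sigma-scaled boundary layers (first-passage moments
    # converge slowly in dv/sigma at weak noise)
    dv = max(min(dv, sigma / 32.0), 1.0 / 512.0)
    n_lo = int(math.ceil((v_reset - v_lb) / dv))
    n_hi = int(math.ceil((v_th - v_reset) / dv))
    v = np.concatenate([
        v_reset - np.arange(n_lo, 0, -1) * (v_reset - v_lb) / n_lo,
        v_reset + np.arange(0, n_hi + 1) * (v_th - v_reset) / n_hi,
    ])
    return v, n_lo


def _drift_arrays(params: NeuronParams, mu: float, sigma: float, v: np.ndarray):
    a = (params.drift_fn()(v) + mu) / params.tau_m
    d = sigma * sigma / params.tau_m
    return a, d


def _window_transit(params: NeuronParams, v: np.ndarray) -> float:
    """Deterministic transit time (ms) spent beyond the solver's voltage
    window: for the QIF the drift carries the voltage from v[-1] to
    +inf and from -inf back to v[0] in tau_m*Delta_T/|V| each."""
    if params.model_kind != "qif":
        return 0.0
    return params.tau_m * params.delta_t * (1.0 / v[-1] + 1.0 / abs(v[0]))


# ----------------------------------------------------------------------
# numba kernels: threshold integration
# ----------------------------------------------------------------------

@njit(cache=True)
def _steady_kernel(v, a, d, reset_idx):
    """Scaled density p = P/r by downward integration; flux/r is 1 above
    the reset and 0 below (1 everywhere if reset_idx < 0)."""
    n = v.shape[0]
    p = np.zeros(n)
    for i in range(n - 2, -1, -1):
        h = v[i + 1] - v[i]
        am = 0.5 * (a[i] + a[i + 1])
        jhat = 1.0 if (reset_idx < 0 or i >= reset_idx) else 0.0
        ah = am * h / d
        if ah > 500.0:  # solution collapses onto the flux-carrying branch
            p[i] = jhat / am
            continue
        e = math.exp(-ah)
        if abs(ah) < 1e-7:
            term = (jhat / d) * h * (1.0 - 0.5 * ah)
        else:
            term = (jhat / am) * (1.0 - e)
        p[i] = p[i + 1] * e + term
        if p[i] > 1e250:  # vanishing-rate regime; avoid overflow
            p[i] = 1e250
    return p


@njit(cache=True)
def _fpt_w_kernel(v, a, d, src):
    """Upward pass: w' = src - (a/d) w, w(v[0]) = 0 (reflecting floor)."""
    n = v.shape[0]
    w = np.zeros(n)
    for i in range(1, n):
        h = v[i] - v[i - 1]
        am = 0.5 * (a[i] + a[i - 1])
        cm = 0.5 * (src[i] + src[i - 1])
        ah = am * h / d
        if ah > 500.0:
            w[i] = cm * d / am if am != 0.0 else w[i - 1]
            continue
        e = math.exp(-ah)
        if abs(ah) < 1e-7:
            w[i] = w[i - 1] * e + cm * h * (1.0 - 0.5 * ah)
        else:
            w[i] = w[i - 1] * e + (cm * d / am) * (1.0 - e)
        if w[i] > 1e250:
            w[i] = 1e250
    return w


@njit(cache=True)
def _fpt_m_kernel(v, w, d):
    """Downward pass: M' = -w/d, M(threshold) = 0 (trapezoid)."""
    n = v.shape[0]
    m = np.zeros(n)
    for i in range(n - 2, -1, -1):
        h = v[i + 1] - v[i]
        m[i] = m[i + 1] + 0.5 * (w[i] + w[i + 1]) * h / d
    return m


@njit(cache=True)
def _shoot_kernel(v, a, d, reset_idx, lam, ref_factor):
    """Downward shooting for the eigenfunction pair (phi, j).

    phi' = (a phi - j)/d, j' = -lam phi, phi(th) = 0, j(th) = 1,
    with the re-injection jump j -> j - ref_factor at the reset.
    Returns j at the floor (the characteristic function of lam).
    """
    n = v.shape[0]
    phi = 0.0 + 0.0j
    j = 1.0 + 0.0j
    for i in range(n - 2, -1, -1):
        h = v[i + 1] - v[i]
        am = 0.5 * (a[i] + a[i + 1])
        ah = am * h / d
        jh = j + lam * (0.5 * h) * phi
        if ah > 500.0:
            phi_new = jh / am
        else:
            e = math.exp(-ah)
            if abs(ah) < 1e-7:
                phi_new = phi + (am * phi - jh) * (-h) / d
            else:
                phi_new = (phi - jh / am) * e + jh / am
        j = j + lam * (0.5 * h) * (phi + phi_new)
        phi = phi_new
        if i == reset_idx:
            j = j - ref_factor
    return j


@njit(cache=True)
def _linresp_kernel(v, a, d, reset_idx, p0_over_tau, omega, ref_factor,
                    with_source, with_unit_flux):
    """Downward shooting for the rate-modulation problem at frequency omega.

    Phat' = (a Phat + c - Jhat)/d with c = P0/tau (source on/off),
    Jhat' = -i omega Phat, Phat(th) = 0, Jhat(th) = 1 or 0, reset jump
    Jhat -> Jhat - ref_factor when with_unit_flux.  Returns Jhat(floor).
    """
    n = v.shape[0]
    ph = 0.0 + 0.0j
    jh = (1.0 + 0.0j) if with_unit_flux else (0.0 + 0.0j)
    iw = 1j * omega
    for i in range(n - 2, -1, -1):
        h = v[i + 1] - v[i]
        am = 0.5 * (a[i] + a[i + 1])
        cm = 0.5 * (p0_over_tau[i] + p0_over_tau[i + 1]) if with_source else 0.0
        ah = am * h / d
        jmid = jh + iw * (0.5 * h) * ph
        if ah > 500.0:
            ph_new = (jmid - cm) / am
        else:
            e = math.exp(-ah)
            if abs(ah) < 1e-7:
                ph_new = ph + (am * ph + cm - jmid) * (-h) / d
            else:
                pp = (jmid - cm) / am
                ph_new = (ph - pp) * e + pp
        jh = jh + iw * (0.5 * h) * (ph + ph_new)
        ph = ph_new
        if with_unit_flux and i == reset_idx:
            jh = jh - ref_factor
    return jh


# ----------------------------------------------------------------------
# stationary solution and ISI statistics
# ----------------------------------------------------------------------

@dataclass
class StationarySolution:
    """Stationary density, flux and rate at one (mu, sigma)."""

    v: np.ndarray          # mV, ascending
    density: np.ndarray    # P0(V), 1/mV
    flux: np.ndarray       # J(V), 1/ms (equals rate above the reset)
    rate_hz: float         # steady rate, refractory-corrected
    mu: float
    sigma: float
    params: NeuronParams

    @property
    def normalization(self) -> float:
        """integral of P0 plus refractory (and tail-transit) mass; == 1."""
        r = self.rate_hz / 1000.0
        held = self.params.tau_ref + _window_transit(self.params, self.v)
        return float(np.trapezoid(self.density, self.v) + r * held)


def steady_state(params: NeuronParams, mu: float, sigma: float,
                 dv: float = _DEFAULT_DV) -> StationarySolution:
    """Stationary Fokker-Planck solution by threshold integration.

    Requires sigma > 0 (the diffusion approximation); for sigma = 0 use
    the deterministic closed-form interspike interval instead.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0; use the deterministic closed "
                         "form for noiseless drive")
    v, reset_idx = _grid(params, mu, sigma, dv=dv)
    a, d = _drift_arrays(params, mu, sigma, v)
    p_scaled = _steady_kernel(v, a, d, reset_idx)
    area = float(np.trapezoid(p_scaled, v))
    mean_isi = area + params.tau_ref + _window_transit(params, v)
    r = 1.0 / mean_isi  # 1/ms
    jhat = np.ones_like(v)
    if reset_idx >= 0:
        jhat[:reset_idx] = 0.0
    return StationarySolution(v=v, density=r * p_scaled, flux=r * jhat,
                              rate_hz=1000.0 * r, mu=mu, sigma=sigma,
                              params=params)


def _fpt_moments(params: NeuronParams, mu: float, sigma: float,
                 dv: float = _DEFAULT_DV):
    """Mean and variance (ms, ms^2) of the threshold first-passage time
    from the effective reset, via the backward-equation moment ODEs."""
    v, reset_idx = _grid(params, mu, sigma, dv=dv)
    a, d = _drift_arrays(params, mu, sigma, v)
    w1 = _fpt_w_kernel(v, a, d, np.ones_like(v))
    m1 = _fpt_m_kernel(v, w1, d)
    w2 = _fpt_w_kernel(v, a, d, 2.0 * m1)
    m2 = _fpt_m_kernel(v, w2, d)
    i0 = max(reset_idx, 0)
    t1 = m1[i0] + _window_transit(params, v)  # deterministic shift
    if m1[i0] > 1e120:  # vanishing-rate regime
        return t1, 0.0
    var = m2[i0] - m1[i0] ** 2
    return t1, max(var, 0.0)


def isi_cv(params: NeuronParams, mu: float, sigma: float,
           dv: float = _DEFAULT_DV) -> float:
    """Interspike-interval coefficient of variation at (mu, sigma).

    The refractory period adds to the mean but not to the variance of
    the interval.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t1, var = _fpt_moments(params, mu, sigma, dv=dv)
    return float(math.sqrt(var) / (t1 + params.tau_ref))


def mean_rate_from_moments(params: NeuronParams, mu: float, sigma: float,
                           dv: float = _DEFAULT_DV) -> float:
    """Steady rate (Hz) via the mean first-passage time; cross-check of
    ``steady_state``."""
    t1, _ = _fpt_moments(params, mu, sigma, dv=dv)
    return 1000.0 / (t1 + params.tau_ref)


# ----------------------------------------------------------------------
# dominant nonzero eigenvalue
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexEigenvalue:
    """Dominant nonzero Fokker-Planck eigenvalue at one operating point.

    Stored with ``imag >= 0``; when complex, the conjugate is also an
    eigenvalue.  Units 1/ms.
    """

    value: complex
    model_kind: str
    mu: float
    sigma: float
    residual: float = 0.0

    def __post_init__(self):
        if self.value.real >= 0:
            raise ValueError("nonzero Fokker-Planck eigenvalues must have "
                             "negative real part")

    @property
    def decay_rate(self) -> float:
        return -self.value.real

    @property
    def frequency_hz(self) -> float:
        return 1000.0 * self.value.imag / (2.0 * math.pi)


@dataclass(frozen=True)
class OperatingPoint:
    """(mu, sigma) <-> (r_inf, CV) correspondence at one input condition."""

    mu: float
    sigma: float
    rate_hz: float
    cv: float


def _default_lambda_guess(params: NeuronParams, mu: float, sigma: float):
    """Initial guess for the eigenvalue Newton search from the universal
    (r_inf, CV) parameterization."""
    from .rate_models import LambdaFit  # deferred: avoids module cycle
    r = steady_state(params, mu, sigma).rate_hz
    cv = isi_cv(params, mu, sigma)
    return LambdaFit().lam(r, min(cv, 1.0)), r, cv


def _shoot_residual(params, mu, sigma, lam, dv=_DEFAULT_DV):
    v, reset_idx = _grid(params, mu, sigma, dv=dv)
    a, d = _drift_arrays(params, mu, sigma, v)
    ref = np.exp(-lam * params.tau_ref)
    return _shoot_kernel(v, a, d, reset_idx, lam, ref)


def _newton_eigen(params, mu, sigma, guess, dv=_DEFAULT_DV, tol=1e-8,
                  max_iter=50):
    lam = complex(guess)
    scale = abs(lam) + 1e-3
    for _ in range(max_iter):
        f = _shoot_residual(params, mu, sigma, lam, dv)
        if not np.isfinite(f.real) or not np.isfinite(f.imag):
            return None, math.inf
        step = 1e-7 * (abs(lam) + 1e-3)
        fp = (_shoot_residual(params, mu, sigma, lam + step, dv) - f) / step
        if fp == 0:
            return None, abs(f)
        dlam = -f / fp
        # damp wild steps; characteristic functions have nearby roots
        if abs(dlam) > 0.5 * scale:
            dlam *= 0.5 * scale / abs(dlam)
        lam = lam + dlam
        if abs(dlam) < tol * (abs(lam) + 1e-12):
            res = abs(_shoot_residual(params, mu, sigma, lam, dv))
            return lam, res
    return None, abs(f)


def _eigen_shooting(params: NeuronParams, mu: float, sigma: float,
                    initial_guess=None, dv: float = _DEFAULT_DV
                    ) -> ComplexEigenvalue:
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if initial_guess is None:
        guess, _, _ = _default_lambda_guess(params, mu, sigma)
    else:
        guess = complex(initial_guess)
    # restart lattice of perturbed guesses around the prediction; collect
    # the distinct converged roots and keep the least-negative-Re one
    # (characteristic equations have nearby strongly-damped branches).
    # Pure-real starts catch the diffusive real branch that dominates at
    # high noise (Newton preserves realness there).
    starts = [guess * c for c in
              (1.0, 0.8, 1.25, 1.0 + 0.3j, 1.0 - 0.3j, 0.6, 1.6,
               0.9 + 0.5j, 0.9 - 0.5j)]
    starts += [complex(guess.real * c, 0.0) for c in (0.3, 0.6, 1.2)]
    roots, trace = [], []
    for start in starts:
        lam, res = _newton_eigen(params, mu, sigma, start, dv=dv)
        trace.append(res)
        if lam is None:
            continue
        if abs(lam) < 0.02 * abs(guess) or lam.real >= 0:
            continue  # collapsed onto the stationary mode or spurious root
        if lam.imag < 0:
            lam = lam.conjugate()
        roots.append((lam, res))
    if not roots:
        raise RuntimeError(
            f"eigenvalue Newton search failed at mu={mu}, sigma={sigma}; "
            f"residuals of restarts: {trace}")
    lam, res = max(roots, key=lambda t: t[0].real)
    return ComplexEigenvalue(value=lam, model_kind=params.model_kind,
                             mu=mu, sigma=sigma, residual=res)


def eigenvalue_eif(params: NeuronParams, mu: float, sigma: float,
                   initial_guess=None, dv: float = _DEFAULT_DV
                   ) -> ComplexEigenvalue:
    """Dominant nonzero eigenvalue of the EIF by complex shooting on the
    eigenfunction ODE (threshold integration + Newton-Raphson)."""
    if params.model_kind != "eif":
        raise ValueError("params must describe an EIF model")
    return _eigen_shooting(params, mu, sigma, initial_guess, dv)


def eigenvalue_lif(params: NeuronParams, mu: float, sigma: float,
                   initial_guess=None, dv: float = _DEFAULT_DV
                   ) -> ComplexEigenvalue:
    """Dominant nonzero eigenvalue of the LIF.

    The eigenfunctions solve a confluent-hypergeometric equation; the
    characteristic function is evaluated by high-accuracy numerical
    integration of that same ODE, located in the complex plane by
    Newton-Raphson.
    """
    if params.model_kind != "lif":
        raise ValueError("params must describe an LIF model")
    return _eigen_shooting(params, mu, sigma, initial_guess, dv)


# -- QIF via the theta model -------------------------------------------

def _theta_operator(params: NeuronParams, mu: float, sigma: float,
                    n_fourier: int) -> np.ndarray:
    """Fokker-Planck operator of the theta model in the Fourier basis.

    V = (Delta_T/2) tan(theta/2) maps the QIF onto a phase variable on
    [-pi, pi) with periodic boundary conditions (spike and reset are the
    same point).  The Ito-corrected drift and diffusion are finite
    trigonometric polynomials, so multiplication couples only nearby
    harmonics and the operator is banded in Fourier space.
    """
    tau, delta = params.tau_m, params.delta_t
    beta = 4.0 * sigma * sigma / (tau * delta * delta)
    # f(V) = (V - v_t)^2 / delta, so mu enters the phase drift only
    # through 2 mu / (delta tau)
    m2 = 2.0 * mu / (delta * tau)
    alpha = {}
    alpha[0] = 0.5 / tau + m2
    alpha[1] = -0.25 / tau + 0.5 * m2 + 0.5j * beta
    alpha[-1] = -0.25 / tau + 0.5 * m2 - 0.5j * beta
    alpha[2] = 0.25j * beta
    alpha[-2] = -0.25j * beta
    b = {0: 1.5 * beta, 1: beta, -1: beta, 2: 0.25 * beta, -2: 0.25 * beta}
    size = 2 * n_fourier + 1
    m = np.zeros((size, size), dtype=complex)
    for row in range(size):
        n = row - n_fourier
        for dk in (-2, -1, 0, 1, 2):
            col = row - dk
            if 0 <= col < size:
                m[row, col] = -1j * n * alpha[dk] - n * n * b[dk]
    return m


def eigenvalue_qif(params: NeuronParams, mu: float, sigma: float,
                   n_fourier: int = 100) -> ComplexEigenvalue:
    """Dominant nonzero eigenvalue of the QIF via the theta-model Fourier
    operator (truncated at ``n_fourier`` harmonics)."""
    if params.model_kind != "qif":
        raise ValueError("params must describe a QIF model")
    if n_fourier < 16:
        raise ValueError("n_fourier must be >= 16")
    m = _theta_operator(params, mu, sigma, n_fourier)
    ev = np.linalg.eigvals(m)
    # drop the stationary (~0) eigenvalue, take the least-negative rest
    idx = np.argsort(-ev.real)
    ev = ev[idx]
    lam = None
    for e in ev:
        if abs(e) < 1e-10 or e.real >= 0:
            continue
        lam = e
        break
    if lam is None:
        raise RuntimeError("no nonzero eigenvalue found; increase n_fourier")
    if lam.imag < 0:
        lam = lam.conjugate()
    return ComplexEigenvalue(value=complex(lam), model_kind="qif",
                             mu=mu, sigma=sigma, residual=0.0)


def qif_stationary_fourier(params: NeuronParams, mu: float, sigma: float,
                           n_fourier: int = 100):
    """Stationary Fourier coefficients and rate (Hz) of the theta model;
    independent cross-check of the threshold-integration rate."""
    m = _theta_operator(params, mu, sigma, n_fourier)
    ev, vec = np.linalg.eig(m)
    k = int(np.argmin(np.abs(ev)))
    c = vec[:, k]
    c = c / (2.0 * np.pi * c[n_fourier])  # normalize integral of P to 1
    n = np.arange(-n_fourier, n_fourier + 1)
    p_pi = np.real(np.sum(c * np.exp(1j * n * np.pi)))
    return c, 1000.0 * p_pi / params.tau_m


def eigenvalue(params: NeuronParams, mu: float, sigma: float,
               **kw) -> ComplexEigenvalue:
    """Dispatch to the per-model dominant-eigenvalue solver."""
    return {"lif": eigenvalue_lif, "eif": eigenvalue_eif,
            "qif": eigenvalue_qif}[params.model_kind](params, mu, sigma, **kw)


# ----------------------------------------------------------------------
# linear response of the spiking models
# ----------------------------------------------------------------------

def spiking_linear_response(params: NeuronParams, mu: float, sigma: float,
                            freqs_hz, dv: float = _DEFAULT_DV,
                            n_fourier: int = 100):
    """First-order rate response to sinusoidal modulation of the mean.

    Returns ``(gain, phase)`` arrays over ``freqs_hz``: gain in Hz per
    mV of modulation amplitude, phase in radians (positive = rate lags
    input).  The zero-frequency limit is dr_inf/dmu.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz < 0):
        raise ValueError("frequencies must be >= 0")
    if params.model_kind == "qif":
        return _qif_linear_response(params, mu, sigma, freqs_hz, n_fourier)
    v, reset_idx = _grid(params, mu, sigma, dv=dv)
    a, d = _drift_arrays(params, mu, sigma, v)
    p_scaled = _steady_kernel(v, a, d, reset_idx)
    area = float(np.trapezoid(p_scaled, v))
    r0 = 1.0 / (area + params.tau_ref)  # 1/ms
    p0_over_tau = r0 * p_scaled / params.tau_m
    gains = np.empty_like(freqs_hz)
    phases = np.empty_like(freqs_hz)
    for k, f in enumerate(freqs_hz):
        w = 2.0 * np.pi * f / 1000.0  # rad/ms
        ref = np.exp(-1j * w * params.tau_ref)
        j1 = _linresp_kernel(v, a, d, reset_idx, p0_over_tau, w, ref,
                             False, True)
        j2 = _linresp_kernel(v, a, d, reset_idx, p0_over_tau, w, ref,
                             True, False)
        rhat = -j2 / j1  # rate modulation (1/ms) per mV
        gains[k] = 1000.0 * abs(rhat)
        phases[k] = -np.angle(rhat)
    return gains, np.unwrap(phases)


def _qif_linear_response(params, mu, sigma, freqs_hz, n_fourier):
    m = _theta_operator(params, mu, sigma, n_fourier)
    c0, _ = qif_stationary_fourier(params, mu, sigma, n_fourier)
    size = 2 * n_fourier + 1
    nvec = np.arange(-n_fourier, n_fourier + 1)
    # d(operator)/dmu: only the drift harmonics 0, +-1 carry mu
    dm = np.zeros((size, size), dtype=complex)
    dal = {0: 2.0 / (params.delta_t * params.tau_m),
           1: 1.0 / (params.delta_t * params.tau_m),
           -1: 1.0 / (params.delta_t * params.tau_m)}
    for row in range(size):
        n = row - n_fourier
        for dk in (-1, 0, 1):
            col = row - dk
            if 0 <= col < size:
                dm[row, col] = -1j * n * dal[dk]
    rhs = -dm @ c0
    sign = np.where(nvec % 2 == 0, 1.0, -1.0)
    gains = np.empty_like(freqs_hz)
    phases = np.empty_like(freqs_hz)
    eye = np.eye(size)
    for k, f in enumerate(freqs_hz):
        w = 2.0 * np.pi * f / 1000.0
        chat = np.linalg.solve(m - 1j * w * eye, rhs)
        rhat = np.sum(sign * chat) / params.tau_m
        gains[k] = 1000.0 * abs(rhat)
        phases[k] = -np.angle(rhat)
    return gains, np.unwrap(phases)


# ----------------------------------------------------------------------
# operating tables and calibration
# ----------------------------------------------------------------------

class OperatingTable:
    """Tabulated (mu, sigma) -> (r_inf, CV, lambda_1) with interpolation
    and inverse lookup.

    Queries outside the tabulated rectangle raise rather than silently
    extrapolate.
    """

    def __init__(self, params: NeuronParams, mu_grid, sigma_grid,
                 rate_hz, cv, lam_re, lam_im, interp_order: int = 1):
        self.params = params
        self.mu_grid = np.asarray(mu_grid, dtype=float)
        self.sigma_grid = np.asarray(sigma_grid, dtype=float)
        self.rate_hz = np.asarray(rate_hz, dtype=float)
        self.cv = np.asarray(cv, dtype=float)
        self.lam_re = np.asarray(lam_re, dtype=float)
        self.lam_im = np.asarray(lam_im, dtype=float)
        self.interp_order = interp_order

    # fast scalar bilinear lookup (hot path of the rate-network loop)
    def _locate(self, grid, x, name):
        if x < grid[0] - 1e-12 or x > grid[-1] + 1e-12:
            raise ValueError(f"{name}={x} outside tabulated range "
                             f"[{grid[0]}, {grid[-1]}]")
        i = int(np.searchsorted(grid, x) - 1)
        i = min(max(i, 0), len(grid) - 2)
        t = (x - grid[i]) / (grid[i + 1] - grid[i])
        return i, min(max(t, 0.0), 1.0)

    def _bilinear(self, arr, i, ti, j, tj):
        return ((1 - ti) * ((1 - tj) * arr[i, j] + tj * arr[i, j + 1])
                + ti * ((1 - tj) * arr[i + 1, j] + tj * arr[i + 1, j + 1]))

    def lookup(self, mu: float, sigma: float):
        """Interpolated (rate_hz, cv, lambda) at (mu, sigma)."""
        i, ti = self._locate(self.mu_grid, mu, "mu")
        j, tj = self._locate(self.sigma_grid, sigma, "sigma")
        r = self._bilinear(self.rate_hz, i, ti, j, tj)
        cv = self._bilinear(self.cv, i, ti, j, tj)
        lam = complex(self._bilinear(self.lam_re, i, ti, j, tj),
                      self._bilinear(self.lam_im, i, ti, j, tj))
        return float(r), float(cv), lam

    def rate_cv(self, mu: float, sigma: float):
        r, cv, _ = self.lookup(mu, sigma)
        return r, cv

    def inverse(self, rate_hz: float, cv: float):
        """(mu, sigma) whose interpolated (rate, CV) match the targets."""
        r_nodes = self.rate_hz
        k = np.unravel_index(
            np.argmin((r_nodes - rate_hz) ** 2 / max(rate_hz, 1.0) ** 2
                      + (self.cv - cv) ** 2 / max(cv, 1e-3) ** 2),
            r_nodes.shape)
        x0 = np.array([self.mu_grid[k[0]], self.sigma_grid[k[1]]])

        def resid(x):
            mu = min(max(x[0], self.mu_grid[0]), self.mu_grid[-1])
            sg = min(max(x[1], self.sigma_grid[0]), self.sigma_grid[-1])
            r, c = self.rate_cv(mu, sg)
            return [(r - rate_hz) / max(rate_hz, 1.0),
                    (c - cv) / max(cv, 1e-3)]

        sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
        if not sol.success or np.linalg.norm(sol.fun) > 1e-4:
            raise ValueError(f"target (rate={rate_hz} Hz, cv={cv}) not inside "
                             "the tabulated hull")
        return float(sol.x[0]), float(sol.x[1])

    # -- persistence -------------------------------------------------------

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["model_kind"] = self.params.model_kind
            f.attrs["params_json"] = self.params.to_json()
            f.attrs["interp_order"] = self.interp_order
            for name in ("mu_grid", "sigma_grid", "rate_hz", "cv",
                         "lam_re", "lam_im"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            params = NeuronParams.from_json(f.attrs["params_json"])
            data = {name: f[name][...] for name in
                    ("mu_grid", "sigma_grid", "rate_hz", "cv",
                     "lam_re", "lam_im")}
            order = int(f.attrs["interp_order"])
        return cls(params, interp_order=order, **data)

    def to_csv(self, path):
        import pandas as pd
        mm, ss = np.meshgrid(self.mu_grid, self.sigma_grid, indexing="ij")
        pd.DataFrame({
            "mu_mv": mm.ravel(), "sigma_mv": ss.ravel(),
            "rate_hz": self.rate_hz.ravel(), "cv": self.cv.ravel(),
            "lam_re_per_ms": self.lam_re.ravel(),
            "lam_im_per_ms": self.lam_im.ravel(),
        }).to_csv(path, index=False)


def build_operating_table(params: NeuronParams, mu_grid, sigma_grid,
                          with_eigenvalues: bool = True,
                          dv: float = _DEFAULT_DV) -> OperatingTable:
    """Solve the stationary and spectral problems on a (mu, sigma) grid."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    shape = (len(mu_grid), len(sigma_grid))
    rate = np.empty(shape)
    cv = np.empty(shape)
    lre = np.zeros(shape)
    lim = np.zeros(shape)
    for i, mu in enumerate(mu_grid):
        for j, sg in enumerate(sigma_grid):
            rate[i, j] = steady_state(params, mu, sg, dv=dv).rate_hz
            cv[i, j] = isi_cv(params, mu, sg, dv=dv)
            if with_eigenvalues:
                lam = eigenvalue(params, mu, sg).value
                lre[i, j], lim[i, j] = lam.real, lam.imag
    return OperatingTable(params, mu_grid, sigma_grid, rate, cv, lre, lim)


def calibrate_operating_point(params: NeuronParams, target_rate_hz: float,
                              target_cv: float, mu_bounds=(0.5, 60.0),
                              sigma_bounds=(0.05, 12.0),
                              table: OperatingTable | None = None):
    """Find (mu, sigma) whose direct steady-state rate and CV match the
    targets (relative tolerance 0.5%% or better).

    A coarse internal scan (or a supplied table) seeds a least-squares
    refinement on the direct solvers.
    """
    if table is not None:
        x0 = np.array(table.inverse(target_rate_hz, target_cv))
    else:
        mus = np.linspace(mu_bounds[0], mu_bounds[1], 14)
        sgs = np.geomspace(sigma_bounds[0], sigma_bounds[1], 10)
        best, x0 = math.inf, None
        for mu in mus:
            for sg in sgs:
                r = steady_state(params, mu, sg).rate_hz
                c = isi_cv(params, mu, sg)
                err = ((r - target_rate_hz) / target_rate_hz) ** 2 \
                    + ((c - target_cv) / max(target_cv, 1e-3)) ** 2
                if err < best:
                    best, x0 = err, np.array([mu, sg])

    def resid(x):
        r = steady_state(params, x[0], x[1]).rate_hz
        c = isi_cv(params, x[0], x[1])
        # log-ratio residuals keep the search out of the flat zero-rate
        # region and weight rate and CV comparably
        return [math.log(max(r, 1e-9) / target_rate_hz),
                math.log(max(c, 1e-9) / max(target_cv, 1e-3))]

    sol = optimize.least_squares(
        resid, x0, diff_step=1e-4,
        bounds=([mu_bounds[0], sigma_bounds[0]],
                [mu_bounds[1], sigma_bounds[1]]),
        x_scale=[max(x0[0], 1.0), max(x0[1], 0.2)],
        xtol=3e-14, ftol=3e-14, gtol=1e-14)
    if np.linalg.norm(sol.fun, ord=np.inf) > 5e-3:
        raise ValueError(
            f"calibration target (rate={target_rate_hz} Hz, cv={target_cv}) "
            f"unreachable within bounds; residual {sol.fun}")
    return float(sol.x[0]), float(sol.x[1])


# ----------------------------------------------------------------------
# direct PDE integration (independent oracle)
# ----------------------------------------------------------------------

def _sg_weights(a_face, d, h):
    """Scharfetter-Gummel face flux J = (d/h) [B(-p) P_left - B(p) P_right]
    with p = a h / d and B the Bernoulli function; exact for locally
    constant drift, stable at any cell Peclet number."""
    p = a_face * h / d

    def bern(x):
        out = np.where(np.abs(x) < 1e-8, 1.0 - 0.5 * x,
                       x / np.expm1(np.clip(x, -500, 500)))
        return out
    wl = (d / h) * bern(-p)
    wr = (d / h) * bern(p)
    return wl, wr


def pde_rate_transient(params: NeuronParams, mu0: float, mu1: float,
                       sigma: float, t_end: float = 120.0, dt: float = 0.01,
                       dv: float = 0.05):
    """Population-rate transient after a step mu0 -> mu1 of the mean drive,
    by direct Crank-Nicolson integration of the Fokker-Planck PDE.

    Returns ``(t, rate_hz)``.  Serves as the model-free oracle for the
    spectral solvers: fitting a damped cosine to the transient recovers
    Re and Im of the dominant nonzero eigenvalue.
    """
    dv = min(dv, sigma / 10.0)
    v, reset_idx = _grid(params, mu1, sigma, dv=dv)
    if params.model_kind == "qif":
        reset_idx = 0  # re-inject at the lower edge of the window
    n = len(v)
    h = np.diff(v)
    a1, d = _drift_arrays(params, mu1, sigma, v)
    a_face = 0.5 * (a1[:-1] + a1[1:])
    wl, wr = _sg_weights(a_face, d, h)
    # cell widths (finite volumes centred on nodes; absorbing top node)
    widths = np.empty(n)
    widths[0] = h[0] / 2
    widths[-1] = h[-1] / 2
    widths[1:-1] = 0.5 * (h[:-1] + h[1:])
    # operator L P: dP_i/dt = (J_{i-1/2} - J_{i+1/2}) / width_i with face
    # flux J_{i+1/2} = wl[i] P_i - wr[i] P_{i+1}; P_i loses wl[i] upward
    # and wr[i-1] downward, gains wl[i-1] P_{i-1} and wr[i] P_{i+1}
    main = np.zeros(n)
    main[:-1] -= wl / widths[:-1]
    main[1:] -= wr / widths[1:]
    lo = wl / widths[1:]
    hi = wr / widths[:-1]
    lop = sparse.diags([lo, main, hi], offsets=[-1, 0, 1], format="csc")
    # absorbing top: P_n-1 held at 0 -> zero its row
    lop = lop.tolil()
    lop[n - 1, :] = 0.0
    lop = lop.tocsc()
    eye = sparse.identity(n, format="csc")
    lhs = splu((eye - 0.5 * dt * lop).tocsc())
    rhs_m = (eye + 0.5 * dt * lop).tocsc()

    # initial condition: stationary density at mu0
    s0 = steady_state(params, mu0, sigma, dv=dv)
    p = np.interp(v, s0.v, s0.density)
    p[-1] = 0.0

    n_steps = int(round(t_end / dt))
    rate = np.empty(n_steps)
    held = params.tau_ref + _window_transit(params, v)
    delay_steps = int(round(held / dt))
    queue = np.zeros(max(delay_steps, 1))
    # seed the refractory queue with the stationary rate at mu0
    queue[:] = s0.rate_hz / 1000.0
    qi = 0
    reinj = max(reset_idx, 0)
    for k in range(n_steps):
        # absorbed flux at threshold face during this step (1/ms)
        r_now = wl[-1] * p[-2] - wr[-1] * p[-1]
        rate[k] = r_now
        if delay_steps > 0:
            r_rein = queue[qi]
            queue[qi] = r_now
            qi = (qi + 1) % delay_steps
        else:
            r_rein = r_now
        b = rhs_m @ p
        b[reinj] += dt * r_rein / widths[reinj]
        p = lhs.solve(b)
        p[-1] = 0.0
        np.clip(p, 0.0, None, out=p)
    t = np.arange(n_steps) * dt
    return t, 1000.0 * rate


def fit_damped_cosine(t, rate_hz, blank_ms: float = 20.0,
                      window_ms: float = 100.0):
    """Fit r(t) = r_inf + A exp(alpha t) cos(Omega t + phi) to a rate
    transient.  Returns ``(alpha, Omega)`` in 1/ms (alpha < 0).

    Initial guesses come from the FFT peak of the detrended signal and
    the log-envelope slope, independent of any spectral solver.
    """
    t = np.asarray(t, float)
    rate_hz = np.asarray(rate_hz, float)
    sel = (t >= blank_ms) & (t <= blank_ms + window_ms)
    ts, ys = t[sel], rate_hz[sel]
    dt = ts[1] - ts[0]
    r_inf = ys[-max(5, len(ys) // 20):].mean()
    z = ys - r_inf
    freqs = np.fft.rfftfreq(len(z), dt)
    spec = np.abs(np.fft.rfft(z * np.hanning(len(z))))
    k = 1 + int(np.argmax(spec[1:]))
    omega0 = 2.0 * np.pi * freqs[k]
    # envelope slope via analytic signal
    from scipy.signal import hilbert
    env = np.abs(hilbert(z))
    good = env > max(env.max() * 1e-3, 1e-12)
    slope = np.polyfit(ts[good], np.log(env[good]), 1)[0]
    alpha0 = min(slope, -1e-4)

    def model(tt, rinf, amp, alpha, omega, phi):
        return rinf + amp * np.exp(alpha * (tt - ts[0])) * np.cos(
            omega * (tt - ts[0]) + phi)

    from scipy.optimize import curve_fit
    p0 = [r_inf, max(abs(z).max(), 1e-6), alpha0, omega0, 0.0]
    try:
        popt, _ = curve_fit(model, ts, ys, p0=p0, maxfev=20000)
    except RuntimeError:
        popt = p0
    alpha, omega = popt[2], abs(popt[3])
    return float(alpha), float(omega)
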