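"""Classic and complex-valued firing-rate models.

The classic rate model relaxes the rate exponentially toward the
steady-state rate r_inf(t) with a single real rate constant.  The
complex-valued model promotes both the rate and the rate constant to
complex numbers,

    d r_hat / dt = lam * (r_hat - r_inf(t)),      r(t) = Re r_hat,

where ``lam`` is the dominant nonzero eigenvalue of the Fokker-Planck
operator of the underlying spiking model.  Its imaginary part sets the
frequency of rate transients (partial spike synchronization at the
firing rate itself) and its real part their decay.

Across the LIF, QIF and EIF, ``lam`` expressed as a function of the
output statistics (r_inf, CV) is approximately model-independent:

    Im lam = 2 pi r_inf,          Re lam = -alpha * CV^2 * r_inf,

valid for CV below about 0.75.  ``LambdaFit`` holds these constants.
The quadratic coefficient alpha was frozen from this package's own
reproduction of the eigenvalue surfaces (EIF at sigma = 1, 2 and 4 mV);
it agrees with the small-CV phase-diffusion prediction 2 pi^2 for a
renewal process, and the linear Im coefficient 2 pi reflects the ringing
at the interspike frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fokker_planck import OperatingPoint, OperatingTable

__all__ = ["ComplexRateState", "LambdaFit", "LinearResponse",
           "integrate_classic", "fit_classic_lambda", "integrate_complex",
           "complex_linear_response"]

TWO_PI = 2.0 * math.pi


@dataclass
class ComplexRateState:
    """Complex rate trajectory; the real part is the predicted rate."""

    t: np.ndarray          # ms
    r_hat: np.ndarray      # complex, Hz

    @property
    def rate_hz(self) -> np.ndarray:
        return self.r_hat.real

    @property
    def imag_hz(self) -> np.ndarray:
        return self.r_hat.imag

    def to_csv(self, path):
        import pandas as pd
        pd.DataFrame({"time_ms": self.t, "rate_hz": self.rate_hz,
                      "imag_hz": self.imag_hz}).to_csv(path, index=False)


@dataclass(frozen=True)
class LambdaFit:
    """Universal map (r_inf, CV) -> lam (1/ms) closing the complex model.

    ``lam = (r_inf/1000) * (-alpha CV^2 + i im_coef)`` with rates in Hz.
    ``cv_max`` bounds the validity domain of the quadratic Re fit.
    """

    alpha: float = 19.74       # ~ 2 pi^2; frozen from the eigenvalue fit
    im_coef: float = TWO_PI
    cv_max: float = 0.75

    def lam(self, rate_hz: float, cv: float) -> complex:
        if rate_hz <= 0:
            raise ValueError("r_inf must be positive")
        r = rate_hz / 1000.0  # 1/ms
        return complex(-self.alpha * cv * cv * r, self.im_coef * r)

    __call__ = lam

    def in_domain(self, cv: float) -> bool:
        return 0.0 < cv <= self.cv_max


@dataclass
class LinearResponse:
    """Gain (Hz/mV) and unwrapped phase (rad) on a frequency grid (Hz)."""

    freqs_hz: np.ndarray
    gain: np.ndarray
    phase: np.ndarray

    @property
    def peak_frequency_hz(self) -> float:
        return float(self.freqs_hz[int(np.argmax(self.gain))])


# ----------------------------------------------------------------------
# classic rate model
# ----------------------------------------------------------------------

def integrate_classic(r_inf_traj, lam: float, r0: float, dt: float):
    """Integrate dr/dt = -lam (r - r_inf(t)) exactly on each dt segment.

    ``lam`` is the positive decay rate (1/ms) of the classic model;
    ``r_inf_traj`` is sampled at dt (Hz).  Exponential stepping makes the
    solution exact for piecewise-constant r_inf.
    """
    if lam <= 0:
        raise ValueError("classic-model decay rate must be positive")
    r_inf_traj = np.asarray(r_inf_traj, dtype=float)
    out = np.empty_like(r_inf_traj)
    e = math.exp(-lam * dt)
    r = float(r0)
    for k, ri in enumerate(r_inf_traj):
        out[k] = r
        r = ri + (r - ri) * e
    return out


def classic_step_response(t, t_on: float, r_pre: float, r_post: float,
                          lam: float):
    """Closed-form step response of the classic model."""
    t = np.asarray(t, dtype=float)
    out = np.where(t < t_on, r_pre,
                   r_post + (r_pre - r_post) * np.exp(-lam * np.clip(
                       t - t_on, 0.0, None)))
    return out


def fit_classic_lambda(params, mu_lo: float, mu_hi: float, sigma: float,
                       n_neurons: int = 2000, n_reps: int = 10,
                       seed: int = 0, dt: float | None = None,
                       t_pre: float = 300.0, t_post: float = 300.0,
                       bin_ms: float = 1.0, psth=None) -> float:
    """Least-squares-optimal decay rate (1/ms) of the classic model for a
    step mu_lo -> mu_hi of the common input.

    Simulates ``n_reps`` populations of ``n_neurons`` spiking neurons,
    averages their PSTHs, and fits the analytic classic-model step
    response with the Fokker-Planck steady rates as the pre/post levels.
    A precomputed ``psth`` (sampled at ``bin_ms``) bypasses the
    simulation.
    """
    from . import population_sim as ps
    from .fokker_planck import steady_state
    from .neurons import InputDrive
    from .stimulus import StimulusSpec

    r_pre = steady_state(params, mu_lo, sigma).rate_hz
    r_post = steady_state(params, mu_hi, sigma).rate_hz
    if abs(r_post - r_pre) < 1e-3:
        raise ValueError("step produces no measurable rate change")
    if psth is None:
        spec = StimulusSpec(kind="step", baseline=mu_lo,
                            step_amplitude=mu_hi - mu_lo, step_onset=t_pre,
                            duration=t_pre + t_post, dt=dt or 0.05)
        psum = None
        for rep in range(n_reps):
            raster = ps.simulate_population(
                params, InputDrive(i0=spec, sigma=sigma),
                n_neurons=n_neurons, duration=spec.duration, dt=dt,
                seed=seed + 7919 * rep)
            pr = ps.estimate_rate(raster, bin_ms=bin_ms)
            psum = pr.rate_hz if psum is None else psum + pr.rate_hz
        psth = psum / n_reps
    t = (np.arange(len(psth)) + 0.5) * bin_ms
    if float(np.std(psth)) == 0.0:
        raise ValueError("degenerate (flat) PSTH")

    from scipy.optimize import minimize_scalar

    def sse(log_lam):
        lam = math.exp(log_lam)
        model = classic_step_response(t, t_pre, r_pre, r_post, lam)
        return float(np.sum((model - psth) ** 2))

    sol = minimize_scalar(sse, bounds=(math.log(1e-4), math.log(10.0)),
                          method="bounded",
                          options={"xatol": 1e-10})
    return float(math.exp(sol.x))


# ----------------------------------------------------------------------
# complex-valued rate model
# ----------------------------------------------------------------------

def integrate_complex(drive, table: OperatingTable,
                      fit: LambdaFit | None = None, dt: float = 0.1,
                      duration: float | None = None,
                      r_hat0: complex | None = None) -> ComplexRateState:
    """Integrate the complex rate model under a time-dependent drive.

    ``drive`` provides ``mean_at(t)`` and ``sigma_at(t)`` (an
    ``InputDrive``).  Each step looks up (r_inf, CV) at the
    instantaneous (mu, sigma) from the operating table, maps them to
    ``lam`` through the universal fit, and advances the linear complex
    ODE exactly over the step (quasi-static approximation).
    """
    fit = fit or LambdaFit()
    if duration is None:
        raise ValueError("duration (ms) is required")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    mu = np.asarray(drive.mean_at(t), dtype=float)
    sg = np.asarray(drive.sigma_at(t), dtype=float)
    out = np.empty(n, dtype=complex)
    r0_hz, cv0, _ = table.lookup(mu[0], sg[0])
    r_hat = complex(r0_hz) if r_hat0 is None else complex(r_hat0)
    for k in range(n):
        try:
            r_inf, cv, _ = table.lookup(mu[k], sg[k])
        except ValueError as err:
            raise ValueError(f"drive leaves the operating table at "
                             f"t={t[k]:.2f} ms: {err}") from err
        lam = fit.lam(max(r_inf, 1e-6), max(cv, 1e-4))
        out[k] = r_hat
        r_hat = r_inf + (r_hat - r_inf) * np.exp(lam * dt)
    return ComplexRateState(t=t, r_hat=out)


def complex_linear_response(operating: OperatingPoint,
                            fit: LambdaFit | None = None,
                            dmu_gain: float = 1.0,
                            freqs_hz=None) -> LinearResponse:
    """First-order gain and phase of the complex rate model.

    For input modulation mu -> mu + eps cos(omega t) the rate responds
    with complex gain

        G(omega) = (dr_inf/dmu) * [lam/(lam - i omega)
                                   + lam*/(lam* - i omega)] / 2,

    whose DC limit is dr_inf/dmu (``dmu_gain``, Hz/mV, finite-differenced
    from an operating table by the caller).  The lam-dependence of the
    first-order dynamics enters only through the baseline lam because
    the perturbation multiplies (r_hat - r_inf), which vanishes at the
    fixed point.
    """
    fit = fit or LambdaFit()
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 201.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    lam = fit.lam(operating.rate_hz, operating.cv)
    w = 2.0 * np.pi * freqs_hz / 1000.0  # rad/ms
    g = 0.5 * (lam / (lam - 1j * w) + np.conj(lam) / (np.conj(lam) - 1j * w))
    gain = dmu_gain * np.abs(g)
    phase = np.unwrap(-np.angle(g))
    return LinearResponse(freqs_hz=freqs_hz, gain=gain, phase=phase)
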