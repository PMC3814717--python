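"""Integrate-and-fire neuron models and their stochastic input drive.

Three one-dimensional spiking models share the membrane equation

    tau_m dV/dt = f(V) + I(t),

with the model-specific drift

    LIF:  f(V) = -(V - E_L)
    QIF:  f(V) = (V - V_T)^2 / Delta_T
    EIF:  f(V) = -(V - E_L) + Delta_T * exp((V - V_T) / Delta_T)

A spike is recorded when V reaches the threshold (a finite V_th for the
LIF; a numerical ceiling ``v_max`` standing in for the divergence to
infinity for the QIF and EIF), after which V is reset and held for the
refractory period ``tau_ref``.

The input current is I(t) = I0(t) + sigma(t) * sqrt(2 tau_m) * eta(t),
where eta is unit-variance white noise (delta-correlated, zero mean).
With this scaling a purely leaky membrane has stationary voltage
variance sigma^2, and the drift-diffusion coefficients of the
Fokker-Planck description are (f(V) + I0)/tau_m and sigma^2/tau_m.

Units: millivolts and milliseconds throughout; rates cross the API in Hz.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

__all__ = ["NeuronParams", "InputDrive", "membrane_drift", "spike_and_reset"]

_MODEL_KINDS = ("lif", "qif", "eif")


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one integrate-and-fire model variant.

    ``v_max``/``v_min`` are the numerical stand-ins for the infinite
    spike threshold (QIF/EIF) and the open lower end of the voltage
    axis.  For the QIF the reset also lies at minus infinity; the time
    spent on the deterministic tails beyond the numerical window is
    accounted for analytically (see ``tail_transit_time``).
    """

    model_kind: str
    v_th: float          # spike threshold (mV); inf for QIF/EIF
    v_reset: float       # reset potential (mV); -inf for QIF
    tau_m: float = 10.0  # membrane time constant (ms)
    tau_ref: float = 0.0  # absolute refractory period (ms)
    e_l: float = 0.0     # leak reversal (mV), LIF/EIF
    v_t: float = 0.0     # soft threshold (mV), QIF/EIF
    delta_t: float = 0.0  # spike sharpness (mV), QIF/EIF
    v_max: float = 0.0   # numerical spike ceiling (mV)
    v_min: float = -60.0  # numerical floor (mV)

    def __post_init__(self):
        if self.model_kind not in _MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.model_kind in ("qif", "eif") and self.delta_t <= 0:
            raise ValueError("delta_t must be positive for QIF/EIF")
        if not self.effective_reset < self.effective_threshold:
            raise ValueError("require v_reset < v_th")
        if not (self.v_min <= self.effective_reset):
            raise ValueError("require v_min <= v_reset")
        if np.isfinite(self.v_th) and self.v_max < self.v_th:
            raise ValueError("require v_max >= v_th")

    # -- constructors mirroring the reference parameter table ---------------

    @classmethod
    def lif(cls, **overrides) -> "NeuronParams":
        kw = dict(model_kind="lif", v_th=20.0, v_reset=10.0, e_l=0.0,
                  tau_m=10.0, tau_ref=0.0, v_max=20.0, v_min=-40.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def qif(cls, **overrides) -> "NeuronParams":
        # true threshold and reset at +/- infinity; window +/-100 mV with
        # analytic tail-transit correction
        kw = dict(model_kind="qif", v_th=math.inf, v_reset=-math.inf,
                  v_t=0.0, delta_t=10.0, tau_m=10.0, tau_ref=0.0,
                  v_max=100.0, v_min=-100.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def eif(cls, **overrides) -> "NeuronParams":
        kw = dict(model_kind="eif", v_th=math.inf, v_reset=3.0, e_l=0.0,
                  v_t=10.0, delta_t=1.0, tau_m=10.0, tau_ref=2.0,
                  v_max=30.0, v_min=-40.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def preset(cls, model_kind: str, **overrides) -> "NeuronParams":
        return {"lif": cls.lif, "qif": cls.qif, "eif": cls.eif}[model_kind](**overrides)

    # -- derived quantities --------------------------------------------------

    @property
    def effective_threshold(self) -> float:
        """Voltage whose crossing is counted as a spike."""
        return self.v_th if np.isfinite(self.v_th) else self.v_max

    @property
    def effective_reset(self) -> float:
        """Voltage at which the membrane re-enters after a spike."""
        return self.v_reset if np.isfinite(self.v_reset) else self.v_min

    @property
    def tail_transit_time(self) -> float:
        """Deterministic time (ms) spent outside the numerical window.

        For the QIF the drift V^2/Delta_T carries the voltage from v_max
        to +inf and from -inf to v_min in tau_m*Delta_T/|V| each; for the
        EIF the exponential tail time is negligible and for the LIF zero.
        """
        if self.model_kind != "qif":
            return 0.0
        return self.tau_m * self.delta_t * (1.0 / self.v_max + 1.0 / abs(self.v_min))

    def drift_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        """Return f(V) as a vectorized callable (input current excluded)."""
        if self.model_kind == "lif":
            e_l = self.e_l
            return lambda v: -(np.asarray(v, dtype=float) - e_l)
        if self.model_kind == "qif":
            v_t, dt_ = self.v_t, self.delta_t
            return lambda v: (np.asarray(v, dtype=float) - v_t) ** 2 / dt_
        e_l, v_t, dt_ = self.e_l, self.v_t, self.delta_t
        return lambda v: (-(np.asarray(v, dtype=float) - e_l)
                          + dt_ * np.exp((np.asarray(v, dtype=float) - v_t) / dt_))

    # -- flat config I/O -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, float) and np.isinf(v):
                d[k] = "inf" if v > 0 else "-inf"
        return json.dumps(d, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        d = {k: (float(v) if isinstance(v, str) and v.lstrip("+-").startswith("inf")
                 else v) for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "NeuronParams":
        return cls.from_dict(json.loads(s))


def membrane_drift(v, params: NeuronParams, input_mean: float):
    """Full deterministic right-hand side f(V) + I0, in mV per tau_m.

    Continuous in V for all three models; errors on an unknown kind are
    raised at NeuronParams construction.
    """
    return params.drift_fn()(v) + input_mean


def spike_and_reset(v: float, params: NeuronParams):
    """Threshold test at the effective (numerical) spike ceiling.

    Returns ``(spiked, v_new)``; holding the voltage through the
    refractory period is the caller's job.
    """
    if v >= params.effective_threshold:
        return True, params.effective_reset
    return False, v


@dataclass
class InputDrive:
    """Common mean I0(t) and noise s.d. sigma(t) of the input current.

    ``i0`` and ``sigma`` are scalars or callables of time (ms) returning
    mV.  ``noise_convention`` records the scaling of the stochastic
    term; only the sqrt(2*tau_m) convention stated in the module
    docstring is implemented.
    """

    i0: float | Callable[[np.ndarray], np.ndarray]
    sigma: float | Callable[[np.ndarray], np.ndarray]
    noise_convention: str = "sqrt_2taum"

    def __post_init__(self):
        if self.noise_convention != "sqrt_2taum":
            raise ValueError("unsupported noise convention")

    def mean_at(self, t):
        return self.i0(t) if callable(self.i0) else np.broadcast_to(
            float(self.i0), np.shape(t)).astype(float) if np.ndim(t) else float(self.i0)

    def sigma_at(self, t):
        s = self.sigma(t) if callable(self.sigma) else (
            np.broadcast_to(float(self.sigma), np.shape(t)).astype(float)
            if np.ndim(t) else float(self.sigma))
        if np.any(np.asarray(s) < 0):
            raise ValueError("sigma(t) must be non-negative")
        return s
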