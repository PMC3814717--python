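"""Monte-Carlo simulation of uncoupled integrate-and-fire populations.

N identical neurons share a common input mean I0(t) and receive
independent white noise of s.d. sigma(t); the trial-averaged population
rate of this ensemble is the ground truth against which the rate models
are judged.  Integration is Euler-Maruyama with threshold crossings
handled at step granularity; the QIF's excursions beyond the numerical
voltage window are accounted for with the deterministic tail-transit
delay, during which the neuron is held like a refractory one.

Default time steps: 0.02 ms for the stiff QIF/EIF drifts, 0.05 ms for
the LIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .neurons import InputDrive, NeuronParams

__all__ = ["SpikeRaster", "PopulationRate", "simulate_population",
           "estimate_rate", "isi_statistics"]

_DEFAULT_DT = {"lif": 0.05, "qif": 0.02, "eif": 0.02}


@dataclass
class SpikeRaster:
    """Spike events (time ms, neuron index) of one simulated population."""

    times: np.ndarray
    neuron_ids: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self):
        order = np.argsort(self.times, kind="stable")
        self.times = np.asarray(self.times, dtype=float)[order]
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spikes_of(self, i: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == i])

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.times, self.neuron_ids]),
                   fmt=["%.5f", "%d"], header="time_ms neuron_id")

    @classmethod
    def from_text(cls, path, n_neurons, duration):
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            data = np.empty((0, 2))
        return cls(times=data[:, 0], neuron_ids=data[:, 1].astype(np.int64),
                   n_neurons=n_neurons, duration=duration)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times_ms", data=self.times)
            f.create_dataset("neuron_ids", data=self.neuron_ids)
            f.attrs["n_neurons"] = self.n_neurons
            f.attrs["duration_ms"] = self.duration

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            return cls(times=f["times_ms"][...],
                       neuron_ids=f["neuron_ids"][...],
                       n_neurons=int(f.attrs["n_neurons"]),
                       duration=float(f.attrs["duration_ms"]))


@dataclass
class PopulationRate:
    """Binned (optionally kernel-smoothed) population rate estimate."""

    t: np.ndarray          # bin centres, ms
    rate_hz: np.ndarray
    bin_ms: float
    smooth_ms: float = 0.0

    def to_csv(self, path):
        import pandas as pd
        pd.DataFrame({"time_ms": self.t, "rate_hz": self.rate_hz}
                     ).to_csv(path, index=False)


# model-kind codes for the kernel
_KIND = {"lif": 0, "qif": 1, "eif": 2}


@njit(cache=True)
def _sim_chunk(v, hold_until, kind, e_l, v_t, delta_t, tau_m, tau_ref,
               v_thr_eff, v_reset_eff, v_min, transit_spike, transit_total,
               i0, sigma, noise, dt, t0,
               spike_t, spike_i, count):
    n_neurons, n_steps = noise.shape
    amp = np.sqrt(2.0 / tau_m)
    for k in range(n_steps):
        t = t0 + k * dt
        cur = i0[k]
        sig = sigma[k]
        for i in range(n_neurons):
            if t < hold_until[i]:
                continue
            vi = v[i]
            if kind == 0:
                f = -(vi - e_l)
            elif kind == 1:
                f = (vi - v_t) * (vi - v_t) / delta_t
            else:
                dv_arg = (vi - v_t) / delta_t
                if dv_arg > 30.0:  # far above ceiling; spike this step anyway
                    dv_arg = 30.0
                f = -(vi - e_l) + delta_t * np.exp(dv_arg)
            vi = vi + (f + cur) * dt / tau_m + sig * amp * noise[i, k]
            if not np.isfinite(vi):
                return -1, count
            if vi >= v_thr_eff:
                st = t + dt + transit_spike
                if count >= spike_t.shape[0]:
                    return -2, count
                spike_t[count] = st
                spike_i[count] = i
                count += 1
                v[i] = v_reset_eff
                hold_until[i] = t + dt + transit_total + tau_ref
            else:
                if vi < v_min:
                    vi = v_min
                v[i] = vi
    return 0, count


def simulate_population(params: NeuronParams, drive: InputDrive,
                        n_neurons: int, duration: float,
                        dt: float | None = None, seed: int = 0,
                        v0: float | None = None,
                        chunk_steps: int = 20000) -> SpikeRaster:
    """Euler-Maruyama simulation of N uncoupled neurons.

    Noise is generated in time chunks from per-population substreams of
    ``seed``; results are deterministic given (seed, dt, n_neurons).
    """
    import warnings

    dt = dt or _DEFAULT_DT[params.model_kind]
    if params.tau_m / dt < 100:
        warnings.warn("tau_m/dt < 100; integration may be inaccurate")
    n_steps = int(round(duration / dt))
    tgrid = np.arange(n_steps) * dt
    i0 = np.ascontiguousarray(np.broadcast_to(
        drive.mean_at(tgrid), (n_steps,)), dtype=np.float64)
    sigma = np.ascontiguousarray(np.broadcast_to(
        drive.sigma_at(tgrid), (n_steps,)), dtype=np.float64)

    v = np.full(n_neurons, params.effective_reset if v0 is None else v0)
    hold = np.full(n_neurons, -1.0)
    kind = _KIND[params.model_kind]
    if params.model_kind == "qif":
        transit_spike = params.tau_m * params.delta_t / params.v_max
        transit_total = transit_spike + params.tau_m * params.delta_t / abs(
            params.v_min)
    else:
        transit_spike = transit_total = 0.0

    cap = int(n_neurons * duration * 1.0) + 1024  # 1 kHz per-neuron headroom
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)
    count = 0

    root = np.random.SeedSequence(seed)
    gens = [np.random.default_rng(s) for s in root.spawn(n_neurons)]
    sqdt = np.sqrt(dt)
    for start in range(0, n_steps, chunk_steps):
        stop = min(start + chunk_steps, n_steps)
        noise = np.empty((n_neurons, stop - start))
        for i, g in enumerate(gens):
            noise[i] = g.standard_normal(stop - start)
        noise *= sqdt
        status, count = _sim_chunk(
            v, hold, kind, params.e_l, params.v_t, max(params.delta_t, 1e-12),
            params.tau_m, params.tau_ref, params.effective_threshold,
            params.effective_reset, params.v_min, transit_spike,
            transit_total, i0[start:stop], sigma[start:stop], noise, dt,
            start * dt, spike_t, spike_i, count)
        if status == -1:
            raise FloatingPointError(
                "non-finite membrane potential; dt too large for this model")
        if status == -2:
            raise RuntimeError("spike buffer overflow (>1 kHz mean rate)")
    sel = spike_t[:count] <= duration
    return SpikeRaster(times=spike_t[:count][sel],
                       neuron_ids=spike_i[:count][sel],
                       n_neurons=n_neurons, duration=duration)


def estimate_rate(raster: SpikeRaster, bin_ms: float = 1.0,
                  smooth_ms: float = 0.0) -> PopulationRate:
    """PSTH: counts per bin / (N * bin), with optional Gaussian smoothing.

    The smoothing kernel is normalized so the time-integral of the rate
    is preserved.  An empty raster gives an all-zero rate.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(round(raster.duration / bin_ms))
    counts, _ = np.histogram(raster.times, bins=n_bins,
                             range=(0.0, n_bins * bin_ms))
    rate = 1000.0 * counts / (raster.n_neurons * bin_ms)
    if smooth_ms > 0:
        from scipy.ndimage import gaussian_filter1d
        rate = gaussian_filter1d(rate, sigma=smooth_ms / bin_ms,
                                 mode="nearest")
    t = (np.arange(n_bins) + 0.5) * bin_ms
    return PopulationRate(t=t, rate_hz=rate, bin_ms=bin_ms,
                          smooth_ms=smooth_ms)


def isi_statistics(raster: SpikeRaster, discard_ms: float = 200.0,
                   min_isis: int = 100):
    """Pooled mean rate (Hz) and ISI coefficient of variation.

    Discards the transient before ``discard_ms``; the rate is the
    inverse of the pooled mean interval.
    """
    isis = []
    for i in range(raster.n_neurons):
        st = raster.spikes_of(i)
        st = st[st >= discard_ms]
        if len(st) >= 2:
            isis.append(np.diff(st))
    if not isis:
        raise ValueError("insufficient data: no ISIs after discard")
    isis = np.concatenate(isis)
    if len(isis) < min_isis:
        raise ValueError(f"insufficient data: {len(isis)} ISIs < {min_isis}")
    mean = float(isis.mean())
    cv = float(isis.std(ddof=1) / mean)
    return 1000.0 / mean, cv
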