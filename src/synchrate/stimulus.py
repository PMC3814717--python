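"""Common-input protocols and per-neuron white-noise streams.

The stimulus kinds mirror the protocols used to probe the population
response: constant baselines, current steps, sums of equal-amplitude
sinusoids with random phases (the five-frequency mixture at 61, 50, 33,
13.1 and 7.9 Hz), and arbitrary piecewise-constant segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["StimulusSpec", "SINUSOID_MIX_FREQS_HZ", "render_common_input",
           "draw_noise_increments"]

#: The five-frequency mixture of the fluctuating common-input protocol.
SINUSOID_MIX_FREQS_HZ = (61.0, 50.0, 33.0, 13.1, 7.9)


@dataclass
class StimulusSpec:
    """Declarative description of a common-input time series I0(t)."""

    kind: str                       # constant | step | sinusoid_mix | piecewise
    baseline: float = 0.0           # mV
    duration: float = 1000.0        # ms
    dt: float = 0.1                 # ms
    # step
    step_amplitude: float = 0.0     # mV
    step_onset: float = 0.0         # ms
    # sinusoid mixture
    frequencies_hz: Sequence[float] = SINUSOID_MIX_FREQS_HZ
    amplitude: float = 1.0          # mV, common to all sinusoids
    phase_seed: int | None = None   # seeded draw of the random phases
    phases: Sequence[float] | None = None  # explicit override (radians)
    # piecewise: list of (start_ms, value_mV), values hold until next start
    segments: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("constant", "step", "sinusoid_mix", "piecewise"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.kind == "sinusoid_mix":
            if len(self.frequencies_hz) == 0:
                raise ValueError("sinusoid_mix requires a non-empty frequency list")
            if any(f <= 0 for f in self.frequencies_hz):
                raise ValueError("frequencies must be positive")

    def drawn_phases(self) -> np.ndarray:
        """Phases of the sinusoid mixture, uniform on [0, 2pi).

        Drawn from a dedicated sub-seed so the stimulus is reproducible;
        an explicit ``phases`` sequence overrides the draw.
        """
        if self.phases is not None:
            return np.asarray(self.phases, dtype=float)
        if self.phase_seed is None:
            return np.zeros(len(self.frequencies_hz))
        rng = np.random.default_rng(np.random.SeedSequence([self.phase_seed, 0x5714]))
        return rng.uniform(0.0, 2.0 * np.pi, size=len(self.frequencies_hz))

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return np.arange(n) * self.dt

    def __call__(self, t):
        """Evaluate I0 at time(s) t (ms)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.baseline)
        if self.kind == "step":
            return self.baseline + self.step_amplitude * (t >= self.step_onset)
        if self.kind == "sinusoid_mix":
            f = np.asarray(self.frequencies_hz) / 1000.0  # cycles per ms
            ph = self.drawn_phases()
            flat = t.reshape(-1)
            out = self.baseline + self.amplitude * np.sin(
                2.0 * np.pi * f[:, None] * flat[None, :]
                + ph[:, None]).sum(axis=0)
            return out.reshape(t.shape)
        # piecewise
        starts = np.asarray([s for s, _ in self.segments], dtype=float)
        values = np.asarray([v for _, v in self.segments], dtype=float)
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.where(idx >= 0, values[np.clip(idx, 0, None)], self.baseline)
        return out


def render_common_input(spec: StimulusSpec):
    """Render the common input on the stimulus time grid.

    Returns ``(t, i0)`` arrays (ms, mV).  Deterministic given
    ``phase_seed``.
    """
    t = spec.time_grid()
    return t, spec(t)


def draw_noise_increments(n_neurons: int, n_steps: int, dt: float, seed: int,
                          stream_offset: int = 0) -> np.ndarray:
    """Independent Gaussian increments, shape (n_neurons, n_steps), variance dt.

    Multiplied by sigma*sqrt(2/tau_m) they realize the white-noise term
    of the input current in an Euler-Maruyama step.  Streams are
    counter-based — neuron ``i`` always draws from sub-stream
    ``stream_offset + i`` of the seed — so enlarging the population
    leaves existing neurons' noise unchanged.
    """
    if n_neurons < 1 or n_steps < 1:
        raise ValueError("n_neurons and n_steps must be >= 1")
    root = np.random.SeedSequence(seed)
    out = np.empty((n_neurons, n_steps))
    sqdt = np.sqrt(dt)
    for i in range(n_neurons):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(stream_offset + i,)))
        out[i] = rng.standard_normal(n_steps) * sqdt
    return out
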