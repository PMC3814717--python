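"""Reproduction recipes tying the modules into full experiments.

Each recipe reproduces one of the package's headline analyses at a
configurable scale: the step-response comparison, the eigenvalue
surfaces, the sinusoid-mixture fidelity sweep, the linear-response
comparison, and the excitatory-inhibitory stability map.  A run is
described by a ``RunConfig`` (JSON-compatible), seeds every stochastic
operation from a single master seed through named substreams, and
writes CSV outputs plus a JSON manifest carrying the configuration
hash.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .neurons import NeuronParams, InputDrive
from .stimulus import StimulusSpec
from . import population_sim as ps
from . import fokker_planck as fp
from . import rate_models as rm
from . import ei_network as net
from . import metrics

__all__ = ["RunConfig", "run_experiment", "EXPERIMENTS"]


@dataclass
class RunConfig:
    """Validated experiment configuration.

    ``scale`` multiplies population sizes and repetition counts (1.0 =
    the defaults listed per recipe); ``overrides`` are recipe-specific
    keyword arguments.
    """

    experiment: str
    model_kind: str = "eif"
    seed: int = 0
    scale: float = 1.0
    out_dir: str = "results"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {sorted(EXPERIMENTS)}")
        if self.model_kind not in ("lif", "qif", "eif"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # location does not affect the computation
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def substream(self, name: str) -> int:
        """Deterministic per-module seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**json.load(f))


def _save_csv(out_dir, name, **columns):
    import pandas as pd
    path = os.path.join(out_dir, name)
    pd.DataFrame(columns).to_csv(path, index=False)
    return path


def fig1_step(cfg: RunConfig) -> dict:
    """Step response of a spiking population vs both rate models."""
    ov = cfg.overrides
    params = NeuronParams.preset(cfg.model_kind)
    sigma = ov.get("sigma", 1.0)
    mu_lo, mu_hi = ov.get("mu_lo", 11.0), ov.get("mu_hi", 13.0)
    n = max(int(2000 * cfg.scale), 200)
    spec = StimulusSpec(kind="step", baseline=mu_lo,
                        step_amplitude=mu_hi - mu_lo, step_onset=200.0,
                        duration=500.0)
    raster = ps.simulate_population(params, InputDrive(i0=spec, sigma=sigma),
                                    n, spec.duration,
                                    seed=cfg.substream("population"))
    psth = ps.estimate_rate(raster, bin_ms=1.0, smooth_ms=2.0)
    # complex model on the quasi-static drive
    mu_grid = np.linspace(min(mu_lo, mu_hi) - 2, max(mu_lo, mu_hi) + 2, 11)
    table = fp.build_operating_table(params, mu_grid, [sigma * 0.9, sigma,
                                                       sigma * 1.1],
                                     with_eigenvalues=False)
    state = rm.integrate_complex(InputDrive(i0=spec, sigma=sigma), table,
                                 duration=spec.duration, dt=0.1)
    lam_fit = rm.fit_classic_lambda(params, mu_lo, mu_hi, sigma,
                                    n_neurons=max(int(500 * cfg.scale), 100),
                                    n_reps=max(int(4 * cfg.scale), 2),
                                    seed=cfg.substream("classic_fit"))
    r_pre = fp.steady_state(params, mu_lo, sigma).rate_hz
    r_post = fp.steady_state(params, mu_hi, sigma).rate_hz
    classic = rm.classic_step_response(psth.t, 200.0, r_pre, r_post, lam_fit)
    complex_on_bins = np.interp(psth.t, state.t, state.rate_hz)
    path = _save_csv(cfg.out_dir, "fig1_step.csv", time_ms=psth.t,
                     spiking_hz=psth.rate_hz, classic_hz=classic,
                     complex_hz=complex_on_bins)
    corr_cx = metrics.shifted_correlation(psth.rate_hz, complex_on_bins, 1.0)
    corr_cl = metrics.shifted_correlation(psth.rate_hz, classic, 1.0)
    return {"outputs": [path], "classic_lambda_per_ms": lam_fit,
            "corr_complex": corr_cx.coefficient,
            "corr_classic": corr_cl.coefficient}


def fig2_lambda_surfaces(cfg: RunConfig) -> dict:
    """Dominant eigenvalue along fixed-noise curves, all three models."""
    ov = cfg.overrides
    sigmas = ov.get("sigmas", [1.0, 2.0, 4.0])
    n_mu = max(int(9 * cfg.scale), 4)
    eif = NeuronParams.eif()
    rows = {k: [] for k in ("model", "sigma_curve", "rate_hz", "cv",
                            "lam_re", "lam_im")}
    for sg in sigmas:
        for mu in np.linspace(10.5, 18.0, n_mu):
            r = fp.steady_state(eif, mu, sg).rate_hz
            cv = fp.isi_cv(eif, mu, sg)
            if cv > 0.75:
                continue
            points = [("eif", fp.eigenvalue_eif(eif, mu, sg).value)]
            for kind in ("lif", "qif"):
                p = NeuronParams.preset(kind)
                try:
                    m2, s2 = fp.calibrate_operating_point(
                        p, r, cv, mu_bounds=(0.5, 200.0))
                    points.append((kind, fp.eigenvalue(p, m2, s2).value))
                except ValueError:
                    continue
            for kind, lam in points:
                rows["model"].append(kind)
                rows["sigma_curve"].append(sg)
                rows["rate_hz"].append(r)
                rows["cv"].append(cv)
                rows["lam_re"].append(lam.real)
                rows["lam_im"].append(lam.imag)
    path = _save_csv(cfg.out_dir, "fig2_lambda.csv", **rows)
    x = np.array(rows["cv"]) ** 2 * np.array(rows["rate_hz"]) / 1000.0
    y = -np.array(rows["lam_re"])
    alpha = float(np.sum(x * y) / np.sum(x * x))
    return {"outputs": [path], "alpha_fit": alpha, "n_points": len(y)}


def fig3_correlation_sweep(cfg: RunConfig) -> dict:
    """Shifted correlation of both rate models with a spiking population
    under the five-sinusoid protocol, across noise levels."""
    ov = cfg.overrides
    params = NeuronParams.preset(cfg.model_kind)
    cvs = ov.get("cvs", [0.1, 0.8])
    duration = ov.get("duration", 5000.0) * max(cfg.scale, 0.1)
    n = max(int(2000 * cfg.scale), 200)
    amp = ov.get("amplitude", 1.0)
    base_rate = ov.get("base_rate", 50.0)
    rows = {k: [] for k in ("cv", "corr_complex", "corr_classic")}
    for cv in cvs:
        mu0, sg = fp.calibrate_operating_point(params, base_rate, cv)
        spec = StimulusSpec(kind="sinusoid_mix", baseline=mu0, amplitude=amp,
                            duration=duration,
                            phase_seed=cfg.substream(f"phases{cv}"))
        drive = InputDrive(i0=spec, sigma=sg)
        raster = ps.simulate_population(params, drive, n, duration,
                                        seed=cfg.substream(f"pop{cv}"))
        psth = ps.estimate_rate(raster, bin_ms=1.0, smooth_ms=2.0)
        mu_t = spec(spec.time_grid())
        table = fp.build_operating_table(
            params, np.linspace(mu_t.min() - 1, mu_t.max() + 1, 13),
            [sg * 0.9, sg, sg * 1.1], with_eigenvalues=False)
        state = rm.integrate_complex(drive, table, duration=duration, dt=0.1)
        cx = np.interp(psth.t, state.t, state.rate_hz)
        lam_c = rm.fit_classic_lambda(
            params, mu0 - 1.0, mu0 + 1.0, sg,
            n_neurons=max(int(500 * cfg.scale), 100), n_reps=2,
            seed=cfg.substream(f"classic{cv}"))
        r_inf_t = np.array([table.lookup(m, sg)[0] for m in mu_t])
        classic = rm.integrate_classic(r_inf_t, lam_c, r_inf_t[0], spec.dt)
        cl = np.interp(psth.t, spec.time_grid(), classic)
        rows["cv"].append(cv)
        rows["corr_complex"].append(metrics.shifted_correlation(
            psth.rate_hz, cx, 1.0).coefficient)
        rows["corr_classic"].append(metrics.shifted_correlation(
            psth.rate_hz, cl, 1.0).coefficient)
    path = _save_csv(cfg.out_dir, "fig3_correlation.csv", **rows)
    return {"outputs": [path], **{f"cv{c}": (a, b) for c, a, b in zip(
        rows["cv"], rows["corr_complex"], rows["corr_classic"])}}


def fig4_linear_response(cfg: RunConfig) -> dict:
    """Spiking vs complex-model linear response at low and high noise."""
    ov = cfg.overrides
    params = NeuronParams.preset(cfg.model_kind)
    base_rate = ov.get("base_rate", 50.0)
    freqs = np.arange(1.0, ov.get("f_max", 201.0), 1.0)
    out = []
    for cv in ov.get("cvs", [0.1, 0.7]):
        mu0, sg = fp.calibrate_operating_point(params, base_rate, cv)
        gain, phase = fp.spiking_linear_response(params, mu0, sg, freqs)
        dmu = (fp.steady_state(params, mu0 + 0.05, sg).rate_hz
               - fp.steady_state(params, mu0 - 0.05, sg).rate_hz) / 0.1
        op = fp.OperatingPoint(mu=mu0, sigma=sg, rate_hz=base_rate, cv=cv)
        lr = rm.complex_linear_response(op, dmu_gain=dmu, freqs_hz=freqs)
        path = _save_csv(cfg.out_dir, f"fig4_linresp_cv{cv}.csv",
                         freq_hz=freqs, spiking_gain=gain,
                         spiking_phase=phase, complex_gain=lr.gain,
                         complex_phase=lr.phase)
        out.append(path)
    return {"outputs": out}


def fig5_stability(cfg: RunConfig) -> dict:
    """Stability map of the two-unit rate network, optional spiking spot
    checks."""
    ov = cfg.overrides
    params = NeuronParams.preset(cfg.model_kind)
    mu_x, sg_x = fp.calibrate_operating_point(params, 50.0, 0.1)
    table = fp.build_operating_table(
        params, np.arange(-20.0, 50.1, 2.0), np.geomspace(0.4, 8.0, 14),
        with_eigenvalues=False)
    w_grid = ov.get("w_grid", list(np.arange(0.0, 0.61, 0.05)))
    smap = net.scan_stability_map(w_grid, w_grid, (mu_x, sg_x), table,
                                  table, g=ov.get("g", 0.5),
                                  k=ov.get("k", 500))
    path = os.path.join(cfg.out_dir, "fig5_stability.csv")
    smap.to_csv(path)
    n_cells = smap.stable.size
    return {"outputs": [path], "n_cells": int(n_cells),
            "n_limit_cycle": int((~smap.stable & ~smap.failed).sum()),
            "baseline_mu": mu_x, "baseline_sigma": sg_x}


EXPERIMENTS = {
    "fig1_step": fig1_step,
    "fig2_lambda_surfaces": fig2_lambda_surfaces,
    "fig3_correlation_sweep": fig3_correlation_sweep,
    "fig4_linear_response": fig4_linear_response,
    "fig5_stability": fig5_stability,
}


def run_experiment(cfg: RunConfig) -> dict:
    """Execute a recipe and write its manifest; returns the manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    result = EXPERIMENTS[cfg.experiment](cfg)
    manifest = {
        "experiment": cfg.experiment,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "package_version": __import__("synchrate").__version__,
        **result,
    }
    path = os.path.join(cfg.out_dir, f"{cfg.experiment}_manifest.json")
    with open(path, "w") as f:
        json.dump(manifest, f, indent=1, default=float)
    return manifest
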