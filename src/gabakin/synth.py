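"""Synthetic datasets with the statistical structure of patch-clamp data.

Everything the analysis consumes can be generated here with known ground
truth: whole-cell concentration-jump current sweeps (finite solution
exchange, additive Gaussian noise, geometric per-sweep rundown, a
spontaneous-activity baseline), idealized cell-attached dwell lists
(exact stochastic gating plus detection dead time), and Hill-shaped
dose-response replicate tables.  Each generator returns its data together
with a machine-readable truth sidecar so downstream recovery can be
scored.

Defaults mirror the recording conditions the analysis assumes: 250 us
theta-glass solution exchange, recordings rejected beyond 20% rundown,
0.1 ms detection dead time, and a P4S dose-response centred on
EC50 = 46 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dwell import DwellSequence, gillespie_simulate, impose_dead_time, \
    theoretical_dwell_mixture
from .energetics import hill_response
from .metrics import pulse_metrics
from .schemes import apply_modulation, load_fixture, load_modulation
from .simulate import ConcentrationProtocol, CurrentTrace, build_protocol, \
    popen_to_current, simulate_relaxation

__all__ = [
    "GeneratorConfig",
    "DoseResponseConfig",
    "make_macroscopic_dataset",
    "make_single_channel_dataset",
    "make_dose_response",
]

RUNDOWN_REJECT_FRACTION = 0.2  # recordings beyond this drift are excluded


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for macroscopic / single-channel dataset generation."""

    scheme: str = "glig_wt"
    modulation: str | None = None
    protocol: ConcentrationProtocol | None = None
    seed: int = 0
    n_sweeps: int = 5
    noise_sd: float = 0.02       # additive Gaussian, fraction of peak
    rundown_per_sweep: float = 0.02
    exchange_tau_s: float = 250e-6
    n_channels: int = 500
    unitary_current_pa: float = 2.0
    dead_time_ms: float = 0.1
    n_openings: int = 2000
    n_files: int = 5

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.rundown_per_sweep < 1):
            raise ValueError("rundown_per_sweep must be in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _load(config: GeneratorConfig):
    scheme = load_fixture(config.scheme)
    if config.modulation:
        scheme = apply_modulation(scheme, load_modulation(config.modulation))
    return scheme


def make_macroscopic_dataset(config: GeneratorConfig, dt: float = 1e-4) -> dict:
    """Noisy whole-cell sweeps plus a ground-truth sidecar.

    The noiseless open-probability trace is simulated once, converted to
    current, then each sweep gets an independent Gaussian noise
    realization and a geometric rundown factor ``(1 - r)^sweep``.  The
    sidecar holds the metrics of the clean trace; sessions whose
    cumulative rundown exceeds 20% are flagged ``rejected`` (mirroring
    the inclusion rule for real recordings).
    """
    scheme = _load(config)
    protocol = config.protocol or build_protocol(
        "long_pulse", agonist=scheme.ligands[0] if scheme.ligands else "GABA",
        conc=0.1, pulse_s=0.6, exchange_tau_s=config.exchange_tau_s)
    trace = simulate_relaxation(scheme, protocol, dt=dt)
    clean = popen_to_current(trace, config.n_channels, config.unitary_current_pa)
    peak_abs = float(np.abs(clean.current_pa).max())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    sweeps: list[CurrentTrace] = []
    for k in range(config.n_sweeps):
        scale = (1.0 - config.rundown_per_sweep) ** k
        noisy = scale * clean.current_pa + rng.normal(
            0.0, config.noise_sd * peak_abs, clean.current_pa.size)
        sweeps.append(CurrentTrace(
            time_s=clean.time_s.copy(), current_pa=noisy,
            baseline_definition=clean.baseline_definition,
            metadata=dict(clean.metadata, sweep=k, rundown_scale=scale),
        ))
    total_rundown = 1.0 - (1.0 - config.rundown_per_sweep) ** (config.n_sweeps - 1)
    b = protocol.boundaries
    pulse = (float(b[1]), float(b[2])) if len(b) > 2 else (float(b[0]), float(b[-1]))
    truth = {
        "scheme": scheme.name,
        "protocol": protocol.label,
        "pulse_window_s": pulse,
        "metrics": pulse_metrics(trace.time_s, trace.popen, pulse).to_dict(),
        "n_channels": config.n_channels,
        "unitary_current_pa": config.unitary_current_pa,
        "noise_sd": config.noise_sd,
        "rundown_per_sweep": config.rundown_per_sweep,
        "total_rundown": total_rundown,
        "seed": config.seed,
    }
    return {
        "sweeps": sweeps,
        "clean": clean,
        "popen_trace": trace,
        "truth": truth,
        "rejected": bool(total_rundown > RUNDOWN_REJECT_FRACTION),
    }


def make_single_channel_dataset(config: GeneratorConfig,
                                concentrations: Mapping[str, float] | None = None
                                ) -> dict:
    """Idealized dwell lists from exact stochastic gating + dead time.

    ``n_files`` independent recordings of ``n_openings`` openings each,
    with per-file seeds spawned deterministically from the master seed.
    The sidecar holds the generating theoretical open/shut mixtures.
    """
    scheme = _load(config)
    conc = dict(concentrations or {})
    ss = np.random.SeedSequence([config.seed, 202])
    file_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_files)]
    files: list[DwellSequence] = []
    for fs in file_seeds:
        raw = gillespie_simulate(scheme, conc, n_openings=config.n_openings, seed=fs)
        files.append(impose_dead_time(raw, config.dead_time_ms))
    truth = {
        "scheme": scheme.name,
        "open_mixture": theoretical_dwell_mixture(scheme, conc, "open").to_dict(),
        "shut_mixture": theoretical_dwell_mixture(scheme, conc, "shut").to_dict(),
        "dead_time_ms": config.dead_time_ms,
        "file_seeds": file_seeds,
        "seed": config.seed,
    }
    return {"files": files, "truth": truth}


@dataclass(frozen=True)
class DoseResponseConfig:
    """Hill-curve replicate table; defaults are the P4S calibration."""

    ec50_m: float = 46e-6
    hill_n: float = 1.4
    r_max: float = 1.0
    concentrations_m: tuple[float, ...] = tuple(
        float(c) for c in np.geomspace(1e-6, 3e-3, 8))
    n_replicates: int = 5
    noise_sd: float = 0.05  # multiplicative Gaussian
    seed: int = 42

    def __post_init__(self):
        c = np.asarray(self.concentrations_m)
        if not (c.min() < self.ec50_m < c.max()):
            raise ValueError("concentrations must span the configured EC50")


def make_dose_response(config: DoseResponseConfig | None = None) -> dict:
    """Replicate dose-response table with multiplicative Gaussian noise."""
    config = config or DoseResponseConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    conc = np.asarray(config.concentrations_m)
    mean = hill_response(conc, config.ec50_m, config.hill_n, config.r_max)
    rows = []
    for rep in range(config.n_replicates):
        noisy = mean * (1.0 + rng.normal(0.0, config.noise_sd, conc.size))
        noisy = np.clip(noisy, 0.0, None)
        for c, r in zip(conc, noisy):
            rows.append({"concentration_M": c, "replicate": rep, "response": r})
    table = pd.DataFrame(rows)
    truth = {
        "ec50_m": config.ec50_m,
        "hill_n": config.hill_n,
        "r_max": config.r_max,
        "noise_sd": config.noise_sd,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }
    flagged = np.unique(conc).size < 4
    return {"table": table, "truth": truth, "flagged": flagged}
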