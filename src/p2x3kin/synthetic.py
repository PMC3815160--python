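"""Seeded synthetic current traces with known ground truth.

Stands in for recorded whole-cell currents: every other module is testable
against traces whose generating rate constants are known exactly.  Noise is
additive i.i.d. Gaussian with a standard deviation expressed as a fraction
of the control peak amplitude — a proxy for recording noise; baseline drift,
capacitive transients and series-resistance error are deliberately not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import RateParameters
from .protocols import (
    ApplicationProtocol,
    CurrentTrace,
    DEFAULT_SAMPLING_RATE,
    DEFAULT_TAU_EXCHANGE,
    make_steady_state_protocol,
    make_time_grid,
    occupancy_to_current,
    simulate_occupancy,
    simulate_protocol_sequence,
)

__all__ = ["SyntheticSpec", "RecoveryDataset", "generate_trace", "generate_recovery_dataset"]


@dataclass
class SyntheticSpec:
    """Everything needed to generate one trace reproducibly."""

    params: RateParameters
    protocol: ApplicationProtocol
    noise_sd: float = 0.02          # fraction of the noiseless peak amplitude
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    background_rate: float = 20.0
    scale: float = 1.0              # current units per unit open probability
    seed: int = 0
    desensitization_on: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def generate_trace(spec: SyntheticSpec, *, rtol: float = 1e-8, atol: float = 1e-10) -> CurrentTrace:
    """Simulate, render and (optionally) add seeded Gaussian noise.

    The noise SD is ``noise_sd`` times the trace's own noiseless peak |I|,
    and the metadata block records the generating truth.
    """
    grid = make_time_grid(spec.protocol, spec.sampling_rate, spec.background_rate)
    t, P = simulate_occupancy(
        spec.params, spec.protocol, grid,
        desensitization_on=spec.desensitization_on, rtol=rtol, atol=atol,
    )
    trace = occupancy_to_current(t, P, spec.scale, sampling_rate=spec.sampling_rate)
    peak = float(np.max(np.abs(trace.I)))
    if spec.noise_sd > 0 and peak > 0:
        rng = np.random.default_rng(spec.seed)
        trace.I = trace.I + rng.normal(0.0, spec.noise_sd * peak, size=trace.I.shape)
    trace.metadata = {
        "protocol": spec.protocol.name,
        "agonist_conc_uM": spec.protocol.agonist_conc,
        "antagonist_conc_uM": spec.protocol.antagonist_conc,
        "noise_sd": spec.noise_sd,
        "scale": spec.scale,
        "seed": spec.seed,
        "truth": spec.params.to_dict(),
    }
    return trace


@dataclass
class RecoveryDataset:
    """Bundle of steady-state-protocol traces plus a truth manifest."""

    traces: list[CurrentTrace]
    protocols: list[ApplicationProtocol]
    manifest: dict = field(default_factory=dict)


def generate_recovery_dataset(
    true_params: RateParameters,
    antagonist_concs: Sequence[float],
    *,
    agonist_conc: float = 10.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    scale: float = 1.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    background_rate: float = 20.0,
    chained: bool = True,
    gap: float = 300.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RecoveryDataset:
    """Steady-state-protocol dataset: one control run plus one run per level.

    Runs are simulated back to back from one virtual cell (state carried
    across 5-min drug-free gaps) in ascending antagonist order, as in the
    experimental series.  The noise SD for every run is ``noise_sd`` times
    the control run's peak amplitude; per-run noise streams are spawned from
    ``seed`` so the bundle is byte-reproducible from its manifest.
    """
    levels = [0.0] + sorted(float(b) for b in antagonist_concs if b > 0)
    protocols = [make_steady_state_protocol(agonist_conc, b, tau=tau) for b in levels]
    grids = [make_time_grid(p, sampling_rate, background_rate) for p in protocols]
    if chained:
        results = simulate_protocol_sequence(
            true_params, protocols, gap=gap, t_grids=grids, rtol=rtol, atol=atol,
        )
    else:
        results = [
            simulate_occupancy(true_params, p, g, rtol=rtol, atol=atol)
            for p, g in zip(protocols, grids)
        ]
    clean = [occupancy_to_current(t, P, scale, sampling_rate=sampling_rate)
             for t, P in results]
    control_peak = float(np.max(np.abs(clean[0].I)))
    child_seeds = np.random.SeedSequence(seed).spawn(len(clean))
    traces = []
    for trace, prot, ss in zip(clean, protocols, child_seeds):
        if noise_sd > 0 and control_peak > 0:
            rng = np.random.default_rng(ss)
            trace.I = trace.I + rng.normal(0.0, noise_sd * control_peak, size=trace.I.shape)
        trace.metadata = {
            "protocol": prot.name,
            "agonist_conc_uM": prot.agonist_conc,
            "antagonist_conc_uM": prot.antagonist_conc,
            "noise_sd": noise_sd,
            "scale": scale,
            "seed": seed,
            "truth": true_params.to_dict(),
        }
        traces.append(trace)
    manifest = {
        "protocol": "steady_state",
        "agonist_conc_uM": agonist_conc,
        "antagonist_concs_uM": levels,
        "noise_sd": noise_sd,
        "seed": seed,
        "scale": scale,
        "tau_exchange_s": tau,
        "sampling_rate_hz": sampling_rate,
        "background_rate_hz": background_rate,
        "chained": chained,
        "gap_s": gap,
        "truth": true_params.to_dict(),
    }
    return RecoveryDataset(traces, protocols, manifest)
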