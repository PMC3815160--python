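"""Antagonist rate estimation and equilibrium/thermodynamic conversions.

With the agonist and gating rates fixed (they are determined separately from
agonist-only recordings), the scheme has exactly two free parameters: the
antagonist association rate k₁ and dissociation rate k₋₁.  They are
estimated by least squares between simulated and observed currents across
one or more protocol runs, searched in log-space from several starts.  The
equilibrium constant and binding energy follow as

    K_D = k₋₁ / k₁              (reported in nM)
    ΔG  = R·T·ln K_D[M]         (kJ/mol, negative for sub-molar K_D)

with standard deviations propagated from the rate-constant covariance by the
delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import RateParameters
from .protocols import (
    ApplicationProtocol,
    CurrentTrace,
    occupancy_to_current,
    simulate_occupancy,
    simulate_protocol_sequence,
)

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE",
    "FitResult",
    "compute_KD",
    "compute_dG",
    "propagate_sd",
    "fit_antagonist_rates",
]

R_GAS = 8.314  # J mol⁻¹ K⁻¹

#: room temperature of the recordings (K)
DEFAULT_TEMPERATURE = 295.0


def compute_KD(k1: float, k_minus1: float) -> float:
    """Equilibrium dissociation constant in nM from (µM⁻¹s⁻¹, s⁻¹) rates."""
    if k1 <= 0:
        raise ValueError("k1 must be positive to form K_D = k_minus1/k1")
    if k_minus1 < 0:
        raise ValueError("k_minus1 must be non-negative")
    return k_minus1 / k1 * 1e3  # µM → nM


def compute_dG(KD_nM: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy ΔG = RT·ln K_D (kJ/mol), K_D given in nM."""
    if KD_nM <= 0:
        raise ValueError("K_D must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_GAS * temperature * math.log(KD_nM * 1e-9) / 1000.0


def propagate_sd(
    covariance: np.ndarray,
    k1: float,
    k_minus1: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float]:
    """Delta-method SDs of K_D (nM) and ΔG (kJ/mol) from the rate covariance.

    ``covariance`` is the 2×2 covariance of (k1, k_minus1) on the linear
    scale.  First-order propagation through K_D = k₋₁/k₁ and ΔG = RT ln K_D.
    """
    C = np.asarray(covariance, dtype=float)
    if C.shape != (2, 2):
        raise ValueError("covariance must be 2x2 over (k1, k_minus1)")
    eig = np.linalg.eigvalsh((C + C.T) / 2)
    if eig.min() < -1e-12 * max(1.0, eig.max()):
        raise ValueError("covariance must be positive semi-definite")
    KD = compute_KD(k1, k_minus1)
    g_kd = np.array([-KD / k1, 1e3 / k1])  # dKD/dk1, dKD/dk_minus1 (nM units)
    var_kd = float(g_kd @ C @ g_kd)
    rt = R_GAS * temperature / 1000.0
    if k_minus1 > 0:
        g_dg = np.array([-rt / k1, rt / k_minus1])
        var_dg = float(g_dg @ C @ g_dg)
    else:
        var_dg = np.inf
    return math.sqrt(max(var_kd, 0.0)), math.sqrt(max(var_dg, 0.0))


@dataclass
class FitResult:
    """Estimated antagonist rates with uncertainties and derived quantities."""

    k1_hat: float                 # µM⁻¹ s⁻¹
    k_minus1_hat: float           # s⁻¹
    sd_k1: float
    sd_k_minus1: float
    KD: float                     # nM
    sd_KD: float
    dG: float                     # kJ/mol
    sd_dG: float
    residual_norm: float
    n_traces: int
    converged: bool
    covariance: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    n_evaluations: int = 0


class UnidentifiableError(ValueError):
    """Raised when the supplied protocols carry no antagonist information."""


def fit_antagonist_rates(
    traces: Sequence[CurrentTrace],
    protocols: Sequence[ApplicationProtocol],
    fixed_params: RateParameters,
    initial_guess: tuple[float, float] = (1.0, 0.1),
    *,
    scale: float | None = None,
    chained: bool = True,
    gap: float = 300.0,
    n_starts: int = 3,
    start_spread: float = 10.0,
    weights: Sequence[float] | None = None,
    desensitization_on: bool = True,
    temperature: float = DEFAULT_TEMPERATURE,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_nfev: int = 100,
) -> FitResult:
    """Fit (k1, k₋₁) to one or more current traces by trust-region least squares.

    Every rate except the antagonist pair is taken from ``fixed_params``.
    ``chained=True`` re-simulates the runs sequentially with ``gap``-second
    drug-free intervals carrying the receptor state, matching how series of
    runs are recorded from one cell.  ``n_starts`` log-spaced multi-starts
    (factors ``start_spread**(-1,0,+1,…)`` on the initial guess) guard
    against local minima; the best final cost wins.  Deterministic given the
    data and the initial guess.
    """
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    if len(traces) != len(protocols):
        raise ValueError("traces and protocols must correspond one-to-one")
    if all(p.antagonist_profile.max_target == 0 for p in protocols):
        raise UnidentifiableError(
            "antagonist concentration is zero in every run: "
            "k1 and k_minus1 are unidentifiable"
        )
    if scale is None:
        scale = traces[0].metadata.get("scale")
        if scale is None:
            raise ValueError("current scale must be given or present in trace metadata")
    w = np.ones(len(traces)) if weights is None else np.asarray(weights, float)
    if w.shape != (len(traces),) or np.any(w < 0):
        raise ValueError("weights must be one non-negative value per trace")
    t_grids = [tr.t for tr in traces]
    observed = np.concatenate([tr.I * wi for tr, wi in zip(traces, w)])
    n_eval = 0

    def simulate(k1: float, k_minus1: float) -> np.ndarray:
        params = replace(fixed_params, k1=k1, k_minus1=k_minus1)
        if chained:
            results = simulate_protocol_sequence(
                params, protocols, gap=gap, t_grids=t_grids,
                desensitization_on=desensitization_on, rtol=rtol, atol=atol,
            )
        else:
            results = [
                simulate_occupancy(
                    params, prot, grid,
                    desensitization_on=desensitization_on, rtol=rtol, atol=atol,
                )
                for prot, grid in zip(protocols, t_grids)
            ]
        return np.concatenate([
            occupancy_to_current(t, P, scale).I * wi
            for (t, P), wi in zip(results, w)
        ])

    def residuals(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        return simulate(math.exp(x[0]), math.exp(x[1])) - observed

    # two-phase multi-start: short, loosely converged runs from each start,
    # then one fully converged polish from the best exploration endpoint
    x0 = np.log(np.asarray(initial_guess, dtype=float))
    offsets = np.arange(n_starts) - (n_starts - 1) / 2.0
    best = None
    for off in offsets:
        res = least_squares(
            residuals, x0 + off * math.log(start_spread),
            method="trf", max_nfev=25, ftol=1e-6, xtol=1e-6, x_scale=1.0,
            diff_step=1e-3,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    best = least_squares(
        residuals, best.x, method="trf", max_nfev=max_nfev, x_scale=1.0,
        diff_step=1e-3,
    )
    k1_hat, km1_hat = float(np.exp(best.x[0])), float(np.exp(best.x[1]))

    # covariance of log-rates from the Gauss-Newton approximation, then
    # transformed to the linear scale
    J = best.jac
    dof = max(observed.size - 2, 1)
    s2 = 2.0 * best.cost / dof
    JTJ = J.T @ J
    try:
        cov_log = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov_log = s2 * np.linalg.pinv(JTJ)
    D = np.diag([k1_hat, km1_hat])
    cov = D @ cov_log @ D
    sd_k1, sd_km1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    KD = compute_KD(k1_hat, km1_hat)
    dG = compute_dG(KD, temperature)
    sd_KD, sd_dG = propagate_sd(cov, k1_hat, km1_hat, temperature)
    return FitResult(
        k1_hat=k1_hat,
        k_minus1_hat=km1_hat,
        sd_k1=sd_k1,
        sd_k_minus1=sd_km1,
        KD=KD,
        sd_KD=sd_KD,
        dG=dG,
        sd_dG=sd_dG,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_traces=len(traces),
        converged=bool(best.status > 0),
        covariance=cov,
        temperature=temperature,
        n_evaluations=n_eval,
    )
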