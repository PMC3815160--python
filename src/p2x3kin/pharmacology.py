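"""Derived pharmacology: inhibition curves, Hill fits, Schild analysis,
recovery/overshoot/protection metrics.

The Schild demonstration is the centrepiece: for a purely competitive
antagonist at equilibrium, agonist concentration–response curves shift in
parallel by the dose ratio dr = 1 + [B]/K_B, so the regression of
log₁₀(dr−1) on log₁₀[B] has slope 1 and x-intercept −pA₂ = log₁₀ K_B.  Fast
desensitization destroys the required equilibrium: the peak current is
truncated before agonist and antagonist re-equilibrate, the fitted maxima
drop with antagonist concentration and the shift is no longer parallel —
reproducing why classical Schild analysis misclassifies competitive blockers
at this receptor.  Switching the desensitized tier off restores textbook
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import RateParameters
from .protocols import (
    ApplicationProtocol,
    ConcentrationProfile,
    CurrentTrace,
    DEFAULT_TAU_EXCHANGE,
    make_steady_state_protocol,
    make_time_grid,
    occupancy_to_current,
    simulate_occupancy,
    sweep_peaks,
)

__all__ = [
    "HillFit",
    "SchildResult",
    "SchildAnalysis",
    "ProtectionIndex",
    "concentration_inhibition_curve",
    "fit_hill",
    "schild_analysis",
    "recovery_ratio",
    "overshoot_metric",
    "protection_index",
]


@dataclass
class HillFit:
    """Three-parameter Hill fit: midpoint, slope coefficient, plateau."""

    ic50: float              # midpoint concentration, µM (EC50 for activation fits)
    hill_coefficient: float
    top: float               # response plateau
    residual: float
    direction: str           # "inhibition" or "activation"
    well_determined: bool = True

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, (conc / self.ic50) ** self.hill_coefficient, 0.0)
        if self.direction == "inhibition":
            return self.top / (1.0 + ratio)
        return self.top * ratio / (1.0 + ratio)


def fit_hill(conc, response, direction: str = "auto") -> HillFit:
    """Least-squares three-parameter Hill fit.

    ``direction="inhibition"`` fits top/(1+(x/ic50)^h); ``"activation"`` fits
    the rising counterpart with ic50 playing the role of EC50.  ``"auto"``
    picks the direction from the ends of the sorted data.  Data that show no
    transition at all are rejected; data that do not span the half-maximal
    level are fitted but flagged as poorly determined.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape or conc.size < 4:
        raise ValueError("need at least 4 (conc, response) pairs")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    order = np.argsort(conc)
    c, r = conc[order], response[order]
    span = float(np.ptp(r))
    top0 = float(np.max(np.abs(r)))
    if top0 == 0 or span < 1e-9 * top0:
        raise ValueError("responses show no transition; Hill fit is rejected")
    if direction == "auto":
        direction = "inhibition" if r[-1] < r[0] else "activation"
    if direction not in ("inhibition", "activation"):
        raise ValueError("direction must be 'inhibition', 'activation' or 'auto'")

    # midpoint guess: first crossing of the half-maximal level
    half = top0 / 2.0
    pos = c[c > 0]
    mid0 = float(np.sqrt(pos[0] * pos[-1])) if pos.size else 1.0
    crossing = np.nonzero((r[:-1] - half) * (r[1:] - half) <= 0)[0]
    if crossing.size and c[crossing[0]] > 0:
        mid0 = float(np.sqrt(c[crossing[0]] * max(c[crossing[0] + 1], c[crossing[0]])))

    def model(x):
        mid, h, top = np.exp(x[0]), np.exp(x[1]), x[2]
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / mid) ** h, 0.0)
        return top / (1.0 + ratio) if direction == "inhibition" else top * ratio / (1.0 + ratio)

    def fun(x):
        return model(x) - r

    x0 = np.array([np.log(mid0), 0.0, top0])
    res = least_squares(fun, x0, method="lm", max_nfev=2000)
    mid, h, top = float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(res.x[2])
    # well determined only if the data actually cross the half-maximal level
    rel = r / top if top != 0 else r
    spans_half = rel.min() < 0.5 < rel.max()
    return HillFit(
        ic50=mid,
        hill_coefficient=h,
        top=top,
        residual=float(np.sqrt(2.0 * res.cost)),
        direction=direction,
        well_determined=bool(spans_half),
    )


# ---------------------------------------------------------------------------
# concentration–inhibition


def concentration_inhibition_curve(
    params: RateParameters,
    antagonist_concs: Sequence[float],
    *,
    agonist_conc: float = 10.0,
    pulse_index: int = 0,
    scale: float = 1.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
    sampling_rate: float = 1000.0,
    desensitization_on: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized peak response versus antagonist concentration.

    Each level is simulated as an independent steady-state-protocol run from
    rest; the response is the peak |I| of pulse ``pulse_index`` normalized to
    the control (zero-antagonist) run, which must be included in the grid.
    """
    concs = np.asarray(antagonist_concs, dtype=float)
    if not np.any(concs == 0):
        raise ValueError("the concentration grid must include 0 (control) for normalization")
    peaks = []
    for b in concs:
        prot = make_steady_state_protocol(agonist_conc, float(b), tau=tau)
        t, P = simulate_occupancy(
            params, prot, make_time_grid(prot, sampling_rate),
            desensitization_on=desensitization_on, rtol=rtol, atol=atol,
        )
        trace = occupancy_to_current(t, P, scale)
        peaks.append(sweep_peaks(trace, prot.sweeps)[pulse_index])
    peaks = np.asarray(peaks)
    control = peaks[concs == 0][0]
    if control <= 0:
        raise ValueError("control response is zero; cannot normalize")
    return concs, peaks / control


# ---------------------------------------------------------------------------
# Schild analysis


@dataclass
class SchildResult:
    antagonist_concs: np.ndarray   # µM, nonzero levels
    dose_ratios: np.ndarray
    pA2: float
    slope: float
    r_squared: float


@dataclass
class SchildAnalysis:
    result: SchildResult | None
    curves: pd.DataFrame           # columns: antagonist_conc, agonist_conc, response
    hill_fits: list[HillFit]       # one activation fit per antagonist level
    desensitization_on: bool


DEFAULT_AGONIST_GRID = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
DEFAULT_ANTAGONIST_GRID = (0.0, 0.1, 0.3, 1.0, 3.0)


def _single_pulse_protocol(
    agonist_conc: float,
    antagonist_conc: float,
    pre_application: float,
    pulse_duration: float,
    tau: float,
) -> ApplicationProtocol:
    """Antagonist pre-equilibration followed by one agonist test pulse."""
    on = pre_application
    off = on + pulse_duration
    ag = ConcentrationProfile(((on, agonist_conc), (off, 0.0)), tau=tau)
    ant = ConcentrationProfile(((0.0, antagonist_conc), (off, 0.0)), tau=tau)
    return ApplicationProtocol(
        "schild_pulse", ag, ant, ((on - 0.2, off + 0.5),), off + 1.0,
        agonist_conc, antagonist_conc,
    )


def schild_analysis(
    params: RateParameters,
    agonist_concs: Sequence[float] = DEFAULT_AGONIST_GRID,
    antagonist_concs: Sequence[float] = DEFAULT_ANTAGONIST_GRID,
    desensitization_on: bool = True,
    *,
    pre_application: float = 30.0,
    pulse_duration: float | None = None,
    scale: float = 1.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
    sampling_rate: float = 500.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SchildAnalysis:
    """Simulate agonist CRC families across antagonist levels and regress.

    Per (B, A) pair one single-pulse run is simulated from rest (antagonist
    pre-applied for ``pre_application`` s); the response is the peak |I| of
    the pulse.  Each level's curve gets an activation Hill fit; dose ratios
    come from the EC50 shifts and feed an ordinary least-squares Schild
    regression of log₁₀(dr−1) on log₁₀[B in M].  With fewer than two usable
    nonzero levels the regression is skipped (``result=None``).
    """
    ant_concs = np.asarray(antagonist_concs, dtype=float)
    if 0.0 not in ant_concs:
        raise ValueError("antagonist grid must include 0 as the reference curve")
    if pulse_duration is None:
        # the pulse must outlast antagonist unbinding (the slowest
        # re-equilibration step) for peak responses to reach the
        # agonist/antagonist equilibrium when desensitization is off
        pulse_duration = max(10.0, 8.0 / params.k_minus1) if params.k_minus1 > 0 else 10.0
    def peak_response(a: float, b: float) -> float:
        prot = _single_pulse_protocol(a, b, pre_application, pulse_duration, tau)
        t, P = simulate_occupancy(
            params, prot, make_time_grid(prot, sampling_rate, background_rate=5.0),
            desensitization_on=desensitization_on, rtol=rtol, atol=atol,
        )
        return sweep_peaks(occupancy_to_current(t, P, scale), prot.sweeps)[0]

    # order levels control-first so the reference EC50 is available
    order = np.argsort(ant_concs)
    base = np.asarray(agonist_concs, dtype=float)
    rows = []
    fits_by_conc: dict[float, HillFit] = {}
    rel_grid = None
    for b in ant_concs[order]:
        concs = base
        responses = [peak_response(a, float(b)) for a in concs]
        fit = fit_hill(concs, responses, direction="activation")
        if b == 0.0:
            rel_grid = base / fit.ic50
        else:
            # second pass: sample the shifted curve at the same positions
            # relative to its own EC50 as the control, so the fitted maxima
            # are comparable across antagonist levels (the curves are not
            # exactly Hill-shaped, which otherwise biases extrapolated tops)
            concs = rel_grid * fit.ic50
            responses = [peak_response(a, float(b)) for a in concs]
            fit = fit_hill(concs, responses, direction="activation")
        fits_by_conc[float(b)] = fit
        rows.extend(
            {"antagonist_conc": b, "agonist_conc": a, "response": r}
            for a, r in zip(concs, responses)
        )
    fits = [fits_by_conc[float(b)] for b in ant_concs]
    curves = pd.DataFrame(rows)

    ec50_0 = fits[list(ant_concs).index(0.0)].ic50
    nonzero = ant_concs[ant_concs > 0]
    dr = np.array([
        fits[i].ic50 / ec50_0 for i, b in enumerate(ant_concs) if b > 0
    ])
    # dose ratios indistinguishable from 1 (no measurable EC50 shift) carry
    # no information for the regression
    usable = dr > 1.05
    result = None
    if usable.sum() >= 2:
        x = np.log10(nonzero[usable] * 1e-6)  # µM → M
        y = np.log10(dr[usable] - 1.0)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        pA2 = float(intercept / slope)
        result = SchildResult(nonzero, dr, pA2, float(slope), r2)
    return SchildAnalysis(result, curves, fits, desensitization_on)


# ---------------------------------------------------------------------------
# protocol-derived metrics


def recovery_ratio(trace: CurrentTrace, sweeps: Sequence[tuple[float, float]]) -> np.ndarray:
    """Peak of each agonist pulse relative to the first pulse of the run."""
    peaks = sweep_peaks(trace, sweeps)
    if peaks[0] <= 0:
        raise ValueError("first-pulse peak is zero; recovery ratio undefined")
    return peaks / peaks[0]


def overshoot_metric(
    trace: CurrentTrace,
    sweeps: Sequence[tuple[float, float]],
    *,
    plateau_pulses: tuple[int, ...] = (5, 6, 7),
    post_pulses: Sequence[int] | None = None,
) -> float:
    """Post-washout peak over pre-antagonist plateau (dynamic protocol).

    ``plateau_pulses`` are 1-based pulse numbers averaged for the run-down
    plateau (the train is stable from about the fourth pulse onwards);
    ``post_pulses`` defaults to every pulse after the antagonist episode
    (14th onward for the canonical 8–13 block).  A ratio above 1 is an
    overshoot: receptors occupied by a quickly dissociating antagonist were
    protected from desensitization and become available at once.
    """
    peaks = sweep_peaks(trace, sweeps)
    if post_pulses is None:
        post_pulses = range(14, len(sweeps) + 1)
    plateau = np.mean([peaks[i - 1] for i in plateau_pulses])
    if plateau <= 0:
        raise ValueError("plateau amplitude is zero; overshoot undefined")
    post = max(peaks[i - 1] for i in post_pulses)
    return float(post / plateau)


@dataclass
class ProtectionIndex:
    s4_over_s2: float
    s7_over_s2: float

    @property
    def protected(self) -> bool:
        return self.s4_over_s2 > self.s7_over_s2


def protection_index(trace: CurrentTrace, sweeps: Sequence[tuple[float, float]]) -> ProtectionIndex:
    """Compare responses after antagonist applied to occupied vs vacant receptors.

    For the protection protocol the six sweeps are S1–S5 and S7.  The
    antagonist follows the S3 agonist pulse (sites still agonist-occupied or
    desensitized) and precedes S7 at S6 (sites vacant).  Protection of the
    shared binding site shows as S4/S2 exceeding S7/S2.
    """
    peaks = sweep_peaks(trace, sweeps)
    if len(peaks) != 6:
        raise ValueError("protection protocol provides six agonist sweeps (S1–S5, S7)")
    s2 = peaks[1]
    if s2 <= 0:
        raise ValueError("S2 response is zero; protection index undefined")
    return ProtectionIndex(float(peaks[3] / s2), float(peaks[5] / s2))
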