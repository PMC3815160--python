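"""Drug-application protocols, master-equation integration and current readout.

Concentration profiles are piecewise relaxations toward a target level with a
single solution-exchange time constant τ (the measured speed of the
superfusion system); τ=0 gives rectangular steps.  Occupancy evolves by
``dP/dt = Qᵀ(t)·P`` with the generator rebuilt from the instantaneous
concentrations; the macroscopic current is the summed open-state probability
scaled into (inward-negative) current units.

The four canonical application protocols:

* steady-state — antagonist superfusion with three 2-s agonist pulses at
  28/32/94 s (2-s and 60-s gaps): concentration–inhibition and recovery.
* wash-out — 20 s antagonist, then a 10-s agonist pulse after a variable
  delay: direct view of antagonist dissociation.
* dynamic — 25 × 1-s agonist pulses at 1-min intervals, antagonist present
  during pulses 8–13: onset/offset of block, run-down and overshoot.
* protection — seven 5-min-spaced time points S1–S7, agonist at S1–S5 and S7,
  antagonist immediately after S3 and at S6: shared-binding-site test for
  slowly dissociating blockers.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model import (
    RESTING_INDEX,
    GeneratorParts,
    RateParameters,
    build_generator_parts,
    enumerate_states,
)

__all__ = [
    "DEFAULT_TAU_EXCHANGE",
    "ConcentrationProfile",
    "ApplicationProtocol",
    "CurrentTrace",
    "concentration_at",
    "make_time_grid",
    "simulate_occupancy",
    "simulate_protocol_sequence",
    "occupancy_to_current",
    "open_probability",
    "sweep_peaks",
    "make_steady_state_protocol",
    "make_washout_protocol",
    "make_dynamic_protocol",
    "make_protection_protocol",
]

#: default solution-exchange time constant (s); configurable everywhere
DEFAULT_TAU_EXCHANGE = 0.05

#: default digitization rate for rendered traces (Hz)
DEFAULT_SAMPLING_RATE = 2000.0


@dataclass(frozen=True)
class ConcentrationProfile:
    """Piecewise-exponential ligand concentration (µM) versus time (s).

    ``steps`` lists (switch_time, target) pairs with strictly increasing
    times; between switches the concentration relaxes exponentially from its
    value at the switch toward the active target with time constant ``tau``,
    so the trajectory is continuous across switches.
    """

    steps: tuple[tuple[float, float], ...]
    tau: float = DEFAULT_TAU_EXCHANGE
    c0: float = 0.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        if any(c < 0 for _, c in self.steps) or self.c0 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        # concentration reached at each switch instant (continuity)
        start = [self.c0]
        for (t_a, target), (t_b, _) in zip(self.steps, self.steps[1:]):
            start.append(self._relax(start[-1], target, t_b - t_a))
        object.__setattr__(self, "_switch_start", tuple(start))
        object.__setattr__(self, "_switch_times", tuple(times))

    def _relax(self, c_from: float, target: float, dt: float) -> float:
        if self.tau == 0.0:
            return target
        return target + (c_from - target) * np.exp(-dt / self.tau)

    @property
    def switch_times(self) -> tuple[float, ...]:
        return self._switch_times  # type: ignore[attr-defined]

    def value(self, t):
        """Concentration at time(s) ``t`` (scalar or array)."""
        if np.ndim(t) == 0:
            return self._scalar(float(t))
        t = np.asarray(t, dtype=float)
        return np.array([self._scalar(x) for x in t])

    def _scalar(self, t: float) -> float:
        i = bisect_right(self._switch_times, t) - 1  # type: ignore[attr-defined]
        if i < 0:
            return self.c0
        target = self.steps[i][1]
        if self.tau == 0.0:
            return target
        c_start = self._switch_start[i]  # type: ignore[attr-defined]
        return self._relax(c_start, target, t - self._switch_times[i])  # type: ignore[attr-defined]

    @property
    def max_target(self) -> float:
        return max((c for _, c in self.steps), default=self.c0)


def concentration_at(profile: ConcentrationProfile, t) -> float:
    """Concentration (µM) of ``profile`` at time ``t`` (s)."""
    return profile.value(t)


def _pulse_profile(conc: float, intervals: Sequence[tuple[float, float]],
                   tau: float) -> ConcentrationProfile:
    steps: list[tuple[float, float]] = []
    for on, off in intervals:
        steps.append((on, conc))
        steps.append((off, 0.0))
    return ConcentrationProfile(tuple(steps), tau=tau)


@dataclass(frozen=True)
class ApplicationProtocol:
    """A named pair of agonist/antagonist profiles plus per-sweep windows."""

    name: str
    agonist_profile: ConcentrationProfile
    antagonist_profile: ConcentrationProfile
    sweeps: tuple[tuple[float, float], ...]
    t_end: float
    agonist_conc: float = 0.0
    antagonist_conc: float = 0.0
    metadata: dict = field(default_factory=dict)


@dataclass
class CurrentTrace:
    """Sampled macroscopic current: time (s), signed current (inward < 0)."""

    t: np.ndarray
    I: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("time and current arrays must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")


# ---------------------------------------------------------------------------
# protocol builders


def make_steady_state_protocol(
    agonist_conc: float,
    antagonist_conc: float,
    *,
    pulse_starts: tuple[float, ...] = (28.0, 32.0, 94.0),
    pulse_duration: float = 2.0,
    antagonist_start: float = 0.0,
    antagonist_duration: float = 110.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
    t_end: float = 125.0,
) -> ApplicationProtocol:
    """Antagonist superfusion with three short agonist test pulses.

    Defaults: antagonist from t=0 for 110 s; 2-s agonist pulses starting at
    28, 32 and 94 s, i.e. separated by a 2-s and a 60-s gap.  With
    ``antagonist_conc=0`` this is the control run of the series.
    """
    if agonist_conc < 0 or antagonist_conc < 0:
        raise ValueError("concentrations must be non-negative")
    ag = _pulse_profile(
        agonist_conc, [(s, s + pulse_duration) for s in pulse_starts], tau
    )
    ant = ConcentrationProfile(
        ((antagonist_start, antagonist_conc),
         (antagonist_start + antagonist_duration, 0.0)),
        tau=tau,
    )
    sweeps = tuple(
        (s - 0.5, s + pulse_duration + 1.5) for s in pulse_starts
    )
    return ApplicationProtocol(
        "steady_state", ag, ant, sweeps, t_end,
        agonist_conc, antagonist_conc,
        {"pulse_starts": list(pulse_starts), "pulse_duration": pulse_duration},
    )


def make_washout_protocol(
    agonist_conc: float,
    antagonist_conc: float,
    delay: float = 0.0,
    *,
    antagonist_duration: float = 20.0,
    agonist_duration: float = 10.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
) -> ApplicationProtocol:
    """20-s antagonist block, then a 10-s agonist pulse ``delay`` s after wash-out."""
    if delay < 0:
        raise ValueError("delay must be non-negative")
    ag_on = antagonist_duration + delay
    ag = _pulse_profile(agonist_conc, [(ag_on, ag_on + agonist_duration)], tau)
    ant = ConcentrationProfile(((0.0, antagonist_conc), (antagonist_duration, 0.0)), tau=tau)
    sweeps = ((ag_on - 0.5, ag_on + agonist_duration + 2.0),)
    return ApplicationProtocol(
        "washout", ag, ant, sweeps, ag_on + agonist_duration + 5.0,
        agonist_conc, antagonist_conc, {"delay": delay},
    )


def make_dynamic_protocol(
    agonist_conc: float,
    antagonist_conc: float,
    *,
    n_pulses: int = 25,
    pulse_duration: float = 1.0,
    interval: float = 60.0,
    antagonist_pulses: tuple[int, int] = (8, 13),
    tau: float = DEFAULT_TAU_EXCHANGE,
) -> ApplicationProtocol:
    """Repetitive 1-s agonist pulses at 1-min intervals with a block episode.

    The antagonist is present from the start of pulse ``antagonist_pulses[0]``
    to the end of pulse ``antagonist_pulses[1]`` (1-based, defaults 8–13,
    ≈5 min of superfusion).
    """
    starts = [i * interval for i in range(n_pulses)]
    ag = _pulse_profile(agonist_conc, [(s, s + pulse_duration) for s in starts], tau)
    first, last = antagonist_pulses
    if not (1 <= first <= last <= n_pulses):
        raise ValueError("antagonist_pulses must be 1-based indices within the train")
    ant = ConcentrationProfile(
        ((starts[first - 1], antagonist_conc),
         (starts[last - 1] + pulse_duration, 0.0)),
        tau=tau,
    )
    sweeps = tuple((s - 0.2, s + pulse_duration + 1.3) for s in starts)
    return ApplicationProtocol(
        "dynamic", ag, ant, sweeps, starts[-1] + pulse_duration + 4.0,
        agonist_conc, antagonist_conc,
        {"n_pulses": n_pulses, "interval": interval,
         "antagonist_pulses": list(antagonist_pulses)},
    )


def make_protection_protocol(
    agonist_conc: float,
    antagonist_conc: float,
    *,
    point_interval: float = 300.0,
    agonist_duration: float = 2.0,
    antagonist_duration: float = 5.0,
    tau: float = DEFAULT_TAU_EXCHANGE,
) -> ApplicationProtocol:
    """Seven 5-min-spaced points; agonist at S1–S5 and S7, antagonist after S3 and at S6.

    The antagonist pulse after S3 starts the moment the S3 agonist pulse
    ends; the S6 antagonist pulse has no preceding agonist application, so
    comparing the S4 and S7 responses tests whether prior agonist occupancy
    protects the binding sites.
    """
    s = [k * point_interval for k in range(7)]  # S1..S7
    ag_points = [s[0], s[1], s[2], s[3], s[4], s[6]]
    ag = _pulse_profile(agonist_conc, [(t, t + agonist_duration) for t in ag_points], tau)
    ant = ConcentrationProfile(
        ((s[2] + agonist_duration, antagonist_conc),
         (s[2] + agonist_duration + antagonist_duration, 0.0),
         (s[5], antagonist_conc),
         (s[5] + antagonist_duration, 0.0)),
        tau=tau,
    )
    sweeps = tuple((t - 0.5, t + agonist_duration + 1.5) for t in ag_points)
    return ApplicationProtocol(
        "protection", ag, ant, sweeps, s[6] + agonist_duration + 5.0,
        agonist_conc, antagonist_conc,
        {"point_interval": point_interval, "sweep_points": ["S1", "S2", "S3", "S4", "S5", "S7"]},
    )


# ---------------------------------------------------------------------------
# integration


def make_time_grid(
    protocol: ApplicationProtocol,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    background_rate: float = 20.0,
) -> np.ndarray:
    """Output grid: dense sampling inside sweep windows, sparse elsewhere."""
    pieces = [np.arange(0.0, protocol.t_end, 1.0 / background_rate),
              np.array([protocol.t_end])]
    for a, b in protocol.sweeps:
        a = max(a, 0.0)
        b = min(b, protocol.t_end)
        pieces.append(np.arange(a, b, 1.0 / sampling_rate))
    grid = np.unique(np.concatenate(pieces))
    # drop near-coincident points (< 1 µs apart) produced by window overlap
    keep = np.concatenate([[True], np.diff(grid) > 1e-6])
    return grid[keep]


def _integrate(
    parts: GeneratorParts,
    protocol: ApplicationProtocol,
    t_grid: np.ndarray,
    p0: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
) -> np.ndarray:
    """Segment-wise integration with solver restarts at every switch time."""
    Q0T = parts.Q0.T.copy()
    QAT = parts.QA.T.copy()
    QBT = parts.QB.T.copy()
    ag, ant = protocol.agonist_profile, protocol.antagonist_profile

    def qt(t: float) -> np.ndarray:
        return Q0T + ag._scalar(t) * QAT + ant._scalar(t) * QBT

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        return qt(t) @ p

    t_end = float(t_grid[-1])
    boundaries = sorted(
        {0.0, t_end}
        | {t for t in ag.switch_times if 0.0 < t < t_end}
        | {t for t in ant.switch_times if 0.0 < t < t_end}
    )
    P = np.empty((t_grid.size, p0.size))
    p = p0.copy()
    for a, b in zip(boundaries, boundaries[1:]):
        sol = solve_ivp(
            rhs, (a, b), p, method=method, rtol=rtol, atol=atol,
            jac=lambda t, _p: qt(t), dense_output=True,
        )
        if sol.status != 0:  # pragma: no cover - solver failure diagnostics
            raise RuntimeError(
                f"master-equation integration failed on [{a:.6g}, {b:.6g}] s: "
                f"{sol.message}"
            )
        mask = (t_grid >= a) & (t_grid < b) if b < t_end else (t_grid >= a)
        if mask.any():
            P[mask] = sol.sol(t_grid[mask]).T
        p = sol.y[:, -1]
    return P


def simulate_occupancy(
    params: RateParameters,
    protocol: ApplicationProtocol,
    t_grid: np.ndarray | None = None,
    initial: np.ndarray | None = None,
    *,
    desensitization_on: bool = True,
    desens_assignment=None,
    parts: GeneratorParts | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the master equation over one protocol.

    Returns ``(t, P)`` with ``P[i, j]`` the probability of state ``j`` at
    ``t[i]``.  The default initial condition puts all receptors in the
    resting closed, fully unbound state.
    """
    if parts is None:
        parts = build_generator_parts(params, desensitization_on, desens_assignment)
    n = len(parts.states)
    if initial is None:
        p0 = np.zeros(n)
        p0[RESTING_INDEX] = 1.0
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (n,) or not np.isclose(p0.sum(), 1.0, atol=1e-6):
            raise ValueError("initial distribution must be a probability vector over the states")
    if t_grid is None:
        t_grid = make_time_grid(protocol, sampling_rate)
    t_grid = np.asarray(t_grid, dtype=float)
    P = _integrate(parts, protocol, t_grid, p0, rtol, atol, method)
    return t_grid, P


def simulate_protocol_sequence(
    params: RateParameters,
    protocols: Sequence[ApplicationProtocol],
    *,
    gap: float = 300.0,
    t_grids: Sequence[np.ndarray] | None = None,
    desensitization_on: bool = True,
    desens_assignment=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate runs back to back, carrying the receptor state across runs.

    Between runs the cell sits in drug-free solution for ``gap`` seconds
    (default 5 min, the inter-run spacing of the experimental series); the
    drug-free stretch is propagated with a matrix exponential, so slow
    recovery from desensitization is carried faithfully rather than assuming
    a complete reset.
    """
    parts = build_generator_parts(params, desensitization_on, desens_assignment)
    n = len(parts.states)
    p = np.zeros(n)
    p[RESTING_INDEX] = 1.0
    gap_propagator = expm(parts.Q0.T * gap) if gap > 0 else None
    results = []
    for i, prot in enumerate(protocols):
        grid = None if t_grids is None else t_grids[i]
        if grid is None:
            grid = make_time_grid(prot, sampling_rate)
        grid = np.asarray(grid, dtype=float)
        P = _integrate(parts, prot, grid, p, rtol, atol, method)
        results.append((grid, P))
        p = P[-1]
        if gap_propagator is not None and i < len(protocols) - 1:
            # concentrations have decayed to ≈0 by t_end (builders end with a
            # zero target well before t_end), so the drug-free generator applies
            p = gap_propagator @ p
            p = np.clip(p, 0.0, None)
            p /= p.sum()
    return results


# ---------------------------------------------------------------------------
# current readout


def open_state_indices(states=None) -> np.ndarray:
    states = states if states is not None else enumerate_states()
    return np.array([i for i, s in enumerate(states) if s.mode == "open"])


def open_probability(P: np.ndarray, states=None) -> np.ndarray:
    """Total open-state probability per time point (equal weight per open state)."""
    return P[:, open_state_indices(states)].sum(axis=1)


def occupancy_to_current(
    t: np.ndarray,
    P: np.ndarray,
    scale: float = 1.0,
    states=None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    metadata: dict | None = None,
) -> CurrentTrace:
    """Render occupancy into a macroscopic current trace.

    ``I(t) = −scale · ΣP_open(t)``: inward current is negative, matching
    whole-cell recordings at negative holding potentials.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    I = -scale * open_probability(P, states)
    return CurrentTrace(np.asarray(t, float), I, sampling_rate, dict(metadata or {}))


def peak_amplitude(trace: CurrentTrace, window: tuple[float, float]) -> float:
    """Maximum |I| within a sweep window."""
    mask = (trace.t >= window[0]) & (trace.t <= window[1])
    if not mask.any():
        raise ValueError(f"no samples inside window {window}")
    return float(np.max(np.abs(trace.I[mask])))


def sweep_peaks(trace: CurrentTrace, sweeps: Sequence[tuple[float, float]]) -> np.ndarray:
    """Peak |I| for each sweep window of a protocol."""
    return np.array([peak_amplitude(trace, w) for w in sweeps])
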