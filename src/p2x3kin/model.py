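"""State space and generator matrix of the P2X3 competitive-antagonism scheme.

The trimeric P2X3 receptor carries three equivalent inter-subunit binding
sites.  Each site is vacant, agonist-bound or antagonist-bound, and the
receptor as a whole is in one of three gating modes: closed, open or
desensitized.  Opening requires at least two bound agonist molecules, so the
open mode supports only the occupancies (2A,0B), (2A,1B) and (3A,0B).  Full
enumeration gives 10 closed + 3 open + 10 desensitized = 23 states.

A competitive antagonist simply occupies a site and prevents agonist binding
there; it has no effect on gating.  Association rates are stoichiometric:
a state with ``v`` vacant sites binds agonist at ``v·a1·[A]`` and antagonist
at ``v·k1·[B]``; dissociation is proportional to the number of bound
molecules.  The master equation ``dP/dt = Qᵀ P`` uses the generator matrix
assembled here.  Because every concentration enters linearly, the generator
decomposes as ``Q([A],[B]) = Q0 + [A]·QA + [B]·QB`` with three constant
matrices, which makes time-varying-concentration integration cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components

__all__ = [
    "MODES",
    "OccupancyState",
    "RateParameters",
    "GeneratorParts",
    "GeneratorMatrix",
    "DESENS_CLASSES",
    "DEFAULT_DESENS_ASSIGNMENT",
    "enumerate_states",
    "build_generator_parts",
    "build_generator",
    "equilibrium_distribution",
    "binding_multinomial",
]

MODES = ("closed", "open", "desensitized")

#: number of ligand binding sites on the trimeric receptor
N_SITES = 3

#: open-mode occupancies: at least two agonists are required for gating
_OPEN_OCCUPANCIES = ((2, 0), (2, 1), (3, 0))


@dataclass(frozen=True, order=True)
class OccupancyState:
    """One receptor configuration: gating mode plus bound-ligand counts."""

    mode: str
    n_agonist: int
    n_antagonist: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown gating mode {self.mode!r}")
        if not (0 <= self.n_agonist <= N_SITES and 0 <= self.n_antagonist <= N_SITES):
            raise ValueError("ligand counts must be within 0..3")
        if self.n_agonist + self.n_antagonist > N_SITES:
            raise ValueError("at most 3 ligands can be bound")
        if self.mode == "open" and self.n_agonist < 2:
            raise ValueError("open states require at least two bound agonists")

    @property
    def n_vacant(self) -> int:
        return N_SITES - self.n_agonist - self.n_antagonist

    def __str__(self) -> str:  # e.g. "C(2A,1B)"
        return f"{self.mode[0].upper()}({self.n_agonist}A,{self.n_antagonist}B)"


def enumerate_states() -> tuple[OccupancyState, ...]:
    """Canonical ordered state list: mode-major, then n_agonist, then n_antagonist.

    Closed and desensitized modes carry all 10 occupancy combinations of the
    three sites; the open mode carries the three ≥2-agonist occupancies.
    """
    states: list[OccupancyState] = []
    for mode in MODES:
        if mode == "open":
            occ: Sequence[tuple[int, int]] = _OPEN_OCCUPANCIES
        else:
            occ = [
                (na, nb)
                for na in range(N_SITES + 1)
                for nb in range(N_SITES + 1 - na)
            ]
        states.extend(OccupancyState(mode, na, nb) for na, nb in occ)
    return tuple(states)


#: index of the resting state C(0A,0B) in the canonical ordering
RESTING_INDEX = 0

# ---------------------------------------------------------------------------
# rate constants


@dataclass(frozen=True)
class RateParameters:
    """All rate constants of the scheme.

    Units: association rates per µM per s, every other rate per s.  The
    defaults are documented wild-type placeholders (see docs/methods.md):
    agonist/gating values are chosen so that 10 µM agonist sits near the
    peak-response EC50 with millisecond activation, second-scale
    desensitization and minute-scale recovery; antagonist defaults are the
    TNP-ATP rates.  ``ties`` declares groups of rate names that share one
    value (the first member is authoritative); ``free`` names the rates that
    remain adjustable during antagonist fitting — everything else is locked.
    """

    a1: float = 10.0          # agonist association (µM⁻¹ s⁻¹)
    a_minus1: float = 50.0    # agonist dissociation, closed/open modes (s⁻¹)
    k1: float = 15.8          # antagonist association (µM⁻¹ s⁻¹)
    k_minus1: float = 0.056   # antagonist dissociation (s⁻¹)
    beta2: float = 100.0      # opening, diliganded (s⁻¹)
    alpha2: float = 150.0     # closing, diliganded (s⁻¹)
    beta3: float = 600.0      # opening, triliganded (s⁻¹)
    alpha3: float = 15.0      # closing, triliganded (s⁻¹)
    d1: float = 3.0           # desensitization from diliganded open (s⁻¹)
    d2: float = 3.0           # desensitization from triliganded open (s⁻¹)
    d3: float = 0.1           # desensitization from liganded closed (s⁻¹)
    d4: float = 0.5           # recovery, agonist-free desensitized → closed (s⁻¹)
    a_minus1_desens: float = 0.006  # agonist dissociation inside D (s⁻¹, rate-limits recovery)
    ties: tuple[tuple[str, ...], ...] = ()
    free: tuple[str, ...] = ("k1", "k_minus1")

    _RATE_NAMES = (
        "a1", "a_minus1", "k1", "k_minus1", "beta2", "alpha2", "beta3",
        "alpha3", "d1", "d2", "d3", "d4", "a_minus1_desens",
    )

    def __post_init__(self) -> None:
        for name in self._RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be non-negative")
        known = set(self._RATE_NAMES)
        for group in self.ties:
            unknown = set(group) - known
            if unknown:
                raise ValueError(f"tie group references unknown rates: {sorted(unknown)}")
        if set(self.free) - known:
            raise ValueError("free rates must be rate-constant names")

    def resolve_ties(self) -> "RateParameters":
        """Return parameters with each tie group set to its first member's value."""
        if not self.ties:
            return self
        updates = {}
        for group in self.ties:
            value = getattr(self, group[0])
            for name in group[1:]:
                updates[name] = value
        return replace(self, **updates) if updates else self

    def with_antagonist(self, k1: float, k_minus1: float) -> "RateParameters":
        return replace(self, k1=k1, k_minus1=k_minus1)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._RATE_NAMES}


# published antagonist rate constants for the wild-type receptor
TNP_ATP = {"k1": 15.8, "k_minus1": 0.056}
A317491 = {"k1": 6.7, "k_minus1": 0.47}
#: PPADS placeholder: association sized to the minute-scale block onset at
#: 10 µM; dissociation effectively zero on protocol timescales
#: (pseudo-irreversible).  The ratio is deliberately not anchored to an
#: equilibrium constant — equilibrium analysis is meaningless for this blocker.
PPADS = {"k1": 0.002, "k_minus1": 1e-4}

ANTAGONIST_PRESETS = {"tnp-atp": TNP_ATP, "a317491": A317491, "ppads": PPADS}


def wt_params(antagonist: str | Mapping[str, float] = "tnp-atp") -> RateParameters:
    """Wild-type placeholder parameter set with a chosen antagonist's rates."""
    if isinstance(antagonist, str):
        try:
            rates = ANTAGONIST_PRESETS[antagonist.lower()]
        except KeyError:
            raise ValueError(
                f"unknown antagonist preset {antagonist!r}; "
                f"choose from {sorted(ANTAGONIST_PRESETS)}"
            ) from None
    else:
        rates = dict(antagonist)
    return RateParameters(k1=rates["k1"], k_minus1=rates["k_minus1"])


# ---------------------------------------------------------------------------
# desensitization topology

#: source-state classes a d-rate can be assigned to
DESENS_CLASSES = (
    "open_diliganded",   # O(2A,·) → D(same occupancy)
    "open_triliganded",  # O(3A,0B) → D(3A,0B)
    "closed_liganded",   # C(n_a≥2,·) → D(same occupancy)
    "recovery",          # D(0A,·) → C(0A,·)
)

DEFAULT_DESENS_ASSIGNMENT: Mapping[str, str] = {
    "open_diliganded": "d1",
    "open_triliganded": "d2",
    "closed_liganded": "d3",
    "recovery": "d4",
}


def _validate_assignment(assignment: Mapping[str, str]) -> Mapping[str, str]:
    for cls, rate in assignment.items():
        if cls not in DESENS_CLASSES:
            raise ValueError(
                f"unknown desensitization class {cls!r}; known: {DESENS_CLASSES}"
            )
        if rate not in RateParameters._RATE_NAMES:
            raise ValueError(f"unknown rate name {rate!r} in desensitization map")
    return assignment


# ---------------------------------------------------------------------------
# generator assembly


@dataclass(frozen=True)
class GeneratorParts:
    """Concentration decomposition Q([A],[B]) = Q0 + [A]·QA + [B]·QB."""

    states: tuple[OccupancyState, ...]
    Q0: np.ndarray
    QA: np.ndarray
    QB: np.ndarray
    desensitization_on: bool

    def at(self, agonist_conc: float, antagonist_conc: float) -> np.ndarray:
        if agonist_conc < 0 or antagonist_conc < 0:
            raise ValueError(
                f"concentrations must be non-negative, got "
                f"[A]={agonist_conc}, [B]={antagonist_conc} µM"
            )
        return self.Q0 + agonist_conc * self.QA + antagonist_conc * self.QB


@dataclass(frozen=True)
class GeneratorMatrix:
    """Generator evaluated at fixed concentrations (rows sum to zero)."""

    states: tuple[OccupancyState, ...]
    Q: np.ndarray
    agonist_conc: float
    antagonist_conc: float


def _set_diagonal(Q: np.ndarray) -> None:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))


def build_generator_parts(
    params: RateParameters,
    desensitization_on: bool = True,
    desens_assignment: Mapping[str, str] | None = None,
    states: Sequence[OccupancyState] | None = None,
) -> GeneratorParts:
    """Assemble the three constant matrices of the generator decomposition.

    ``desensitization_on=False`` omits every desensitization transition
    (entry into D and recovery out of it), which is how the Schild
    demonstration switches the desensitized tier off; the rest of the scheme
    is untouched.
    """
    p = params.resolve_ties()
    assignment = _validate_assignment(dict(desens_assignment or DEFAULT_DESENS_ASSIGNMENT))
    state_list = tuple(states) if states is not None else enumerate_states()
    index = {s: i for i, s in enumerate(state_list)}
    n = len(state_list)
    Q0 = np.zeros((n, n))
    QA = np.zeros((n, n))
    QB = np.zeros((n, n))

    def add(src: OccupancyState, dst_mode: str, dna: int, dnb: int,
            mat: np.ndarray, rate: float) -> None:
        try:
            dst = OccupancyState(dst_mode, src.n_agonist + dna, src.n_antagonist + dnb)
        except ValueError:
            return  # target does not exist in that mode
        j = index.get(dst)
        if j is not None and rate > 0:
            mat[index[src], j] += rate

    for s in state_list:
        na, nb, v = s.n_agonist, s.n_antagonist, s.n_vacant
        # ligand binding/unbinding within the mode, stoichiometric rates;
        # allowed in every mode wherever the target state exists
        if v > 0:
            add(s, s.mode, +1, 0, QA, v * p.a1)
            add(s, s.mode, 0, +1, QB, v * p.k1)
        if na > 0:
            off = p.a_minus1_desens if s.mode == "desensitized" else p.a_minus1
            add(s, s.mode, -1, 0, Q0, na * off)
        if nb > 0:
            add(s, s.mode, 0, -1, Q0, nb * p.k_minus1)
        # gating: direct closed↔open steps for ≥2 bound agonists
        if s.mode == "closed" and na >= 2:
            add(s, "open", 0, 0, Q0, p.beta2 if na == 2 else p.beta3)
        elif s.mode == "open":
            add(s, "closed", 0, 0, Q0, p.alpha2 if na == 2 else p.alpha3)
        # desensitization tier, per the configurable assignment
        if desensitization_on:
            if s.mode == "open":
                cls = "open_diliganded" if na == 2 else "open_triliganded"
                if cls in assignment:
                    add(s, "desensitized", 0, 0, Q0, getattr(p, assignment[cls]))
            elif s.mode == "closed" and na >= 2 and "closed_liganded" in assignment:
                add(s, "desensitized", 0, 0, Q0, getattr(p, assignment["closed_liganded"]))
            elif s.mode == "desensitized" and na == 0 and "recovery" in assignment:
                add(s, "closed", 0, 0, Q0, getattr(p, assignment["recovery"]))

    for mat in (Q0, QA, QB):
        _set_diagonal(mat)
    return GeneratorParts(state_list, Q0, QA, QB, desensitization_on)


def build_generator(
    params: RateParameters,
    agonist_conc: float,
    antagonist_conc: float,
    desensitization_on: bool = True,
    desens_assignment: Mapping[str, str] | None = None,
    states: Sequence[OccupancyState] | None = None,
) -> GeneratorMatrix:
    """Generator matrix at fixed agonist/antagonist concentrations (µM)."""
    parts = build_generator_parts(params, desensitization_on, desens_assignment, states)
    Q = parts.at(agonist_conc, antagonist_conc)
    return GeneratorMatrix(parts.states, Q, agonist_conc, antagonist_conc)


# ---------------------------------------------------------------------------
# equilibria


def equilibrium_distribution(
    gm: GeneratorMatrix, initial_index: int = RESTING_INDEX
) -> np.ndarray:
    """Stationary distribution of the chain started at ``initial_index``.

    If the chain is reducible at the given concentrations (e.g. gating rates
    zeroed), the distribution is computed on the recurrent class reachable
    from the initial state and a warning is issued; unreachable states get
    probability zero.
    """
    Q = gm.Q
    n = Q.shape[0]
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    graph = csr_matrix(off > 0)
    reach = breadth_first_order(graph, initial_index, return_predecessors=False)
    reachable = np.zeros(n, dtype=bool)
    reachable[reach] = True
    if not reachable.all():
        warnings.warn(
            "chain is reducible at these concentrations; returning the "
            "stationary distribution on the reachable class",
            stacklevel=2,
        )
    idx = np.flatnonzero(reachable)
    sub = graph[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=True, connection="strong")
    # recurrent components: no edge leaves the component
    sub_dense = off[np.ix_(idx, idx)] > 0
    recurrent = []
    for c in range(n_comp):
        members = labels == c
        if not sub_dense[np.ix_(members, ~members)].any():
            recurrent.append(c)
    if len(recurrent) != 1:
        raise ValueError(
            "stationary distribution is not unique: "
            f"{len(recurrent)} recurrent classes reachable from the initial state"
        )
    members = idx[labels == recurrent[0]]
    ns = null_space(Q[np.ix_(members, members)].T)
    if ns.shape[1] != 1:  # pragma: no cover - guarded by recurrence check
        raise ValueError("degenerate null space in equilibrium solve")
    pi = ns[:, 0]
    pi = np.clip(pi * np.sign(pi.sum()), 0.0, None)
    pi /= pi.sum()
    out = np.zeros(n)
    out[members] = pi
    return out


def binding_multinomial(
    params: RateParameters, agonist_conc: float, antagonist_conc: float
) -> dict[tuple[int, int], float]:
    """Closed-form occupancy distribution for three independent sites.

    Each site is independently vacant, agonist-bound or antagonist-bound with
    odds 1 : [A]/K_A : [B]/K_B, where K_A = a₋₁/a₁ and K_B = k₋₁/k₁.  Returns
    P(n_agonist, n_antagonist) as a multinomial over the 10 occupancies.
    """
    p = params.resolve_ties()
    if p.a1 <= 0 or p.k1 <= 0:
        raise ValueError("association rates must be positive for the binding equilibrium")
    odds_a = agonist_conc * p.a1 / p.a_minus1 if p.a_minus1 > 0 else np.inf
    odds_b = antagonist_conc * p.k1 / p.k_minus1 if p.k_minus1 > 0 else np.inf
    z = 1.0 + odds_a + odds_b
    pa, pb, p0 = odds_a / z, odds_b / z, 1.0 / z
    from math import comb

    out = {}
    for na in range(N_SITES + 1):
        for nb in range(N_SITES + 1 - na):
            n0 = N_SITES - na - nb
            coeff = comb(N_SITES, na) * comb(N_SITES - na, nb)
            out[(na, nb)] = coeff * pa**na * pb**nb * p0**n0
    return out
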