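# Methods

## The model

`p2x3kin` implements a continuous-time Markov model of competitive
antagonism at the trimeric, rapidly desensitizing P2X3 receptor. The
receptor carries three equivalent inter-subunit binding sites; each site is
vacant, agonist-bound or antagonist-bound, and the sites are occupied
independently of one another. The receptor as a whole is in one of three
gating modes — closed (C), open (O) or desensitized (D). Opening requires at
least two bound agonist molecules, so the open mode supports only the
occupancies (2A,0B), (2A,1B) and (3A,0B). Full enumeration gives
10 C + 3 O + 10 D = 23 states.

The competitive antagonist is modelled as a pure site blocker: binding and
unbinding are allowed in every gating mode wherever the target occupancy
exists (including the single free site of the diliganded open state), with
the same pair of rate constants (k₁, k₋₁) throughout. Occupying a site has
no other consequence than excluding the agonist from it.

Transition rates are stoichiometric: a state with v vacant sites binds
agonist at v·a₁·[A] and antagonist at v·k₁·[B]; dissociation is
proportional to the number of bound molecules. Gating is a direct C↔O step
for the di- and tri-liganded receptor (β₂/α₂, β₃/α₃), without a
conformational intermediate. Macroscopic occupancy evolves by the master
equation dP/dt = Qᵀ(t)·P, and the macroscopic current is
I(t) = −scale·ΣP_open(t) (inward negative, as in whole-cell recordings at
negative holding potentials), with equal weight for the di- and
tri-liganded open states.

Because every concentration enters the generator linearly, Q decomposes as
Q([A],[B]) = Q₀ + [A]·Q_A + [B]·Q_B with three constant matrices, which
makes integration under time-varying concentrations cheap and exact in
structure.

## Desensitization topology (placeholder — configurable)

The detailed assignment of the desensitization rates to source states is
not fixed by the model's public description, so the package exposes it as a
configurable map over four source-state classes, with the default:

| class             | default rate | transition                          |
|-------------------|--------------|-------------------------------------|
| open_diliganded   | d₁ = 3 s⁻¹   | O(2A,·) → D(same occupancy)         |
| open_triliganded  | d₂ = 3 s⁻¹   | O(3A,0B) → D(3A,0B)                 |
| closed_liganded   | d₃ = 0.1 s⁻¹ | C(n_A≥2,·) → D(same occupancy)      |
| recovery          | d₄ = 0.5 s⁻¹ | D(0A,·) → C(0A,·)                   |

Inside the desensitized tier the agonist dissociates slowly
(`a_minus1_desens` = 0.006 s⁻¹, the wild-type α,β-meATP dissociation rate),
which rate-limits recovery: a fully agonist-bound desensitized receptor
needs minutes to shed its agonists before the fast d₄ step returns it to
the closed tier. Recovery therefore takes minutes while desensitization
takes seconds, reproducing the receptor's characteristic timescale
separation. `desensitization_on=False` removes the desensitization tier
entirely (the Schild demonstration's switch).

## Default rate constants

Antagonist defaults are the published wild-type estimates: TNP-ATP
k₁ = 15.8 µM⁻¹s⁻¹, k₋₁ = 0.056 s⁻¹; A317491 k₁ = 6.7 µM⁻¹s⁻¹,
k₋₁ = 0.47 s⁻¹. The PPADS preset (k₁ = 0.002 µM⁻¹s⁻¹, k₋₁ = 1e−4 s⁻¹) is a
phenomenological placeholder for a pseudo-irreversible blocker: association
sized so the block at 10 µM develops over minutes, dissociation negligible
on protocol timescales. Its ratio is deliberately not an equilibrium
constant — equilibrium analysis is exactly what fails for this compound.

Agonist and gating rates are documented placeholders, not literature
values: a₁ = 10 µM⁻¹s⁻¹, a₋₁ = 50 s⁻¹ (K_A = 5 µM), β₂/α₂ = 100/150 s⁻¹,
β₃/α₃ = 600/15 s⁻¹. They were chosen once so that (i) activation is
millisecond-scale, (ii) desensitization is second-scale and recovery
minute-scale, and (iii) the peak-response EC50 of a 2-s agonist pulse is
≈9 µM, matching the convention that the 10 µM test concentration sits near
the EC50. Users fit to real data should supply their own agonist parameters
through the configuration file; the antagonist fit holds them fixed either
way.

Temperature for ΔG = RT·ln K_D defaults to 295 K (room-temperature
recordings); R = 8.314 J·mol⁻¹·K⁻¹. K_D is reported in nM, ΔG in kJ/mol.

## Protocols and integration

Ligand application is piecewise-exponential: the concentration relaxes
toward each new target with a single solution-exchange time constant
(default τ = 50 ms, configurable; τ = 0 gives rectangular steps). Four
canonical schedules are built in:

* **steady-state** — antagonist from t = 0 for 110 s, 2-s agonist pulses at
  28/32/94 s (2-s and 60-s gaps); concentration–inhibition plus recovery.
* **wash-out** — 20 s antagonist, then a 10-s agonist pulse after a
  configurable delay; direct view of antagonist dissociation.
* **dynamic** — 25 × 1-s agonist pulses at 1-min intervals, antagonist
  covering pulses 8–13; onset/offset of block, run-down and overshoot.
* **protection** — seven 5-min-spaced points, agonist at S1–S5 and S7,
  antagonist immediately after S3 and at S6.

The master equation is integrated segment-wise between switch times with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e−8, atol 1e−10, analytic
Jacobian Qᵀ(t)); restarting at each switch avoids smoothing over target
discontinuities. Output grids are dense (2 kHz by default, the usual
digitization rate) inside per-pulse sweep windows and sparse in the long
quiescent stretches. Series of runs from one virtual cell are chained: the
final state of one run is propagated through the 5-min drug-free gap with a
matrix exponential, so incomplete recovery carries across runs instead of
assuming a reset.

## Fitting

With agonist and gating rates fixed, exactly two parameters remain free:
k₁ and k₋₁. They are estimated by trust-region least squares
(`scipy.optimize.least_squares`) on the pointwise difference between
simulated and observed currents across all supplied runs, searched in
log-space (positivity by construction). Multi-start (default 3 starts,
×10 apart in log-space) guards against local minima; exploration runs are
loosely converged and the best endpoint is polished to full tolerance. The
finite-difference step for the Jacobian is set to 1e−3 on the log scale —
well above the integrator's error floor, which would otherwise turn the
Jacobian into noise. Standard deviations come from the Gauss–Newton
covariance at the optimum, transformed to the linear scale; K_D and ΔG
uncertainties are first-order (delta-method) propagations, which agree with
Monte-Carlo resampling to within 5% for percent-level input SDs.

The objective is least squares on macroscopic currents rather than a
hidden-Markov likelihood; for macroscopic (many-channel) traces with
additive noise the two coincide up to weighting, and least squares keeps
the fitting contract transparent and testable.

## Hill and Schild analyses

Concentration–inhibition and concentration–response curves use the
three-parameter Hill equation (midpoint, slope coefficient, plateau); fits
on data that never cross the half-maximal level are flagged as poorly
determined rather than rejected.

The Schild demonstration simulates agonist CRC families at antagonist
levels 0/0.1/0.3/1/3 µM (agonist 0.1–1000 µM base grid): one
antagonist-pre-equilibrated agonist pulse per (A, B) pair, peak |I| as the
response. Two numerical choices matter and are deliberate:

* the test pulse lasts max(10, 8/k₋₁) s, so that with desensitization off
  the peak reaches the true agonist/antagonist equilibrium (antagonist
  unbinding is the slowest re-equilibration step);
* each shifted curve is re-sampled at the control curve's positions
  relative to its own first-pass EC50, because the true curve is not
  exactly Hill-shaped and fitted maxima are only comparable when curves
  are sampled at matching relative positions.

Dose ratios below 1.05 are excluded from the Schild regression
(no measurable shift); with fewer than two usable levels the regression is
skipped. Without desensitization the family shifts in parallel (slope ≈ 1,
pA₂ ≈ pK_B, maxima preserved within <1%); with desensitization the fitted
maxima collapse with antagonist concentration (≈88% depression at 3 µM
A317491-like block) — the quantitative form of why classical Schild
analysis misclassifies competitive blockers at this receptor.

## Synthetic data

The generator emulates the steady-state experimental series: one control
run plus ascending antagonist levels from a single virtual cell, chained
with 5-min gaps, digitized at 2 kHz in sweep windows, with additive i.i.d.
Gaussian noise scaled to a fraction (default 2%) of the control peak.
Seeded noise streams are spawned per run, so a bundle is byte-reproducible
from its manifest. It does not model baseline drift, capacitive transients,
series-resistance error or solution-exchange variability — passing
round-trip tests therefore demonstrates estimator correctness under the
model's own assumptions, not robustness to every artifact of real
recordings.

## Known limitations

* The desensitization topology and the agonist/gating placeholder rates
  stand in for unpublished parameter values; absolute simulated amplitudes
  and run-down depths are illustrative, and conclusions in the test suite
  are restricted to orderings, ratios and round-trip identities that are
  robust to this choice.
* Single-channel (stochastic trajectory) simulation is out of scope; only
  macroscopic occupancy evolution is computed.
* Allosteric or non-competitive antagonist schemes are not represented.
* The pseudo-irreversible blocker is modelled only in the slow-dissociation
  limit of the competitive scheme; covalent or multi-step block is not.
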