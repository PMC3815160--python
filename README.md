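# p2x3kin

Kinetic simulation and fitting of competitive antagonism at the rapidly
desensitizing P2X3 receptor.

## The problem

P2X3 is a trimeric ATP-gated cation channel on nociceptive neurons and a
prime analgesic drug target. It desensitizes within seconds of agonist
exposure and needs minutes to recover, so agonist and antagonist never reach
equilibrium during a response. That breaks the classical pharmacology
toolbox: Schild analysis of a purely competitive blocker at this receptor
yields depressed maxima and non-parallel shifts — the textbook signature of
*non*-competitive antagonism.

`p2x3kin` takes the kinetic route instead. It implements a 23-state
continuous-time Markov model — three independent binding sites per receptor
(vacant / agonist / antagonist), three gating modes (closed, open,
desensitized), opening requiring ≥2 bound agonists — simulates whole-cell
currents under the standard drug-application protocols, and estimates the
antagonist's two rate constants (k₁, k₋₁) directly from current traces by
least squares, with every other rate fixed. Equilibrium pharmacology then
follows from the kinetics:

    K_D = k₋₁ / k₁          ΔG = R·T·ln K_D

It is intended for ion-channel biophysicists and pharmacologists who want
antagonist affinities at desensitizing receptors without pretending a
steady state exists, and as a sandbox for exactly how desensitization
corrupts dose-ratio analyses.

## Worked example

```python
import p2x3kin as pk

# ground truth: wild-type receptor + published TNP-ATP rates
truth = pk.RateParameters()

# synthetic steady-state series: control + three TNP-ATP levels, 2% noise
dataset = pk.generate_recovery_dataset(
    truth, antagonist_concs=[0.003, 0.01, 0.03], noise_sd=0.02, seed=42,
)

# fit the two free antagonist rates, everything else fixed
fit = pk.fit_antagonist_rates(
    dataset.traces, dataset.protocols, truth, initial_guess=(1.0, 0.1),
)
print(f"k1    = {fit.k1_hat:.2f} ± {fit.sd_k1:.2f} uM^-1 s^-1")
print(f"k-1   = {fit.k_minus1_hat:.4f} ± {fit.sd_k_minus1:.4f} s^-1")
print(f"K_D   = {fit.KD:.2f} ± {fit.sd_KD:.2f} nM")
print(f"dG    = {fit.dG:.2f} ± {fit.sd_dG:.2f} kJ/mol (T = {fit.temperature:.0f} K)")

off = pk.schild_analysis(pk.wt_params("a317491"), desensitization_on=False)
print(f"Schild slope (desensitization off) = {off.result.slope:.3f}, "
      f"pA2 = {off.result.pA2:.2f}")
```

Output:

```
k1    = 15.86 ± 0.14 uM^-1 s^-1
k-1   = 0.0563 ± 0.0006 s^-1
K_D   = 3.55 ± 0.01 nM
dG    = -47.72 ± 0.01 kJ/mol (T = 295 K)
Schild slope (desensitization off) = 1.035, pA2 = 7.18
```

The fit recovers the generating rates (truth: k₁ = 15.8 µM⁻¹s⁻¹,
k₋₁ = 0.056 s⁻¹, K_D = 3.54 nM) from noisy traces to within a fraction of a
percent, and with the desensitized tier switched off the model behaves as a
textbook competitive system: unit Schild slope and pA₂ equal to
−log₁₀ K_B (7.15 for the A317491 rates). With desensitization on, the same
analysis produces collapsing maxima — run `p2x3kin schild` to see both
families side by side.

A command-line surface wraps the same pipeline:

```sh
p2x3kin init-config run.yaml          # write a default configuration
p2x3kin simulate run.yaml             # synthetic trace bundle + manifest
p2x3kin fit run.yaml --traces <dir>   # rate fit -> K_D, ΔG report
p2x3kin schild run.yaml               # CRC families ± desensitization
p2x3kin recover run.yaml              # parameter-recovery study
```

Traces are two-column delimited text with a `#` metadata header; configs
are YAML with units fixed at the boundary (concentrations µM, K_D nM,
ΔG kJ/mol).

Note that the agonist/gating rate constants shipped as defaults are
documented placeholders (see `docs/methods.md`); supply your own via the
config when fitting real recordings.

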