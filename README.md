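# unfoldkit

Equilibrium unfolding models and constraint-network rigidity analysis for
small protein domains.

Marginally stable domains — the N-terminal p53-binding region of MDM2 is
the motivating case — rarely unfold as a clean two-state reaction.
Calorimetry shows multiple overlapping transitions, spectroscopic probes
disagree on midpoints, and denaturation is often irreversible, so only
*apparent* parameters can be reported. `unfoldkit` packages the analysis
chain such a study needs:

* **Curve fitting** of pH titrations, chemical (denaturant) and thermal
  denaturation curves, differential-scanning-fluorimetry (thermofluor)
  traces and DSC thermograms, with honest "apparent parameter" caveats
  for irreversible transitions.
* **State-population analysis** of multi-transition calorimetric models.
* **Simulated thermal unfolding** of a structure by body-and-bar rigidity
  percolation: hydrogen bonds are diluted from weakest to strongest and a
  pebble game tracks where the structure loses rigidity, globally and per
  residue.
* **Synthetic data generators** for every input (curves with seeded
  Gaussian noise, ideal α-helix fixtures), so the whole pipeline is
  testable offline.

## Models

**Two-state thermal transition.** The measured signal mixes native and
unfolded baselines, `F(T) = P_N F_N(T) + P_U F_U(T)` with linear
`F_N, F_U`, populations from `K(T) = exp(−ΔG/RT)` and the
Gibbs–Helmholtz free energy

```
ΔG(T) = ΔH_m (1 − T/T_m) − ΔC_p [(T_m − T) + T ln(T/T_m)].
```

**Two-transition DSC model.** Two energetic domains unfold independently,
`Q(T) = (1 + K₁)(1 + K₂) = 1 + K₁ + K₂ + K₁K₂`, giving four states
(native, two intermediates, unfolded) with populations `1/Q, K₁/Q, K₂/Q,
K₁K₂/Q`. The average excess enthalpy is `⟨ΔH⟩ = RT² ∂lnQ/∂T` and the
excess heat capacity its temperature derivative, evaluated in closed form
via the fluctuation identity `⟨ΔC_p⟩ = (⟨h²⟩ − ⟨h⟩²)/RT² + ⟨c_p⟩`.
A sequential three-state model (`Q = 1 + K₁ + K₁K₂`) is available for
comparison; the two coincide when the transitions are far apart.

**pH titrations** follow a Hill mixing of protonated/deprotonated species,
`X = (X_a + X_b·10^{n(pH−pKa)}) / (1 + 10^{n(pH−pKa)})`; **chemical
denaturation** uses the linear extrapolation model `ΔG = m([D]₁/₂ − [D])`.

**Rigidity unfolding.** Atoms are rigid bodies (6 degrees of freedom);
covalent and hydrogen bonds are 5-bar constraints, hydrophobic tethers
2-bar. At dilution energy E only hydrogen bonds with `|E_HB| ≥ E` remain
(Mayo-style distance/angle energies). A (6,6) pebble game decomposes each
network into rigid clusters and counts floppy modes, yielding

* `Φ` — floppy-mode density, `Σ` — cluster-configuration entropy,
  `Π` — fraction of the initial giant rigid cluster surviving;
* per-residue `P` (energy at which a residue leaves the giant cluster),
  `R` (mean segregation energy of its backbone constraints) and `F`
  (weak-spot frequency over a "fuzzy" ensemble of perturbed topologies);
* the linear map `T(K) = 300 + 20·E` to a temperature scale.

## Worked example

Simulate a thermogram at the study's calorimetric parameters
(transitions at 52.3 °C / 55 kcal·mol⁻¹ and 69.8 °C / 50 kcal·mol⁻¹,
0.2 kcal·mol⁻¹·K⁻¹ noise), fit it, and inspect the intermediate
populations:

```python
import numpy as np
from unfoldkit.datatypes import TransitionParams, NoiseSpec
from unfoldkit.synthetic_data import make_thermogram
from unfoldkit.state_models import fit_dsc

tg = make_thermogram([TransitionParams(52.3, 55.0), TransitionParams(69.8, 50.0)],
                     np.arange(25, 90.001, 0.2), NoiseSpec(sd=0.2, seed=1))
fit = fit_dsc(tg)
for i, t in enumerate(fit.transitions, 1):
    print(f"transition {i}: Tm = {t.Tm:.1f} C, dH = {t.dH:.1f} kcal/mol")
pop = fit.populations(np.arange(25, 90.001, 0.01))
i = int(np.argmax(pop.intermediate1))
print(f"max intermediate-1 population: {100*pop.intermediate1[i]:.1f}% "
      f"at {pop.temperature[i]:.1f} C")
```

prints

```
transition 1: Tm = 52.3 C, dH = 54.6 kcal/mol
transition 2: Tm = 69.7 C, dH = 49.4 kcal/mol
max intermediate-1 population: 78.2% at 60.6 C
```

i.e. the fit recovers both generating transitions within their standard
errors, and the first intermediate transiently dominates (~78% of
molecules near 60 °C) while remaining invisible to any two-state read-out.

The rigidity side runs the same way on a structure (here the built-in
ideal-helix fixture):

```python
from unfoldkit.synthetic_data import HelixFixtureSpec, make_helix_structure
from unfoldkit.rigidity import fuzzy_ensemble

helix = make_helix_structure(HelixFixtureSpec(20))
ens = fuzzy_ensemble(helix, n_topologies=50, sigma_E=0.2, seed=1)
print(f"sigma transition: {ens.sigma_mean:.2f} +/- {ens.sigma_sd:.2f} kcal/mol")
print(f"pi transition:    {ens.pi_mean:.2f} +/- {ens.pi_sd:.2f} kcal/mol")
```

```
sigma transition: 4.08 +/- 0.12 kcal/mol
pi transition:    4.29 +/- 0.09 kcal/mol
```

The entropy transition (bulk melting) precedes the collapse of the giant
rigid cluster — the same ordering of events the global indexes are meant
to resolve on real structures.

A `unfoldkit` console script exposes the same operations
(`simulate`, `fit-titration`, `fit-chemical`, `fit-thermal`,
`fit-thermofluor`, `fit-dsc`, `dsc-populations`, `rigidity-unfold`,
`rigidity-ensemble`, `run --config config.json`).

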