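# Methods

This note documents the models implemented in `unfoldkit`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that affect results.

## Thermodynamic conventions

All energies are kcal/mol, heat capacities kcal/(mol K); the gas
constant is fixed at R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and temperatures
convert as T(K) = T(°C) + 273.15. Every transition is parameterized by
(T_m in °C, ΔH(T_m) ≥ 0, ΔC_p), with the Gibbs–Helmholtz free energy

    ΔG(T) = ΔH_m (1 − T/T_m) − ΔC_p[(T_m − T) + T ln(T/T_m)],

and K(T) = exp(−ΔG/RT). The unfolded direction is positive-enthalpy, so
K grows with temperature and the native fraction decreases.

## DSC model

The two-transition model treats the molecule as two independently
unfolding energetic domains: Q = (1+K₁)(1+K₂). Its four states carry
excess enthalpies {0, h₁, h₂, h₁+h₂} with hᵢ(T) = ΔHᵢ + ΔC_p,ᵢ(T−T_m,ᵢ).
Excess enthalpy and heat capacity are evaluated **analytically** from the
state ensemble:

    ⟨ΔH⟩  = Σ P_s h_s,
    ⟨ΔC_p⟩ = (⟨h²⟩ − ⟨h⟩²)/(R T²) + Σ P_s c_s .

The fluctuation form is the exact temperature derivative of ⟨ΔH⟩ under
per-state Gibbs–Helmholtz energies (each state satisfies
d ln w_s/dT = h_s/RT²); tests verify it against centred finite
differences of ⟨ΔH⟩ to ≤ 10⁻⁶ relative, with and without ΔC_p, rather
than trusting either route alone. A sequential three-state model
(Q = 1 + K₁ + K₁K₂) is provided for comparison; when T_m's are far apart
(K₂ ≪ K₁ throughout the first transition) the two models' heat-capacity
curves and fits coincide, which tests confirm numerically.

Population analysis is routinely done with ΔC_p = 0 per transition: the
heat-capacity step is removed from thermograms as a progress baseline
before fitting, so ΔC_p has no geometric signature left to estimate.
`subtract_progress_baseline` implements that pre-processing (pre/post
linear segments fitted on the terminal 20% of points, interpolated by
the normalized signal integral); it requires the grid to extend far
enough that the terminal segments are baseline-dominated. ΔC_p,ᵢ remain
available as fit parameters (`vary_dcp=True`).

**Fit initialization.** T_m seeds come from the two most prominent
thermogram peaks (`scipy.signal.find_peaks`); ΔH seeds from the
two-state peak-height relation ΔH² ≈ 4RT_m²·C_p,max. Transitions are
relabelled in T_m order after fitting, and a fit is flagged unsuccessful
on parameter collapse (|T_m1 − T_m2| < 0.5 °C).

## Curve fits (pH, chemical, thermal, thermofluor)

All fitters use Levenberg–Marquardt least squares (lmfit) with
heuristic initialization: the midpoint seed is the abscissa of the
largest |numerical derivative| of the (baseline-detrended) signal, and
baselines come from the terminal 20% of points on each side.

* pH titrations: Hill model between acidic and basic species;
  n is expected near 1 for single-group titrations but is fitted freely
  (bounded to (0, 10]).
* Chemical denaturation: linear extrapolation model,
  ΔG = m([D]₁/₂ − [D]), with baselines linear in [D]; the curve's
  temperature enters the Boltzmann factor explicitly.
* Thermal curves: Gibbs–Helmholtz two-state model with baselines linear
  in °C. ΔC_p floats by default (the functional form does not restrict
  it) but is weakly identified by a single curve; `fix_dcp=0` reduces it
  to the van't Hoff form. The thermofluor fitter pins ΔC_p at 0 by
  default for the same identifiability reason (`fix_dcp=None` frees it).

Because denaturation of marginally stable domains is typically
irreversible, every curve-fit result carries an explicit caveat that its
parameters are *apparent*; no ΔG of folding is derived from them.
Degenerate inputs are handled in two ways: structurally unusable curves
(constant signal, too few points) raise `FitError`; curves that fit but
show no resolvable transition (midpoint outside the measured range, or
transition amplitude within the residual noise) return a result flagged
`success=False` with a diagnostic message.

## Rigidity analysis

**Network.** Atoms are bodies with 6 degrees of freedom. Covalent bonds
and hydrogen bonds contribute 5 bars (leaving one dihedral-like degree of
freedom), hydrophobic tethers 2 bars. Hydrogen bonds connect donor and
acceptor heavy atoms. Tethers join C/S atoms from residues ≥ 2 apart
within r_vdw,i + r_vdw,j + 0.25 Å, using united-atom radii C = 1.9 Å,
S = 1.8 Å (hydrogens subsumed, so the rule also works on H-less carbon
frameworks); tethers and covalent bonds are never diluted.

**Hydrogen-bond energies** use a Mayo-style potential,
E = V₀[5(R₀/R)¹² − 6(R₀/R)¹⁰]·cos²θ·exp(−(π−θ)⁶)·cos²φ with V₀ = 8
kcal/mol, R₀ = 2.8 Å, R the donor–acceptor distance, θ the D–H···A
angle and φ the H···A–antecedent angle; candidates need R ≤ 3.6 Å and
θ ≥ 90°, and contacts weaker than 0.01 kcal/mol are not treated as
constraints (they would dissolve at the first dilution step and only
add noise to the bond list). Donor–acceptor pairs within three covalent
bonds are excluded so peptide-unit geometry never scores.

**Pebble game.** The (6,6) pebble game computes the rank of the generic
body-bar rigidity matroid; independence of a bar requires gathering 7
pebbles on its endpoints. Rigid clusters come from the pair test (an
extra bar between mutually rigid bodies is redundant) propagated by
union-find over adjacent pairs — mutual rigidity is transitive and rigid
clusters are edge-connected, so this recovers the full partition.
Floppy modes are free pebbles minus the six global motions. Property
tests check the count against the nullity of a generically embedded
rigidity matrix on hundreds of random networks, and check permutation
invariance of the decomposition.

**Dilution sweep.** E runs from 0 in steps of 0.1 kcal/mol (one step
past the strongest bond by default); at energy E only bonds with
|E_HB| ≥ E remain. Consecutive grid points that remove no bond reuse
the cached decomposition. Global indexes:

* Φ = internal floppy modes / (6N − 6);
* Σ = −Σ_s w_s ln w_s with mass-weighted w_s = s·n_s/N over the
  rigid-cluster size distribution — zero both for a single all-spanning
  cluster and for all singletons;
* Π = the largest fraction of the E = 0 giant-cluster bodies still
  sharing one rigid cluster. This "max over current clusters" reading
  makes Π provably non-increasing, since constraint removal only refines
  the cluster partition.

One body-bar artifact deserves note: pendant atoms (CB, amide H,
carbonyl O without a hydrogen bond) are connected by a single 5-bar edge
and keep a phantom spin degree of freedom, so they count as singleton
clusters even in the native state. Σ therefore starts from a nonzero
floor set by the pendant background; the informative signal is the rise
and fall superimposed on that floor as the giant cluster fragments.

**Transition detection** takes the largest single-step drop (Π) or rise
(Σ), ties resolved toward the lowest energy, and reports the grid energy
at which the responsible bonds were removed. A trace whose largest step
does not exceed twice the median step magnitude is classified as uniform
drift with no transition (this rejects flat and linear traces). Note an
ideal, perfectly symmetric helix has all its i→i+4 bonds at exactly one
energy, so it melts in a single step: Σ never rises and has no
transition to detect — correct behaviour for a two-state fixture.
Hierarchical behaviour (Σ rising through an interior maximum before the
Π collapse) appears as soon as bond strengths are graded or perturbed,
and the tests exercise it that way.

**Fuzzy ensembles** perturb every detected hydrogen-bond energy with
seeded Gaussian noise (default σ_E = 0.2 kcal/mol, default 500
topologies); perturbed bonds that become unfavorable are dropped for
that topology. All topologies share one energy grid so transition
statistics are comparable; means and (n−1)-normalized SDs are reported
per index, with temperatures from the affine map T(K) = 300 + 20·E.

**Local indexes** (ensemble-averaged): P is the lowest E at which a
residue's Cα leaves the giant cluster; R averages, over the residue's
backbone–backbone covalent edges, the E at which the edge's endpoints
stop sharing the giant cluster (side-chain pendant edges are excluded —
they are never in a rigid cluster and would pin R at 0); F is the
fraction of topologies in which the residue donates or accepts the
weakest bond removed at the Π transition. P and R cap at the top of the
simulated range for residues that never segregate.
`annotate_structure` writes a per-residue index into the B-factor column
of PDB snapshots (values unchanged across snapshots; the occupancy
column marks whether the residue's index exceeds the snapshot energy).

## Synthetic data

Generators evaluate the same model code the fitters use and add
homoscedastic Gaussian noise (seeded; identical seeds are bit-identical).
Defaults: 1% of the clean-signal range for curves, 0.2 kcal/(mol K) for
thermograms — stand-ins, since real measurement-error magnitudes are
instrument-specific. Truth parameters are stored in curve metadata.
What they do **not** emulate: baseline drift and scan-rate artifacts,
heteroscedastic or correlated noise, aggregation at high temperature,
and spectra (only scalar progress signals are generated). Passing
recovery tests therefore demonstrates estimator correctness under the
stated error model, not robustness to instrument pathology.

The helix fixture is a deterministic ideal poly-alanine backbone
(N, H, CA, CB, C, O) built by NeRF from tabulated internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.01 Å,
CA–CB 1.521 Å; angles C–N–CA 121.7°, N–CA–C 111.2°, CA–C–N 116.2°,
CA–C–O 120.8°, N–CA–CB 110.4°; ω = 180°), defaults (φ, ψ) = (−57°, −47°).
The amide hydrogen lies on the in-plane bisector of N→C(i−1) and N→CA;
the first residue has no amide H. With defaults, a 12-mer yields exactly
the 8 i→i+4 backbone hydrogen bonds at ≈ −4.4 kcal/mol. The fixture has
no side chains beyond CB, hence essentially no hydrophobic tethers — the
rigidity signal is carried by the hydrogen-bond network, which is the
point of the fixture.

## Problem sizes

Defaults used by the test suite and the reproduction script: population
grids at 0.01 °C over 25–90 °C; thermogram recovery on 0.2 °C grids
(326 points); thermofluor on 0.5 °C grids; titrations on 0.25-pH-unit
grids; rigidity fixtures of 12–20 residues with ensembles of 25–50
topologies. These sizes resolve every tested quantity comfortably while
keeping a full run in seconds; production ensembles of 500 topologies
run in well under a minute on a single core.

## Known limitations

* Van't Hoff ΔC_p from one irreversible curve is weakly identified;
  reported ΔC_p values should not be over-interpreted.
* The rigidity model is static: it ranks regions by flexibility but
  cannot predict actual displacement amplitudes or pathways.
* The cluster-entropy normalization, weak-spot definition and fuzzy
  perturbation scheme follow the definitions above; other rigidity
  codes use related but not identical conventions, so absolute
  transition energies are comparable only within one convention.
* Salt bridges, π-stacking and side-chain donors are not modeled; the
  fixtures are backbone-only.
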