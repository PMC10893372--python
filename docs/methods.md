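# Methods

## Models

### Double-spike inversion

Each purified sample is a two-component mixture: natural Cd related to the
reference standard by the exponential mass-fractionation law, plus a
¹¹¹Cd–¹¹³Cd double spike. On the ¹¹⁰Cd-denominator basis, with
q_i = m_i/m₁₁₀:

    measured_i = [(1 − p)·R_ref,i·q_i^α + p·R_spike,i] · q_i^β,   i ∈ {111, 113, 114}

Three measured ratios determine the three unknowns (p, α, β) exactly. We
solve by damped Newton iteration with the analytic Jacobian (backtracking
halving line search; convergence at residual norm ≤ 1e−12 relative to the
measured-ratio norm; max 100 iterations; default initial guess
(0.5, 0, 0)). The natural composition follows from α alone,
δ¹¹⁴Cd = (q₁₁₄^α − 1)·1000, so it is invariant to p and β by construction —
the central robustness property of double-spike work. α is the
dimensionless exponent on q_i; a δ of −0.64‰ corresponds to α ≈ −0.018.

Isotope dilution: p is the molar fraction of ¹¹⁰Cd from the spike, so
n₁₁₀(natural) = n₁₁₀(spike)·(1 − p)/p; abundances and mean atomic masses
on the four-isotope basis convert between Cd mass and ¹¹⁰Cd moles. With
the spike strongly depleted in ¹¹⁰Cd, a 1–2× spike:natural Cd mass ratio
corresponds to p ≈ 0.1–0.2; the algebra is exact for any p ∈ (0, 1).

The shipped reference/spike compositions (`data/cd_system.json`) are
editable placeholders — natural-abundance reference ratios and an
illustrative spike — not certified values; all tests use self-consistent
synthetic compositions. Blank correction is not applied (procedural blanks
in this kind of work are <0.1% of sample Cd); the reduction has no hidden
corrections.

### Mass balance and Δ arithmetic

Organ Cd mass (µg) = concentration (mg/kg dry weight) × dry mass (g).
Total-plant δ is the Cd-mass-weighted mean of organ δ values; partition
fractions f_organ and f_shoot = f_leaf + f_stem follow directly, and
TF(%) = (Cd_leaf + Cd_stem)/Cd_root · 100. Δ¹¹⁴Cd_A−B = δ_A − δ_B, with
2sd combined in quadrature. Within a single plant Δ_L−R = Δ_L−S + Δ_S−R
holds exactly; the identity does **not** survive replicate averaging, so
all fractionations are computed per plant first and then averaged across
biological replicates — inverse-variance weighting (w = 1/σ², σ = 2sd/2,
combined 2sd = 2/√Σw) for isotope quantities, arithmetic means for masses,
concentrations, fractions, TF and ε. Uncertainties are stored as 2sd
throughout, matching the reporting convention of the data.

The residual solution obeys exact two-pool closure:
f·δ_final + (1 − f)·δ_plants = δ_init, solved for δ_final. Adsorption of
Cd to root surfaces is neglected (a few percent uptake leaves it
insignificant). The solution composition is fixed at
δ_init = −0.36 ± 0.04‰; source material for this value is internally
inconsistent about the sign in one place, and −0.36 (the value used in all
derived quantities) is adopted.

### Rayleigh estimators

Reservoir: ε_uptake = (δ_final − δ_init)/ln f, f the fraction of Cd
remaining. Sink: ε_seq−mob = Δ_sink−tot/ln f_sink per plant, and pooled by
least squares of Δ on x = ln f with zero intercept (ε = Σw·x·y / Σw·x²),
forced through (f = 1, Δ = 0) because a sink holding all the Cd cannot
differ from its source. Weights default to 1; inverse-variance weighting
is available. Signs: a heavy sink (positive Δ) at f < 1 gives ε < 0; the
reporting layer exposes |ε| as well, since uptake fractionations are
conventionally quoted as magnitudes.

The pooled sink fit applies the instantaneous ln-linear form to the
accumulated sink — the convention under which such fractionation factors
are reported for plants. The exact accumulated-product composition,
δ_init − ε·f·ln f/(1 − f), is available separately
(`accumulated_product_delta`) and is what the synthetic generator uses for
the plants' pooled Cd; at 5% uptake the two differ by <0.02‰, which is why
Δ_tot−sol and ε_uptake agree to well within analytical precision
(reservoir effects negligible).

### Group comparisons

Treatments sharing a design variable (hydroponic/foliar Fe or Zn) are
pooled and compared by the Kruskal–Wallis rank test with tie correction —
appropriate for small, mostly non-normal samples. p-values use the χ²
approximation (df = k − 1) except when the pooled n ≤ 12, where the exact
permutation distribution of H is enumerated over all multinomial
assignments (≤ 924 labelings at n = 12). Significance is reported at
p < 0.05, two-sided (the test is inherently omnibus). No post-hoc pairwise
tests or multiplicity corrections are applied: each pooled contrast is a
single planned comparison.

## Synthetic experiment generator

The generator emulates the eight-treatment closed-system design with known
ground truth. Defaults are the study conditions: 3 L × 2.25 mg/L Cd
(6750 µg reservoir) per container of three seedlings, two analysed;
δ_init = −0.36‰; ε_uptake = −0.29‰; ε_seq−mob = −0.13‰; mean container
uptake 5% of the reservoir; total dry biomass uniform on 0.57–0.99 g with
leaves carrying 63–78%; Gaussian noise applied last, 0.05‰ (2sd) on δ and
5% relative on concentrations, independent across organs (δ noise
sd = 2sd/2).

Choices where the emulated design is silent, made once:

* **Uptake dispersion.** Only a 3–8% range is known for container uptake;
  we draw uniformly (±20% relative) around the treatment mean.
* **Fe effect.** Phenomenological: the uptake multiplier (1.7) is applied
  geometrically centred — ×√1.7 with hydroponic Fe, ÷√1.7 without — so the
  cross-treatment mean stays at the 5% base while Fe/no-Fe treatments
  straddle the 3–8% range; the mean shoot fraction is 0.55 with Fe and
  0.30 without (`fe_fshoot_shift` = 0.25). This reproduces the observed
  grouping: Fe-present plants above ~100 µg total Cd and TF > 100%,
  Fe-absent below both thresholds. No mechanistic transporter model is
  implied.
* **Within-plant structure.** Uptake is a single closed-system Rayleigh
  step over the growth period (ε_uptake is defined only on initial/final
  states, so no time resolution is modelled); every plant in a container
  samples the same accumulated pool. The leaf obeys
  Δ_leaf−tot = ε_seq−mob·ln f_leaf exactly at zero noise; the stem sits a
  fixed leaf−stem offset (default 0.23‰) below the leaf — the within-shoot
  split has no published model — and the root closes each plant's isotope
  mass balance. Stem vs root biomass within the non-leaf remainder is
  uniform 40–60% stem, also unconstrained by any published value.

What passing tests on synthetic data do *not* show about real data: the
generator has no growth dynamics, transpiration, speciation chemistry,
foliar absorption, within-container competition, or organ-correlated
noise; real uptake fractionation may vary with solution chemistry in ways
a single fixed ε cannot. Calibration results (estimator bias, type-I
error) are therefore statements about the estimators under the assumed
noise model, not about cacao physiology.

## Numerical and design notes

* Newton tolerance 1e−12 relative, physical-p tolerance 1e−9; a solved
  p outside [0, 1] is flagged (warning), not clamped. Non-convergence
  raises with the final residual vector.
* `plan_spike` returns an explicit infeasibility result when the
  spike:natural ratio and total-Cd windows cannot be met jointly; it never
  silently clamps.
* Degenerate inputs: f = 1 with Δ ≠ 0 in the sink estimator is an
  inconsistency error; f = 1 with Δ = 0 is "undefined, flagged"; all-tied
  data in Kruskal–Wallis yield H = 0, p = 1; missing organs propagate as
  flagged partial records (TF additionally requires a root).
* Replicate-averaged isotope values fall back to equal weights (with a
  warning) when any replicate lacks a positive uncertainty, as in
  zero-noise simulations.
* Pipeline outputs are plain CSV/JSON written at full precision with a
  fixed float format; re-running on identical inputs is byte-identical
  (the merged report embeds the output path and is excluded from that
  guarantee).
* The per-plant pooled Kruskal–Wallis comparison is calibrated (type-I
  error ≈ 0.04–0.05 at n = 10 vs 6 plants) for variables whose variation
  is plant-level, such as Δ_shoot−tot. Variables inheriting a shared
  container-level draw (total Cd under the synthetic model) are
  anticonservative when plants are treated as independent units — a
  cluster effect users should weigh when interpreting plant-level
  p-values; treatment-level pooling is the conservative alternative.

## Problem sizes

The test suite and calibration runs use the experiment's own scale: 8
treatments × 2 analysed plants × 3 organs per simulated experiment;
parameter-recovery calibration uses 200 seeded experiments (the pooled
leaf-sink ε estimator is unbiased to within 0.01‰ with sd ≈ 0.005‰ under
the default noise); the null-calibration study uses 1000 seeded
experiments; double-spike round-trip sweeps use 50–100 random states.

## Known limitations

* The double-spike stage models only the four isotopes used in the
  inversion; spike concentrations are interpreted on that basis.
* No drift/bracketing model, cup-gain calibration, interference
  correction, or optimal spike-composition design — the reduction starts
  from clean measured ratios.
* The published per-plant scatter statistics (per-plant regression R²,
  exact pooled p-values) require per-plant source data that is not part of
  the packaged per-treatment dataset, so they are reproduced only
  qualitatively by the synthetic pipeline, not asserted numerically.
* Speciation of Cd in solution is taken as externally established
  (predominantly free Cd²⁺; EDTA binding of Cd is minimal) and is not
  modelled.
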