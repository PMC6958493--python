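# Methods

## The assay and its models

An immunoreactive fraction assay saturates a fixed trace concentration
*T* of radiolabeled antibody against a series of plate-coated antigen
concentrations [Ag]₀ and measures the bound fraction B/T per well. The
immunoreactive fraction *r* is the bound fraction that would be reached
at infinite antigen excess at equilibrium; it must be extrapolated.

**Exact equilibrium model (with antigen depletion).** Monovalent 1:1
binding with free antigen [Ag] = [Ag]₀ − [B] gives, for x = B/T,
a = [Ag]₀/T and k = K_D/T,

    x² − (k + a + r)·x + r·a = 0,

whose smaller root is the physical solution (it vanishes at [Ag]₀ = 0
and converges to *r* as [Ag]₀ → ∞). Because a reaches 800 on the
default grid, the smaller root is obtained from the product of roots
(r·a divided by the larger root) to avoid cancellation; the residual of
the returned root is below 1e-10·max(1, a) everywhere tested. A warning
is emitted if the discriminant falls below 1e-12 (near-coincident
roots); no parameter set on the study grid approaches this.

**Approximate estimators.** When antigen is in large excess over
antibody, depletion is negligible and B/T ≅ r·[Ag]₀/([Ag]₀+K_D) — the
rectangular hyperbola — whose double inversion is the Lindmo line
T/B = 1/r + (K_D/r)/[Ag]₀. Both are *exact* on depletion-free
equilibrium data; the package quantifies how they degrade when the
assumptions fail.

**Kinetics.** With [Ag]₀ ≫ T, association is pseudo-first order with
rate constant k_on·[Ag]₀; the bound fraction at time t is the
equilibrium value times 1 − e^(−k_on·[Ag]₀·t). The dissociation
contribution to the rate constant is deliberately omitted (the factor
multiplies the *equilibrium* value, so the long-time limit is still
correct); no reversible-kinetics mode is provided. The default
k_on = 1.444e-4 nM⁻¹min⁻¹ corresponds to a 240-min half-time of
complex formation at [Ag]₀ = 20 nM, a representative slow-binding
antibody at 5 °C. The asymmetry of the rate constant in [Ag]₀ is the
central systematic error: at t = 1200 min the 1.25 nM well has reached
only ~19% of equilibrium while the 80 nM well is complete.

**Plate saturation and desorption.** High-binding polystyrene coats a
finite protein mass, so applied antigen above a cap (default 30 nM)
all coats the same amount; computations then use the coated values
while fits use the nominal applied labels — the experimenter does not
know the plate saturated, and that mismatch is the artefact studied.
Desorption of the complex at the capped level is modelled as a constant
0.9 multiplier regardless of time; real desorption is time-dependent,
and this constant-factor form is a deliberate simplification.

## Error model

Four independent Gaussian error sources, each expressed as a per-cell
SD of B/T over the (K_D, [Ag]₀) grid:

| source | default magnitude | behaviour |
|---|---|---|
| antigen quantity | ±10% of [Ag]₀ | peaks (≈0.018) where K_D ≈ [Ag]₀, vanishes when [Ag]₀ ≫ K_D |
| antibody volume | ±1% of T | equals 0.01·(1 − B/T) via the blank-substitution transform |
| nonspecific binding | blank SD 1.5% | constant √2·0.015 ≈ 0.021 (enters through U_blank and U) |
| gamma counter | 0.01 | constant |

Perturbation SDs use the *sample* (n−1) convention, under which the
triplet {x−δ, x, x+δ} has SD exactly δ; this is what makes the
antibody SD identically 0.01·(1−B/T) and pins the printed component
ranges. The overall SD is the cellwise quadratic sum (0.023–0.030 over
the default grid); the CV grid divides by the mean bound fractions and
spans ~3% to >300%, tracking the bound-fraction magnitude.

Under kinetic distortion, the antigen and antibody SD grids are
recomputed from the distorted bound fractions; the antigen perturbation
then enters both the binding model and the rate factor (a flag disables
the rate-factor perturbation, since either reading is defensible); the
two constant components are unchanged. Poisson counting statistics are
out of scope — the counter SD is fixed.

## Monte-Carlo study

Defaults are the study conditions: r = 70%, T = 0.1 nM, nine K_D values
{0.01, 0.0316, 0.1, 0.316, 1, 3.16, 10, 31.62, 100} nM, antigen series
{1.25, 2.5, 5, 10, 20, 40, 80} nM, t = 1200 min, n = 25 replicates.
Each replicate cell is one normal draw centred on the distorted bound
fraction with SD = overall SD/√3 (the SD of a triplicate mean; an
explicit-triplicate mode draws three at full SD and averages —
distributionally identical). Draws use the Mersenne-Twister bit
generator with an independent substream per (replicate, K_D row), so
excluding rows or truncating the study never shifts other draws and the
full summary is bit-reproducible from the seed.

Every replicate row is refit with both methods at exclusion thresholds
{none, 1.25, 2.5, 5} nM, reusing the same draws across thresholds
(stepwise deletion refits the same matrices). Fits with r̂ ≤ 0,
r̂ > 1.25, non-finite estimates or optimizer failure are counted as
flagged; the 1.25 cutoff separates physically impossible values from
the merely inaccurate high-K_D hyperbola estimates. Saturated-scenario
runs also report the study with the duplicate capped point removed.

## Fitting choices

* Hyperbola: unconstrained Levenberg–Marquardt (scipy `curve_fit`),
  tolerance 1e-10, up to 10,000 function evaluations; initialization
  r₀ = max observed bound fraction, K_D,0 = first antigen level whose
  bound fraction exceeds r₀/2 (median level as fallback). No bounds, so
  estimates above 100% and negative values are representable — they are
  data, not errors.
* Lindmo: unweighted OLS on the transformed points. Weighting by a
  constant CV is precisely the assumption the transform smuggles in;
  keeping OLS exposes its error mismanagement rather than papering over
  it. Nonpositive bound fractions are dropped from the transform with a
  count (their reciprocal does not exist); they are retained for the
  hyperbola.
* Report rounding: r̂ to integer percent, K̂_D to 3 significant figures.

## Plate arithmetic and design helpers

Bound fractions from raw counts use the blank-mean convention
T ≡ mean(U_blank), so B_spec = mean(U_blank) − U; separate
total-activity tubes only calibrate the nonspecific binding
B_NS = mean(T_tubes) − mean(U_blank). Negative specific binding is
warned about and kept. k_on is recovered from a kinetic time course as
ln 2 / (t_half·[Ag]₀), with t_half located by linear interpolation
between the sampled times bracketing half the trajectory maximum (the
interpolation method is a package choice; error <1% at the default
sampling grid).

The well-area helper models the well as a cylinder filled to the given
volume (base disc + lateral band: 94.7 mm² at ⌀6.4 mm, 100 µL). The
maximum coatable antigen concentration uses a nominal per-well capacity
of 500 ng — the vendor round figure, consistent with the areal capacity
500 ng/cm² times the ~0.95 cm² wetted area — giving 50 nM for a
100 kDa antigen; `geometric_mass_ng()` exposes the unrounded 473 ng
(47.3 nM) figure for cross-checking. The simulation's 30 nM cap leaves
headroom for heavier antigens and imperfect coating efficiency.

## What the simulator does and does not emulate

The generator reproduces triplicate-mean Gaussian noise with the four
modelled variances, kinetic depression, plate saturation and constant
desorption. It does **not** emulate: antibody avidity or multivalent
binding, reversible-kinetics transients, Poisson counting noise,
time-dependent desorption, partial antigen adsorption or inaccessible
epitopes, or isotope decay. Passing tests therefore demonstrate
estimator behaviour under the modelled error structure, not under every
laboratory failure mode; in particular real K_D estimates from an IRFA
are biased by effects outside this model and should not be trusted
regardless of the fitting method.

## Problem sizes and determinism

All deterministic computations run on the full 9×7 study grid. The
Monte-Carlo study at its default n = 25 takes under a second;
distribution-shape tests in the suite use a few hundred replicate draws
of a single cell. Every stochastic path is seeded; identical
configurations reproduce summaries bit for bit.

## Known limitations

* The Lindmo exclusion semantics drop points with [Ag]₀ ≤ threshold;
  thresholds between grid levels behave as expected but were only
  validated at the study values {1.25, 2.5, 5} nM.
* The hyperbola optimizer is deterministic given input order; permuting
  input points can change the last digits of estimates (within the
  1e-10 tolerance).
* Integer-percent agreement with externally tabulated fits can sit on a
  rounding boundary (a 78.50% estimate rounds differently across
  software); K_D agreement is asserted at 3 significant figures.
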