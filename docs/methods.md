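# Methods

## Endpoint and data model

The unit of observation is one embryo's spontaneous tail coiling (STC)
count per minute at 24 hpf, recorded with exposure metadata (substance or
mixture label, concentration in µmol/L, replicate dish, experiment). The
experimental design emulated throughout is 20 embryos per dish, 2 replicate
dishes per concentration, ≥ 2 independent experiments, with control dishes
at concentration 0 in every experiment.

Absolute coiling frequency varies between experiments, so analysis begins
by expressing each (experiment, concentration) group as the mean percent
change versus that experiment's own controls. Per-experiment series are
then pooled by fitting all points jointly — pooling is invariant to
experiment relabelling, and fitting all points weights experiments by their
number of tested concentrations, which matches how ranges were combined in
practice.

## Concentration–response model

All curves are four-parameter log-logistic,
`y = c + (d − c)/(1 + (e/x)^b)`, written with `b > 0` and the `(e/x)^b`
form so every curve increases with concentration. Hypoactivity is
represented as percent *decrease* (0→100 increasing) with the direction
retained as a flag; one fitting code path serves both directions. Fitting
minimizes least squares on log₁₀ concentration internally (conditioning),
from three inflection starts (geometric mean of tested concentrations,
×0.1, ×10; slope start 1), with box constraints keeping the slope in
[0.05, 50] and the inflection within three decades of the tested range.
Standard errors come from the Gauss–Newton approximation of the Hessian at
the optimum; the confidence convention is ± 2·SE taken literally (no
t-quantile). ECx standard errors use the delta method (ECx ∝ e at fixed
slope). Concentrations are nominal throughout. Control (x = 0)
observations are consumed by normalization, never by the fitter.

Degenerate inputs are rejected explicitly: fewer than 4 distinct nonzero
concentrations, all-zero responses, missing or zero-mean controls.

## Hyperactivity standardization

Hyperactive substances plateau at different maxima, so percent changes are
divided by the substance's maximal percent effect *M* and rescaled to 100.
*M* is the *fitted* ceiling of the raw free-ceiling curve, not the largest
observed mean — observed maxima are single noisy points, while the ceiling
summarizes the whole curve. This choice also absorbs the correlated error
that a finite control sample induces (a mis-estimated control mean rescales
an entire experiment's curve; a free ceiling soaks that up and the
standardization divides it out). Biphasic single-substance data
(hyperactivity followed by decline, plausibly paralysis) are truncated at
the concentration of maximal mean response before the monotone fit; the
declining limb belongs to the antagonism analysis. Hypoactivity beyond a
100% decrease is impossible for a count endpoint and is clamped with a
warning. Toxic-unit extrapolation for partial agonists is deliberately not
implemented: the observed partial maxima are treated as saturated effects,
not partial agonism.

## Mixture prediction

Concentration addition: `ECx_mix = (Σ pᵢ/ECxᵢ)⁻¹` with molar fractions
*pᵢ*; equitoxic designs use `pᵢ = EC50ᵢ/Σ EC50ⱼ`. Independent action:
`E_mix(C) = 1 − Π(1 − Eᵢ(pᵢ C))` on fractional (0–1) standardized effects,
inverted by bracketing plus Brent's method (relative tolerance 1e-8;
initial bracket three decades around the fraction-scaled component EC50s,
expanded geometrically if needed). Both models require a common effect
direction and standardized (0–100) component curves; raw unequal-maximum
curves trigger a warning naming the standardization step, and
mixed-direction designs are rejected with a pointer to the antagonism
module. Prediction curves default to a 99-level effect grid (1–99%).

### Substitution designs

`substitution_design` replaces part of one component with an
EC50-equitoxic amount of another, under two conventions:

* **share** (default): the replaced component's molar share is kept fixed
  and split between old and new substance with toxic-unit weights
  (1 − portion, portion); with portion = 0.5 the pair inside the share is
  exactly equitoxic. This is how the laboratory substitution mixtures were
  composed, and it reproduces their published molar ratios; the molar CA
  EC50 shifts because the newcomer carries different potency per mole.
* **toxic_units**: the removed toxic units are added back as the new
  substance and fractions are renormalized, recording the molar inflation
  factor as `parent_scale`. Total toxic units per parent-equivalent mole
  are conserved, so the CA-predicted EC50 *in parent units*
  (`ca_ecx(50)/parent_scale`) is exactly invariant — the
  dilution-of-each-other identity of CA. No rule can conserve both the
  molar fraction sum and the toxic-unit sum simultaneously when the two
  substances differ in potency; exposing both conventions keeps the
  design-composition use case and the algebraic identity separately
  honest.

## Antagonism (opposing directions)

For mixtures combining hyper- and hypoactive components the additive
models are undefined. The package compares the observed mixture response
with the CA expectation of its same-direction (majority toxic-unit) subset
and calls the mixture **antagonistic** when the observed mean lies below
the reference by more than `se_multiplier` (default 2) standard errors at
`n_consecutive` (default 2) or more consecutive tested concentrations.
No quantitative criterion exists in the assay literature; this rule is the
package's operationalization, chosen to mirror the ± 2·SE confidence
convention used elsewhere in the analysis, and both knobs are exposed. The
reported direction-reversal concentration is the lowest concentration whose
observed mean is *significantly* below zero by the same SE rule, so noise
wiggles at sub-effective concentrations do not register as sign flips.

The rise-then-fall shape is summarized by a Gaussian on log₁₀
concentration, `baseline + amplitude·exp(−(log₁₀c − center)²/(2·width²))`,
with the baseline free (and allowed negative) so the high-concentration
undershoot below control is representable. The Gaussian is reported as
preferred only if its residual sum of squares beats the best monotone
log-logistic fit on the same points; on monotone data the monotone model
wins by construction. No printed parameter values exist for this fit, so
its tests are property-based (exact recovery on noise-free Gaussians,
model-selection consistency).

## Synthetic data generator

The generator emulates the assay's structure, not any particular dataset.
Per-embryo counts are negative binomial (Poisson when dispersion = 0) with
mean `baseline · Π_hyper(1 + hᵢ(pᵢc)/100) · Π_hypo(1 − kᵢ(pᵢc)/100)`;
the multiplicative combination of opposing directions is a declared
assumption, as is the count model itself. Experiment-to-experiment
baseline variation is lognormal. Defaults: baseline 6 coils/min (a typical
24-hpf control rate; no published value exists for the modelled dataset),
dispersion 0.05 (mild overdispersion across embryos), experiment sd 0.15.
Identical seed and configuration give byte-identical output.

What the generator does *not* emulate: malformation/mortality losses,
dish-level (replicate) random effects, video-scoring artefacts,
toxicokinetics, and chemical loss from solution (measured concentrations
for one component of the antagonism mixture were below detection in the
original assay work). Passing tests therefore demonstrate correctness of
the estimators under the declared noise model, not robustness to these
real-data features.

### Precision limit of the assay design

A consequence worth stating explicitly: at ~6 counts per embryo-minute,
the percent-change mean of a 40-embryo group carries a standard deviation
around 13 points near the EC50, and the EC50 recovered by the full
normalize → standardize → fit pipeline from a 20 × 2 × 2 design has a
median error of roughly 12–15% (see `analysis/04_synthetic_recovery.py`;
about half to two-thirds of seeded replicates land within 15%). An oracle
fit with the true slope and ceiling known does no better, so this is an
information limit of the counting design, not an estimator deficiency;
materially tighter EC50s would need more embryos or a higher baseline
count rate. This is consistent with the spread between independently
replicated single-substance EC50s in the published reference set (up to
~40–50% for the most variable substances).

## Numerical conventions

Units are µmol/L end to end; I/O column names carry the `_um` suffix.
Effect levels are percents of the curve's own span, so EC50 equals the
inflection for any ceiling. Fit convergence tolerance 1e-10 (ftol/xtol/
gtol); inverse and root-finding tolerances 1e-8 relative; fraction-sum and
CA-invariance checks at 1e-9. The pipeline is deterministic under a fixed
seed, and every stage's output table is a valid input of the next stage.

## Known limitations

* Single-substance slopes are taken as published inputs; where reported
  predictions were derived from unpublished refits, recomputed IA values
  can differ by a few percent.
* The antagonism criterion is an operationalization, not an inferential
  test; it controls no error rate.
* Mixture predictions assume no toxicokinetic interaction between
  components; deviations of that kind are out of scope.
* The equitoxic closed form `(Σ EC50)/n` holds only at the 50% level of
  equitoxic designs; it is used as an oracle in tests, not as a general
  shortcut.
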