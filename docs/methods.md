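# Methods

## Scoring model

Each patient carries 44 clinical index values partitioned into four blocks,
one per pattern (QD, DP, YD, FH; block sizes are configuration, default
11+11+11+11). Block values are aggregated into an upper-class variable per
pattern — summation by default; the mean is available and, with fixed block
sizes, yields identical standardized scores because standardization is
affine-invariant. Upper-class variables are standardized across the cohort,
component-wise: z = (x − mean)/sd with the sample sd (ddof = 1, the
conventional cohort-summary choice; the denominator is configurable).
Standardization is fitted once on the full analyzed cohort. When later
stages restrict to subsets, scores are *not* refitted — a patient's scores
travel unchanged, so subset means are means of fixed per-patient scores.

Sorting a patient's four standardized scores descending gives
Z(1) ≥ Z(2) ≥ Z(3) ≥ Z(4); ties are broken by the fixed pattern order
QD, DP, YD, FH (ties have probability zero for continuous data but the
ordering must be deterministic). The criteria are

* D = Z(1) − Z(2), R = Z(1) − Z(4), S = Z(2), C = (Z(1)+Z(2)) − (Z(3)+Z(4)),

with the chain C ≥ R ≥ D ≥ 0 holding identically (C − R = Z(2) − Z(3) ≥ 0,
R − D = Z(2) − Z(4) ≥ 0).

### Curvature equivalence for C

Placing the scores at equally spaced abscissae with the two large scores on
the edges — (1, Z(1)), (2, Z(3)), (3, Z(4)), (4, Z(2)) — and fitting the
least-squares parabola y = b0 + b1·x + b2·x² via the normal equations
(cross-product matrix [[4,10,30],[10,30,100],[30,100,354]]; the design has
full column rank, so the system is always solvable exactly) gives
b2 = C/4. b2 is invariant under swapping Z(1)↔Z(2) or Z(3)↔Z(4), since the
placement is symmetric in each pair. Only b2 is meaningful; b0 and b1 are
returned for verification. The implementation solves the fixed 3×3 system;
tests compare it against `numpy.linalg.lstsq` on the raw design.

## Discriminant

The classifier is classical linear discriminant analysis on the raw index
values (44 columns, not the four aggregates): per-class means, pooled
within-class covariance (denominator n − k), priors proportional to class
frequencies, resubstitution evaluation. Class k's score at x is
δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k; prediction is the argmax with
ties resolved by the fixed class order. A ridge term (default
1e-6·trace(Σ)/p) is added to the covariance diagonal so that small cohorts
remain fittable; on well-conditioned data it is numerically negligible.
The model family and prior treatment are design choices — the source
analysis names only "discriminant analysis", and pooled-covariance LDA with
resubstitution is the standard reading; both are configurable surfaces
(`regularization`, direction overrides) rather than hard-coded behavior.
Disagreements between physician and model get the 4-letter type code
physician+predicted; with four classes there are exactly 12 such codes.

## Screening

For criterion with direction `suspect_low` the cohort is sorted ascending
(descending for `suspect_high`), ties broken by patient id. Defaults:

| criterion | direction | reading |
|---|---|---|
| D | suspect_low | top two patterns nearly tied |
| R | suspect_low | flat profile, small range |
| S | suspect_high | strong runner-up pattern |
| C | suspect_low | flat, low-contrast profile |

The direction for C deserves a note: under the bathtub hypothesis a *large*
C flags a two-pattern patient, yet the clinical screening tables place the
small-C tail in the suspect fraction and that tail shows the highest
misclassification rate — an empirical finding that a profile with no
contrast at all (no dominant pattern) is the least reliable. The default
follows that operational record; any direction can be overridden per score.
On the synthetic cohorts both readings in fact enrich, because error arises
both from contaminated (U-shaped, high-C) and from weak-signal (flat,
low-C) patients.

A fraction f of a cohort of n contains round(n·f) patients (half away from
zero, minimum 1): 10% of 3306 is 331, 50% is 1653. The *filtered* subset is
the first round(n·f) patients of the suspect-first ranking; the *selected*
subset is the same count from the opposite (reliable) end — selected-90% is
therefore the complement of filtered-10%. Each row reports N_m, N_c, N_t,
the misclassification rate and the criterion's mean in the misclassified,
correct and total groups. At fraction 1 both subsets are the whole cohort
and the rate equals the base rate.

Retention analysis refits the discriminant on the selected subset only
(classifier refit; standardization and scores are not refitted) and
evaluates it by resubstitution on that subset; the gain column is the
difference from the next-larger retention level. Subsets on which the
discriminant cannot be fitted (a vanished class or a singleton class) are
flagged not-evaluable, never silently dropped.

Profile-group summaries collect, for a pattern pair (A, B), the groups
OK(A), OK(B), AB and BA with mean ± SE (sd/√n) of the four standardized
scores, plus a Total row, and carry the plotting arrangement that puts the
pair's own patterns on the edges — OK groups then draw L-shapes and the
misclassification groups U-shapes. Empty groups appear with n = 0 and NaN
means, singletons with NaN SEs, both flagged.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not the clinical
instrument. Each patient draws a pattern from the class priors (defaults
0.225, 0.336, 0.145, 0.294 for QD, DP, YD, FH — the clinical cohort's
marginals). Index values are Gaussian baseline noise (sd `noise_sd`); the
own-pattern block is elevated by `signal_mean`; with probability
`contamination_rate` exactly one uniformly chosen other block is elevated
by `contamination_mean`. Contaminated patients produce the U-shaped
profiles and most discriminant errors; one contaminated block (not two)
matches the observed two-pattern confusion structure. A Bernoulli
symptom-flag mode (`binary_mode`) and nonnegative clamping are available
behind config switches; continuous severity values are the default because
they make standardization well-defined at small n.

### Calibration

The defaults `signal_mean=0.55`, `contamination_rate=0.45`,
`contamination_mean=0.55`, `noise_sd=1.0` were chosen once by grid search
at n = 3306 (fixed seed) so that the default cohort's resubstitution
misclassification rate falls in the band 28–38% around the one-third rate
the method was designed for; across a 20-seed battery the defaults give
31–35% (mean ≈ 33%). These values are the package's study conditions and
are not tuned per analysis.

### What the generator does not emulate

Real index definitions (binary/ordinal mixtures, skew), inter-rater
disagreement between examining physicians, hospital-site structure, and
correlated indices within a block. Passing tests therefore demonstrate the
pipeline's arithmetic, invariants and qualitative screening behavior
(enrichment of the suspect tail, rising discrimination rate as retention
shrinks), not quantitative agreement with any clinical cohort — the
clinical data are not public, so the published screening rates are
reproducible only where they are pure arithmetic on printed tables (the
confusion summary, subset sizes, and the curvature identity), and those are
asserted exactly.

## Numerical choices and edge cases

* Rounding for reports: rates to two decimals, gains with explicit sign.
* Subset sizes: round half away from zero, floor of 1 patient.
* Sorting: mergesort (stable) everywhere a ranking is produced; patient id
  is the final tie-break, so reports are invariant to input row order.
* Degenerate inputs are errors, not silent successes: zero-variance
  upper-class variables, single-patient cohorts, empty cohort files,
  unknown labels (reported with line numbers), misaligned score/outcome
  tables.
* Problem sizes used by the test suite and the acceptance script: cohorts
  of 3306 (the study size) for end-to-end checks, 20-seed batteries for
  stochastic properties, 1000 random profiles for the curvature identity.

## Known limitations

* The discriminant variant used in the original analysis is unspecified;
  exact reproduction of its confusion matrix from patient data is not
  possible without the clinical cohort.
* The screening evaluation is resubstitution throughout (by design, to
  mirror the source analysis); no held-out or cross-validated rates are
  computed.
* The profile placement scheme and the b2 = C/4 identity are specific to
  four patterns; the package does not generalize to other class counts.
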