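# patternscreen

Screening for likely misclassifications in a four-pattern diagnostic
classifier, using the shape of each patient's standardized score profile.

## The problem

In traditional Korean medicine, stroke patients are assigned one of four
syndrome patterns — Qi deficiency (QD), Dampness-phlegm (DP), Yin
deficiency (YD) or Fire-heat (FH) — from 44 clinical indices, each index
belonging to one pattern's block. A linear discriminant fitted to those
indices disagrees with the physician on roughly a third of patients. For
anyone building diagnostic standards the interesting question is *which*
patients are likely to be misclassified, so that their discrimination can
be deferred or reviewed. This package implements a profile-shape screening
method for that question, end to end, together with a synthetic cohort
generator so the whole pipeline runs and is testable without the (non-public)
clinical data.

## The method

For each patient the four block aggregates are cohort-standardized into
scores Z_QD, Z_DP, Z_YD, Z_FH and sorted descending into order statistics
Z(1) ≥ Z(2) ≥ Z(3) ≥ Z(4). Four criteria summarize the profile shape:

    D = Z(1) − Z(2)        R = Z(1) − Z(4)
    S = Z(2)               C = (Z(1) + Z(2)) − (Z(3) + Z(4))

A clear-cut (correctly classified) patient has an L-shaped profile — one
dominant score; a patient torn between two patterns has a U-shaped
("bathtub") profile — two high, two low scores. C also equals four times
the curvature b2 of the least-squares parabola through the rearranged
points (1, Z(1)), (2, Z(3)), (3, Z(4)), (4, Z(2)): the identity b2 = C/4
holds exactly and is tested against a generic least-squares solver.

Each criterion is evaluated as a screen: the cohort is ranked
most-suspect-first, and at 10% steps the *filtered* (suspect) fraction's
misclassification rate is compared with the cohort base rate, while the
discriminant is refitted on the *selected* (reliable) fraction to measure
the discrimination-rate gain from excluding suspects. The classifier is a
classical pooled-covariance linear discriminant (priors proportional to
class frequencies, resubstitution evaluation), and each disagreement gets a
type code concatenating physician and model labels (e.g. `DPFH`) — 12
possible misclassification types.

## Worked example

```python
import patternscreen as ps

cfg = ps.CohortConfig(seed=1)           # n=3306, calibrated defaults
records = ps.generate_cohort(cfg)
X = ps.feature_matrix(records, cfg.block_sizes)
y = ps.labels_array(records)
model = ps.fit_lda(X, y)
outcomes = ps.outcome_table([r.patient_id for r in records], y, ps.classify(model, X))
summary = ps.confusion(outcomes)
print(f"{summary.overall_rate:.2f}% correct, {summary.n_misclassified} misclassified")

scores = ps.score_table(records, cfg.block_sizes)
tab = ps.screening_table(outcomes, scores, "D", fractions=(0.1, 0.5))
print(tab[tab.side == "filtered"][["fraction", "n_t", "n_m", "rate_m"]].to_string(index=False))
```

prints

```
67.45% correct, 1076 misclassified
 fraction  n_t  n_m    rate_m
      0.1  331  158 47.734139
      0.5 1653  686 41.500302
```

Read: the discriminant misclassifies 32.55% of this synthetic cohort
overall, but among the 331 patients (10%) ranked most suspect by the D
criterion the rate is 47.73% — the screen concentrates misclassifications.
Refitting the discriminant on the most reliable 90% raises the resubstitution
discrimination rate from 67.45% to 69.45%:

```python
gains = ps.discrimination_gain(X, y, [r.patient_id for r in records],
                               scores, "D", fractions=(0.5, 0.9))
print(gains[["retention", "n", "rate", "gain"]].to_string(index=False))
```

```
 retention    n      rate     gain
       1.0 3306 67.453116      NaN
       0.9 2975 69.445378 1.992263
       0.5 1653 77.011494 7.566116
```

The same analysis runs from the shell:

```
patternscreen run-all --n-patients 3306 --seed 1 --out-dir out/
```

which writes the cohort, the per-patient score table, outcome and confusion
tables, per-criterion screening and gain tables, and a run manifest (same
seed, same bytes).

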