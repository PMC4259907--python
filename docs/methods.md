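# Methods

This note documents the statistical model behind `crowdgrade`, the default
parameter values and why they were chosen, the design decisions that were
genuinely open, and what the synthetic-data experiments do and do not show.

## Grading scales and consensus rules

Images are graded on one of three nested ordinal scales, coded as consecutive
integers from 0 with 0 = normal:

| scale      | codes | labels                                    |
|------------|-------|-------------------------------------------|
| two_cat    | 0–1   | normal, abnormal                           |
| three_cat  | 0–2   | normal, mild/moderate, severe              |
| four_cat   | 0–3   | normal, mild, moderate, severe             |

Projection between scales merges mild and moderate (4→3) or collapses every
disease grade to abnormal (4→2). Projection commutes with binarization, which
the test suite asserts exhaustively.

**Mean-threshold rule.** The consensus grade for a mean crowd score *m* is
the code *k* with *m* ∈ [k − ½, k + ½); the top bin is closed above. A mean
exactly on a boundary goes to the *higher* (more severe) bin: a mean of 0.50
is abnormal. This directionality matters clinically — in a screening
instrument ambiguity should escalate, never reassure.

**Mode rule.** The unique most frequent grade when one exists. When the top
frequency is shared, the *strict* policy reports a NO_CONSENSUS sentinel and
the *clinical* policy returns the most severe tied grade. Strict is the
default because it is the bookkeeping used for tabulating percent-correct;
clinical is what one would act on for a patient.

**Order of operations.** Binarization does not commute with the mode
(grades [0,0,1,2,3] have four-category mode *normal* but binary mode
*abnormal*), so sensitivity and specificity are always computed by collapsing
the *consensus* grade, never by aggregating pre-collapsed ratings.

**NO_CONSENSUS accounting.** A no-mode image counts as incorrect for
percent-correct and is recoded as abnormal for sensitivity/specificity. The
two rules together mean an unresolved crowd can depress agreement statistics
but can never produce a false negative.

## Diagnostic accuracy

Accuracy is computed at two levels: per grading instance (every rating scored
against the expert grade) and per image (the consensus grade scored).
Percent-correct is exact agreement on the working scale; sensitivity and
specificity are binary. Percentages are reported rounded to one decimal,
half-up, matching conventional table formatting; internal values keep full
precision.

The ROC area is the tie-corrected Mann–Whitney statistic computed from
average ranks: the probability that a randomly chosen abnormal image outscores
a randomly chosen normal one, counting ties as ½. The ½-per-tie correction is
the only choice for which an uninformative constant score yields exactly 0.5.
Because average ranks are half-integers, the rank formulation is *bit-exact*
against an exhaustive pairwise count, and the suite asserts exact equality on
random instances rather than approximate agreement.

## Task economics

The effective hourly wage is 3600 · pay / (mean seconds per rating), rounded
half-up to cents; it uses the payment to the worker only. The requester's
cost per image is raters · pay · (1 + commission). Commission appears in the
cost and not the wage: the platform's surcharge is paid by the requester and
never reaches the rater. This assignment is the only one consistent with all
six published wage and cost figures the package reproduces (wages 14.31,
7.08, 6.60, 7.06, 9.28, 12.23 USD/h; costs 1.10 and 1.95 USD at 10% and 30%
commission).

## Crowd-size experiment

Given pools of hundreds of independent ratings per image, the experiment
draws, for each crowd size k and each of `n_draws` replicates, a random
sub-crowd of k ratings per image **without replacement** (bootstrap draws
with replacement are available behind a flag but are not the default: the
question is what k *distinct* raters would deliver). Each image is scored by
its sub-crowd mean and each replicate yields one AUC against the binarized
expert labels; the curve reports the per-k mean and variance over replicates.

* `k_range` defaults to 1–50 and `n_draws` to 50; validation tests raise
  `n_draws` where extra Monte-Carlo stability is needed.
* The plateau is the smallest k whose mean AUC is within `tolerance`
  (default 0.01) of the maximum over all k.
* Randomness is counter-based: each (k, draw, image) triple derives its own
  RNG substream from the master seed (`SeedSequence(seed, spawn_key=(k,
  draw, image))`), so results are independent of iteration order. Pools are
  canonically sorted before each seeded shuffle, making draws a function of
  the multiset of grades rather than row order.
* Each replicate pools all images into a single AUC. A per-severity variant
  is available by composing `severity_contrast_auc` with per-image crowd
  means; with one image per severity level, contrast AUCs at the draw level
  would be 0/½/1-valued and uninformative, which is why the pooled
  convention is the primary one.

A degenerate truth (one class absent) raises an explicit undefined-AUC error
rather than returning a conventional value.

## Synthetic crowds

The generator exists so every pipeline stage can be validated without any
external data. A rater archetype is a row-stochastic 4×4 confusion matrix
(rows = true grade, columns = reported grade) plus a log-normal duration
model. Builtin archetypes:

* **accurate** — diagonal-dominant; binary sensitivity 94% and specificity
  70% per rating, matching the observed marginal rates of individual crowd
  raters on this task (93.6% / 67.8%).
* **moderate_biased** — the documented severity-staging error pattern:
  mild disease is often missed entirely (0.30 mass on normal) and every
  abnormality is pulled toward grade 2, so moderate disease is resolved well
  while mild and severe contrasts suffer.
* **severity_inflating** — systematically reports higher grades than the
  truth, the signature of an outlying rater.
* **random_bot** — answers uniformly at random *over the options presented*
  (probability ½ per option on a two-category task, ¼ on four), emulating a
  spam account; a bot's behaviour depends on the response interface, not on
  the underlying four-grade scale, so it is flagged `uniform_over_scale`
  rather than expressed as a projected confusion matrix.

Durations are log-normal with the genuine-rater median set to 25.16 s (the
observed mean two-category task time; log-sd 0.35) and the bot median to 4 s:
strictly positive and right-skewed, as task times are.

Crowds are archetype mixtures. With `shared_raters=True` (default) a
persistent roster grades every image — the regime outlier screening assumes;
with `False` each image gets a fresh anonymous pool — the deep-pool regime of
the crowd-size experiment.

**Calibration.** The deep-pool experiment uses an accurate/random_bot mixture
whose weight is solved in closed form so the expected per-rating binary
accuracy on the four prototype images equals 81.3%, the observed individual
rating accuracy on the two-category task. Expected accuracy is linear in the
weight, so no fitting is involved; the resulting weight is ≈0.82 accurate /
0.18 bot. Under these conditions the plateau lands at 7–11 raters across
seeds — consistent with the reported finding that accuracy saturates at
roughly 7–10 raters — and this is a genuine prediction of the calibrated
generator, not a fitted value.

**Parameter recovery.** `recover_confusion` row-normalizes empirical
reported-given-true counts; at 2 000 ratings per true grade the multinomial
standard error per cell is below 0.011, so the 0.05 max-abs recovery bound
used in validation has a wide margin. True grades with no ratings yield NaN
rows plus a warning rather than an error.

**Outlier screening.** Raters are screened on their mean grade with a
two-condition rule: flag when the modified z-score 0.6745·(x − median)/MAD
exceeds 3.5 (the customary cut-off for that statistic) *and* the absolute
shift from the cohort median is at least 0.5 grade units. The second
condition is essential: with cohorts of ~20 raters the MAD is a noisy scale
estimate and the maximum modified z among perfectly honest raters has a heavy
tail (simulation: it exceeds 8 in ~5 of 10 000 cohorts), so a z-threshold
alone cannot separate honest raters from systematic inflators reliably. Half
a grade step is the natural effect-size floor — a rater whose average sits
within rounding distance of the cohort is not grading systematically higher
or lower. Median/MAD (not mean/SD) keeps a gross outlier from masking
itself. Raters with fewer than `min_ratings` (default 5) ratings are
skipped; a zero MAD (perfectly homogeneous cohort) flags nobody.

## What the generator does and does not emulate

It emulates: ordinal confusion structure per rater type, mixture crowds,
interface-dependent bot behaviour, right-skewed task durations, and
reproducible (byte-for-byte) output from a seed.

It does **not** emulate: per-image difficulty variation within a grade
(all images of one true grade are exchangeable), rater learning or fatigue
over time, correlation between a rater's speed and accuracy, intra-rater
test–retest variability, or non-response/abandonment. Passing the synthetic
validation therefore shows the *pipeline* is correct under the stated error
model; it does not certify performance on real image streams, where
difficulty heterogeneity typically flattens accuracy-versus-crowd-size curves
and can push the plateau upward.

## Numerical conventions and problem sizes

* Grade codes are integers; labels are presentation-only.
* CSV interchange is comma-separated UTF-8 with a header; floats are written
  at full precision and read back with round-trip parsing, so
  read(write(t)) = t exactly.
* Boundary means go to the higher bin; the top bin is closed above.
* Sensitivity/specificity are NaN (JSON null) when the truth contains no
  abnormal (resp. normal) unit, never a division error.
* Validation problem sizes were chosen for tight Monte-Carlo bounds at
  interactive runtimes: 500-deep pools × 4 images × 50 draws × k ≤ 50 for the
  crowd-size experiment (20 independent pools), 2 000 ratings per true grade
  for recovery, 100-image streams × 20 raters × 100 trials for outlier
  screening.

## Known limitations

* The 19-image reference fixture stores one reconciled cell: the published
  three-category expert rating of image 8 contradicts the same image's
  two- and four-category ratings and the published specificity (5/7); the
  fixture records the image as normal on all three scales and keeps the
  discrepancy in provenance metadata.
* The mean-threshold rule's behaviour for a mean exactly at the top boundary
  is fixed by the closed top bin; no reference value exercises it.
* Archetype mixture weights beyond the calibrated accuracy anchor are free
  parameters of the simulation, not measured quantities.
* The package does not implement probabilistic annotator models
  (Dawid–Skene and relatives); the analysis it supports uses only the mean
  and mode rules.
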