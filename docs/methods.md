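# Methods

This note records the models, parameter choices and numerical
conventions behind `qbcal`, and what its synthetic benchmarks do and do
not show about real imaging data.

## The uncertainty score

For each pool sample, the M committee members produce class
distributions p₁ … p_M (binary in the glioma-grading setting, but C ≥ 2
is supported throughout). The informativeness score is

    score = Σₘ H(pₘ) + Σ_{m ≠ m'} D(pₘ ‖ pₘ'),

entropy plus Kullback–Leibler disagreement over **all ordered member
pairs**. KL is asymmetric; summing both directions of every pair is the
symmetrized form, and for M = 2 it equals Jeffreys divergence. Every
term uses the natural logarithm (nats). The only downstream consumer is
the *ranking*, which is invariant to the log base and to the ordered-
vs-unordered pair convention (a global factor of 2); both invariances
are asserted in the test suite.

Numerics: probabilities are validated to sum to 1 within 1e-6;
`0 · log 0` is defined as 0, so degenerate distributions have exactly
zero entropy; inside KL the denominator distribution is clipped to
≥ 1e-12 (no renormalization) so saturated classifier outputs give large
but finite divergences, and the O(1e-12) negative drift this can
introduce is clamped at 0. Ranking ties are broken by ascending
`sample_id`, making selection fully deterministic.

## Committee construction

All members are the same classifier trained on the same labeled seed
subset; only the learning rate differs (defaults 0.001, 0.0005, 0.0001;
SGD with 30 epochs, batch 16, momentum 0.8, L2 penalty 1e-4). Each
member's RNG seed is `config.seed + member_index`, so members are
individually reproducible.

Members fine-tune from a **shared warm start**: unless a `pretrained`
model is supplied, `build_committee` first trains a base model on the
seed subset under the base config and every member continues from its
parameters. This mirrors fine-tuning a single pretrained network at
several learning rates, and it is what makes the disagreement term
meaningful for a convex reference member: trained from zero, members
separated by a 10× learning-rate span differ mostly in weight *scale*,
and the KL between two sigmoids that differ only in scale grows with
the margin — the score would then reward the most confident samples.
From a shared start the members agree in scale, entropy dominates, and
disagreement concentrates on genuinely ambiguous samples.
`shared_init=False` restores independent training for classifiers where
that is wanted.

### The reference classifier

`PixelSoftmaxClassifier` is multinomial logistic regression over
flattened, channel-concatenated pixels, written in numpy with exactly
the minibatch-SGD-with-momentum update the committee's `TrainingConfig`
describes. Weights start at zero (or at the warm-start parameters), so
a fit is bitwise reproducible from (data, config, seed). It is the
package's desk-scale committee member; any model implementing
`fit`/`predict_proba` — e.g. a fine-tuned CNN — can replace it through
the `TrainableProbabilisticClassifier` contract.

When a validation set is passed to `fit`, the epoch checkpoint with the
highest validation ROC-AUC is kept (early stopping at the best epoch);
otherwise training runs to `max_epochs`. The evaluation harnesses
accept the same optional validation set. The bundled sweep benchmarks
do **not** use it: checkpoint selection largely rescues models trained
on contaminated subsets, which is desirable in practice but suppresses
the very contrast (clean vs contaminated training sets) those
benchmarks exist to measure.

## Selection and cost accounting

Positions in the descending ranking are addressed by half-open
fractional ranges `[floor(lo·N), floor(hi·N))`, so adjacent ranges
tile without overlap. Extreme exclusion is `select_range(q_top, 1 −
q_bottom)` with 10%/10% defaults. The budget is a fraction of the
**full** pool, converted to a count by round-half-up
(`proportion_to_count`), and drawn uniformly without replacement from
the retained middle. Fraction-to-count conversion reproduces the whole
correspondence table for the 4,060-slice imbalanced and 4,870-slice
balanced pools exactly.

Cost bounds follow from set arithmetic: with seed fraction s and budget
b, labels needed = |seed ∪ selected| ∈ [max(s, b), min(1, s + b)];
saving = 1 − needed. At s = b = 0.30 the band is 40–70%, mean 55%. When
both id sets are known the measured union is reported and checked
against the bounds.

Selection operates at slice level while dataset splits are assigned at
patient level; the selected subset alone (not its union with the seed)
is what retraining uses — the union enters only the cost accounting.

## Slice pipeline

Patient records carry four co-registered modalities (T1, T1C, T2,
FLAIR) and a segmentation with labels {0, 1, 2, 4}; any non-zero voxel
is tumor. The axial direction is the third array axis. From each
patient, k distinct tumor-bearing planes are drawn uniformly (strict
mode errors when fewer than k exist; permissive mode takes all with a
warning). Each slice stacks T1/T1C/T2 — FLAIR is read and stored but
never emitted — min-max normalizes each channel to [0, 1] per slice,
and resizes bilinearly to the target square. Per-channel min-max is the
least parametric standardization that makes the pipeline invariant to
modality gain; a consequence worth knowing is that absolute lesion
brightness is removed, so grade information survives only as
lesion/background contrast *structure*.

Splits are patient-level: HGG and LGG counts per split are apportioned
by largest remainder of each split's share, then patients are assigned
within grade by a seeded shuffle. For 259 HGG + 76 LGG into 203/66/66
this yields 157+46 / 51+15 / 51+15, and no patient ever contributes
slices to two splits. The count identities are exact: 20 slices per
patient gives 6,700 records on a 335-patient cohort; the balanced
variant (10 per HGG, 30 per LGG) gives 4,870.

## Synthetic data

### Phantom cohorts

Each phantom patient is a small volume (default 12 × 12 × 34 voxels)
with Gaussian background (sd 0.05), an axis-aligned ellipsoidal lesion
whose nested shells carry labels 1 (necrotic core, r ≤ 0.35), 4
(enhancing rim, r ≤ 0.7) and 2 (edema, r ≤ 1), and a grade-dependent
lesion intensity shift (contrast 0.3, scaled 1.0 for HGG vs 0.4 for
LGG, strongest in T1C). The axial half-span guarantees at least
`min_tumor_planes` tumor-bearing planes (default 30, enough for the
balanced 30-slices-per-LGG build). Randomness flows from the spec seed
through per-patient `SeedSequence` spawn keys, so cohorts regenerate
stably. After per-slice min-max normalization the phantom grade signal
yields held-out slice AUC near 0.8 with the reference classifier —
deliberately in the range of real slice-level glioma grading rather
than a toy-separable task. Phantoms contain no bias fields, partial
voluming, anatomy or scanner effects.

### Planted-structure slice tasks

`make_slice_task` builds a flat 2D task around a fixed unit-norm random
pattern u (default 8 × 8 × 3 images, i.e. 192 features): class
prototypes ±(class_sep/2)·u with per-pixel noise sd 1 (class_sep
default 5.0, balanced classes). Two planted subpopulations, each 10% of
n by round-half-up and placed in the train split only so held-out
metrics stay clean:

* **duplicates** — near-copies (noise sd 0.05) of an archetypally easy
  exemplar at 1.8× the class prototype. They carry almost no training
  information and should be ranked uninformative. The 1.8× scale places
  them inside the excluded bottom tail; copies of the class *mean*
  would sit at merely average margins and survive exclusion.
* **outliers** — mislabeled samples (label flipped) whose class signal
  is attenuated to 0.5×, leaving the image noise-dominated. They
  provoke committee disagreement and, when trained on, persistently
  shrink the learned signal coefficient. Isotropic noise *inflation*
  was measured and rejected as the outlier mechanism: for a linear
  member, inflating per-pixel noise enlarges |w·x| margins and makes
  outliers look more confident, not less.

Under the defaults the committee round recovers the plant reliably
(outliers out-score duplicates and exceed 2× their base rate in the top
decile in 20/20 design-phase replicates).

## Evaluation

ROC-AUC is the Mann–Whitney probability that a positive outranks a
negative, ties counted ½ (delegated to scikit-learn; the test oracle is
an independent all-pairs enumeration). Repeated runs are summarized as
mean ± 1.96·sd/√n (sample sd, n − 1 denominator); a Student-t
half-width is available via `method="t"`. Ten runs is the convention
the harness defaults follow; benchmark procedures below use fewer runs
per replicate and more replicates, which spends the same compute where
the variance actually is (subset draws, not training noise).

`range_sweep` requires equal-width ranges so every arm trains on the
same number of samples; `size_sweep` compares, at each fraction 0.1 …
0.8 of the pool, a budget drawn from the exclusion-filtered ranking
against a uniform draw from the untouched pool, with matched
cardinalities enforced, plus a full-pool baseline.

## Benchmark procedures and problem sizes

The bundled acceptance checks run entirely on synthetic data at desk
scale: count identities on a full 335-phantom cohort (seconds);
planted-structure recovery over 10 replicate rounds at n = 400
(success = outliers above duplicates and ≥ 2× top-decile enrichment in
at least 8); and the uncertainty-vs-random sweep aggregated over 240
replicate rounds with 2 training runs per cell (~2 minutes on one CPU).
The large replicate count is deliberate: for a linear member on this
task the true uncertainty-over-random margin at large budgets is a few
10⁻⁴ AUC — class-symmetric label noise shrinks the logit signal
coefficient without rotating the discriminant, so its harm fades as the
training subset grows — and resolving that ordering above seed noise
takes a few hundred draws.

Passing these benchmarks shows the mechanism works end to end: the
score surfaces planted pathology, the arithmetic is exact, and informed
selection never loses to random selection on average. It does not show
that the specific AUC levels transfer to real MRI — phantom and
planted tasks lack anatomy, scanner variation and the failure modes of
deep models — and a single selection round on one dataset is what the
design supports; iterative multi-round acquisition is out of scope.

## Known limitations

* The reference member is linear; conclusions about *which* samples a
  deep committee would find uncertain do not follow.
* Selection imposes no patient-level constraint: slices of one patient
  may split between selected and unselected (splits themselves remain
  leakage-free).
* The CI is a normal approximation at n = 10 runs; with very small run
  counts prefer `method="t"`.
* `proportion_to_count` rounds half up; other conventions would shift
  counts by at most one sample.
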