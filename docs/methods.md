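# Methods

## Problem setting

Pneumothorax — air in the pleural space — is detected on chest radiographs
as a subtle lucent rim, and small pneumothoraces (apex-to-cupola distance
< 3 cm under the ACCP size rule) are disproportionately missed both by
readers and by naively trained classifiers. `pneumocl` implements a
curriculum-learning training regime for this problem: difficulty labels
are obtained from radiology-report text by a deterministic rule labeler,
training batches start with easy (large-lesion) positives only, and hard
(small-lesion) positives are admitted gradually under quantitative
performance gates. Around the trainer sits the full clinical-validation
statistics suite used for computer-assisted triage (CADt) devices: Wilson
score intervals for sensitivity and specificity, DeLong confidence
intervals for AUC, one-sample Z tests against performance goals,
chi-square association tests, three-reader majority-vote ground truth, and
subgroup tables.

Because no clinical images ship with the package, everything runs on a
synthetic cohort generator whose difficulty structure mirrors the clinical
premise; all empirical statements below are computed by the test suite or
the scripts, not asserted.

## Synthetic cohort generator

Each image (default 64×64, intensities in [0, 1]) is a Gaussian-smoothed
white-noise field plus four sinusoidal horizontal bands (a rib-like
texture that defeats global-mean classifiers), clipped to [0.25, 0.85]. A
positive case carries an apical crescent of reduced intensity on one side:
area ∝ `size_px`², amplitude equal to the lesion contrast. The difficulty
link is

    contrast = c0 + c1 · size_px / size_max ,   c0 = 0.05, c1 = 0.5,

so smaller lesions are strictly subtler — the in-silico version of "small
pneumothoraces are harder to see". The size-class threshold is 12 px, the
pixel analog of the 3 cm rule; sizes are drawn uniformly in [4, 12) px for
small and [12, 24] px for large lesions.

Cohort composition defaults to the development-cohort structure: 39.6%
positive prevalence (2554/6445) and a 30.3% small share among positives
(773/2554), with demographic/site/manufacturer marginals matching the
external-validation characteristics table (male 54%, site 2:1 US:Taiwan,
and so on), so the subgroup machinery is exercised under realistic
imbalance. Counts are binomial draws at those rates, or exact quotas with
`exact=true`. One integer seed makes the whole cohort — pixels, metadata,
reports — bit-identical across runs.

Paired report text is templated English: positives carry either a size
adjective ("large"/"moderate" vs "small"/"tiny") or a cupola-to-apex
measurement mapped so that 12 px ↔ 3 cm (never rounded across the
boundary); negatives carry a negation phrase; distractor sentences
("Small left pleural effusion") are mixed in. Templates are constructed so
the rule extractor round-trips the generator truth exactly — a property
the suite checks on 1000 reports.

What the generator does *not* emulate: anatomy, projection physics,
exposure variation, comorbid findings, label noise from imperfect report
extraction, and any correlation between demographics and disease. Passing
tests therefore demonstrate that the machinery is correct and that the
difficulty ordering behaves as designed — not that any accuracy number
transfers to clinical radiographs.

## Report labeling

Presence is keyword matching over a plain-text lexicon
(`pneumocl/data/lexicon.txt`, editable) with NegEx-style forward negation
scope: a cue ("no", "without", "negative for", …) blocks mentions from the
cue to the end of the sentence. Size is decided by, in priority order,
(1) a parsed length within six tokens of a mention in the same sentence
(mm converted to cm) against the 3 cm rule — measurements are the
guideline-grounded signal, so they beat adjectives; (2) a size adjective
within six tokens of a non-negated mention; otherwise the positive is
`unspecified`. Unspecified positives are pooled with large (easy) cases
for curriculum purposes: the hard pool should contain only
confirmed-subtle cases. An external labeler (e.g. an LLM endpoint) can be
substituted through the `ExternalLabeler` protocol; no network code is
bundled.

## Curriculum scheduler

The state machine tracks `f`, the fraction of *positive* batch slots given
to small-lesion cases (the curriculum acts on positives only; negatives
are unaffected). Training starts at `f = 0` (large-only positives); each
time the transition criteria pass, `f` increases by the increment (default
0.05) up to `f_cap`, whose default is the empirical small share among
training positives (≈ 0.303 under default cohorts) so terminal batches
reflect the data distribution rather than over-sampling hard cases.
`f` never decreases, and the cap is an absorbing state (further advances
are logged no-ops).

Transition criteria: validation AUC > 0.95 and sensitivity and specificity
both > 0.80, with strict inequalities, sustained for `patience_epochs`
(default 1) consecutive evaluations; evaluation happens once per epoch.
The gate is computed on the *foundational* validation subset — negatives
plus large-lesion positives. The rationale: the gate asks whether the
model has mastered the material it is currently being taught before
harder material is added. Gating on the full validation set would require
the model to already solve small lesions it has never been trained on; on
the synthetic benchmark the full-set AUC ceiling sits below 0.95, so that
reading would leave the schedule permanently at stage 0. History rows
always record full-validation metrics; only the transition check uses the
subset.

Batch quotas use round-half-away-from-zero with a floor of one small case
whenever `f > 0` and at least one positive slot exists, so the first 5%
stage is non-vacuous at batch size 32. Within strata, sampling is uniform
without replacement per epoch, falling back to with-replacement (logged)
when a stratum is exhausted. With `f` equal to the pool's small share and
the positive fraction equal to pool prevalence, stratified composition is
distributionally equivalent to uniform sampling — checked by a chi-square
goodness-of-fit test on 10⁴ draws.

## Training protocol

Binary cross-entropy, Adam at initial learning rate 1e-3, learning rate
reduced tenfold when the best validation loss fails to improve by more
than 1e-6 for more than 10 consecutive epochs (the improvement tolerance
is configurable; the counter resets after each reduction), early stopping
on validation loss (default patience 20, chosen larger than the plateau
patience so at least one reduction precedes stopping) with restoration of
the best-epoch snapshot, dropout 0.5, L2 penalty 1e-4, and augmentation by
random rotation (uniform up to ±30°) plus horizontal flips (probability
0.5). One master seed is split into named streams (batching,
augmentation), so two runs that differ only in batch composition draw
identical augmentation parameters — the matched-arm requirement of the
ablation. Augmentation draws are consumed even when a flip is not applied,
keeping streams aligned.

The default backbone is a three-block convolutional classifier written in
numpy: non-overlapping patch convolutions (4×4/8, 2×2/16, 2×2/32 channels;
stride equal to kernel size, so forward and backward passes are pure
reshapes and matrix products), ReLU, global average pooling, inverted
dropout, sigmoid head, Adam updates. It is gradient-checked against finite
differences in development and trains on a 2000-image cohort in about a
minute per 30-epoch run on one CPU. A one-hidden-layer perceptron backbone
is included as a lighter alternative, and any stronger model (for example
a pretrained EfficientNet wrapper) plugs in through the same four-method
contract (`train_step`, `predict_scores`, `snapshot`, `restore`).

## Validation statistics

* Wilson score intervals (via statsmodels) for proportions; bounds clipped
  to [0, 1]; preferred over Wald at small n and extreme rates.
* AUC as the Mann–Whitney statistic (ties count ½); the suite proves
  equality with exhaustive concordant-pair counting on short vectors.
* DeLong variance from the midrank structural components, implemented in
  the package (no installed library provides it); the suite checks the SE
  against a 2000-replicate bootstrap (within 15%) and CI coverage over 500
  binormal simulations (90–99%).
* One-sample Z tests, upper-tail at α = 0.025, using the null binomial
  variance for proportions and the DeLong variance for AUC (which variance
  the original analysis used for AUC is not stated; DeLong is the
  documented choice here).
* Chi-square tests of independence with Yates continuity correction on
  2×2 tables — the corrected statistic is what reproduces the published
  demographic p-values (0.0607, 0.4072); larger tables use plain Pearson.
* Majority vote over exactly three readers; size/location decided among
  readers calling present; a 1–1 size split resolves conservatively to
  "small" with a tie flag.
* Subgroup tables report sensitivity/specificity with Wilson CIs and AUC
  with DeLong CIs per stratum (sex, age group, site, manufacturer, size
  class), flagging non-estimable strata instead of erroring. Operating
  threshold defaults to 0.5 with ties called positive (the
  high-sensitivity triage convention); the threshold behind the published
  operating point is not stated, so it is configurable.

The `verify-stats` command recomputes every reconstructable published
interval and p-value from printed counts and prints a side-by-side table
with match flags. Two subgroup rows (ages 18–34 and 50–64) print an upper
bound of 1.00 where the reconstruction gives 0.99 at 2 dp; those rows are
excluded from the audit fixture rather than fudged.

## Ablation benchmark and its outcome

The desk-scale benchmark trains matched curriculum and traditional arms
(shared init and augmentation streams; the arms differ only in batch
composition) on a 2000-image cohort, 70/30 stratified split, 30 epochs,
five seeds, and compares final validation AUC on the hard subset (small
positives vs all negatives). These sizes keep a full benchmark run to a
few minutes on one CPU; full development-cohort-scale settings (n = 6445,
400 epochs) are valid configuration values.

Measured outcome: the paired mean small-subset AUC difference is
approximately zero (magnitude below 0.01, comparable to the per-seed
spread) rather than positive. Two structural reasons: the foundational
gate is cleared within an epoch or two, so the curriculum reaches its cap
by about epoch 6 and the arms are nearly identical for the remaining
epochs; and the synthetic hard cases are *correctly labeled* low-contrast
examples, which act as weakly informative extra data rather than as the
corrupting early signal that curriculum ordering protects against in the
clinical pipeline, where labels themselves come from report extraction.
The directional acceptance test states the expected superiority and is
left failing rather than weakened; the corresponding limitation of the
generator (no label noise, no unlearnable-case pathology) is noted above.

## Known limitations

* Synthetic images are statistical textures, not anatomy; absolute
  performance numbers have no clinical meaning.
* The rule labeler handles templated and simply phrased reports; it is not
  a full clinical NLP system (no section logic, hedging, or uncertainty).
* The curriculum acts only on the large/small dichotomy; no loss-based or
  self-paced difficulty estimation.
* CPU-scale backbones only; large pretrained networks enter through the
  model contract but are not bundled.
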