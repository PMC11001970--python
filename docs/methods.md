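# Methods

`psychonc` implements a prognostic text-classification pipeline: from a
patient's *initial oncology consultation document*, predict whether they
will see a psychiatrist, or a counsellor, within the following 12
months.  Both outcomes are rare-to-moderately imbalanced binary labels
(1.4% and 21.1% prevalence in the population the package emulates).
Because the clinical corpus that motivates the pipeline is confidential,
the package ships a synthetic-corpus generator that reproduces the
statistical structure the analysis depends on; every stage downstream of
the generator treats synthetic and real data identically (same JSONL /
CSV schemas).

## Cohort definition

Patients enter the cohort if they started cancer care exactly once and
have at least one medical- or radiation-oncology consultation within 180
days of diagnosis (day offsets in the closed interval [0, 180]).  The
sole model input per patient is the **index document**: the oncology
consultation minimizing |day − diagnosis day|, ties broken toward the
earlier day and then the smaller document id.  The outcome label is 1
iff a psychiatry (resp. counselling) document exists with day offset in
(0, 365] after the index document — a same-day contact does not count as
"after", and "12 months" is fixed at 365 days to avoid calendar
ambiguity.  Data are split 70/10/20 into training/development/test at
the patient level with largest-remainder rounding (47,625 patients give
a test set of exactly 9,525).

## Synthetic corpus

Each patient carries a latent psychosocial-need pair
(z_psych, z_counsel), standard bivariate normal with correlation ρ
(default 0.6).  Each configured **signal token** (a word or phrase) is
emitted into the patient's document with probability
σ(logit(emit_base) + emit_slope·z̄), where z̄ weights the two latent
scores by the token's absolute outcome effects.  Labels are then
Bernoulli in the emissions:

    P(outcome = 1 | emissions e) = σ(b + Σ_t β_t e_t)

with the intercept b solved numerically — Gauss–Hermite quadrature over
the latents, enumeration of the 2^T emission patterns, then bisection —
so the marginal prevalence equals the configured value exactly in
expectation.  With all β = 0 the labels are independent of the text, an
exact null corpus.

Document length is log-normal matched to the configured mean/SD
(defaults 973/354 tokens) and floored at 50; documents carry the six
canonical consultation sections in order (identifying information,
history of presentation, medical and other histories, physical
examination, impression/assessment, recommendation/plan), with filler
tokens drawn Zipf-weighted from a packaged ~650-word clinical
vocabulary.  The rule-based comparator's trigger forms ("psychiatrist",
"counselling" and variants) are deliberately excluded from filler, so
their document frequency is controlled solely by signal emissions —
mirroring how rare and informative they are in real consultations.
Demographics default to the emulated population: age ~ N(64.9, 13.7²)
truncated at 18, 53.4% female, stage mix (13.7/18.5/13.1/13.2/41.6)%,
51.5% radiation-oncology authorship.  For label-positive patients a
clinician-contact document is planted at a truncated-normal day offset
(psychiatry mean 5.3 months SD 3.4; counselling 2.5/3.1; resampled into
(0, 365]).  Exclusion flags can be planted at configured rates or at
exact counts.  Everything is deterministic given (config, seed).

What the generator does *not* emulate: realistic clinical prose,
discourse structure beyond section headers, multi-site vocabulary
differences, or label noise from missed referrals.  Passing tests
demonstrate that the pipeline recovers known planted structure under
realistic marginals; they cannot certify performance on real clinical
text.

## Preprocessing dialects

* **bow** — lowercase, punctuation stripped, numerals kept whole,
  Snowball (Porter2) suffix-stripping.  Porter2 rather than original
  Porter because it reproduces the stem surface forms the coefficient
  tables are written in ("anxious" stays "anxious"; original Porter
  yields "anxiou").
* **neural** — lowercase word tokens, no stemming.
* **transformer** — WordPiece-style subword pieces with `##`
  continuations.  No pretrained vocabulary is bundled, so the
  vocabulary is trained on the corpus at hand (frequent whole words +
  frequent prefixes/suffix continuations, greedy longest-match,
  character fallback).

Truncation, where configured, keeps the first `max_tokens` tokens and
drops the tail.

## Model zoo

All families expose `fit(train, y, dev, y)` and
`predict_proba -> [0, 1]`; evaluation code never branches on family.

* **rule** — predicts positive iff the target's trigger stem
  ("psychiatrist" / "counsel") occurs; the triviality baseline.
* **bow** — occurrence counts (training-vocabulary, min document
  frequency 5, no stop-word removal) into L2 logistic regression; C is
  selected on development-set balanced accuracy from
  {10⁻³, 10⁻², 10⁻¹, 1}.  Count features are variance-standardized
  (scaled by their training SD, not centred) before the ridge penalty:
  with raw counts the penalty is scale-unfair and several hundred
  weakly-fit filler coefficients can drown a rare informative token at
  165 training positives.  Features remain counts up to a fixed
  per-token rescaling.
* **cnn** — learned embeddings → parallel 1-d convolutions of widths
  {2, 3, 4} (64 filters each by default) → ReLU → global max-pool →
  dropout 0.5 → linear score.
* **lstm** — one bidirectional LSTM layer (hidden width 128 by
  default) → pooling over time → linear score.
* **transformer** — learned embeddings + damped sinusoidal positions →
  one single-head self-attention block with residual and ReLU
  feed-forward → pooling → linear score.  Positional capacity
  (`n_positions`) is fixed at construction; `max_tokens` must be one of
  {512, 1024, 2048, 4096} and cannot exceed it.  The slot trains from
  scratch at desk scale; it honours the same truncation, undersampling
  and early-stopping contracts a fine-tuned encoder would.

The networks are plain numpy with hand-written backprop (verified
against numerical differentiation in the test suite) and Adam.
Embedding row 0 (padding) is frozen at zero.

**Pooling.**  The LSTM and transformer pool over time with a
feature-wise **max** by default (`pooling="mean"` is available).  At
desk scale, mean-pooling dilutes single-token evidence by 1/L (L ≈ 10³),
and both models collapse to chance on corpora the CNN (whose max-pool is
built in) solves; max-over-time preserves presence evidence regardless
of document length.

**Class imbalance.**  `loss_weighting` applies per-class weights
n/(2 n_c), giving a positive:negative weight ratio equal to the inverse
class-frequency ratio ((1−p)/p ≈ 70:1 at p = 1.4%).  `undersample`
keeps every positive and subsamples negatives to 1:1 without
duplication.  The packaged desk-scale presets train neural families
with undersampling (the regime the token-limit comparison prescribes)
and BoW with loss weighting, which also makes BoW exactly deterministic
across repeated runs.

**Early stopping.**  Training stops when development-set balanced
accuracy has not improved for `patience` epochs (default 5); the
best-dev checkpoint is restored.  `min_epochs` (0 by default; 10 in the
desk presets) keeps training alive through the initial stretch where
dev BAC sits flat at 0.5 before the score distribution crosses the 0.5
threshold, which otherwise exhausts patience before learning starts.
For the transformer preset, per-epoch dev scoring is capped at 768
documents (all positives kept, negatives subsampled, seeded) to bound
the quadratic attention cost of scoring the full development split each
epoch; the final evaluation always uses the full test set.

## Evaluation protocol

Metrics: accuracy, sensitivity, specificity, balanced accuracy
(BAC = (sens + spec)/2), F1 (0 when precision + recall = 0), and AUC
(Mann–Whitney with midrank ties).  The decision threshold for the
thresholded metrics is 0.5.

Each family is trained 10 times with unchanged hyperparameters but
reshuffled training data (run i uses seed + i), always evaluated on the
same holdout test partition; tables report mean (SD) per metric.
Deterministic families (rule; BoW under loss weighting) print SD 0.000.
Model pairs are compared with two-tailed dependent t-tests on the
per-run differences, Bonferroni-corrected over all pairs within one
target and metric; the rule baseline is compared one-tailed
(model > rule).  Cohen's d for paired series is mean(diff)/SD(diff)
(d_z); a pooled-SD variant is available.  Zero-variance differences
with nonzero mean report p below machine precision and d = ±∞.  The
token-limit study fits OLS of a metric on `max_tokens` and reports the
slope, its two-sided p and R².

## Interpretation

* **Coefficient ranking** — BoW tokens sorted by |coefficient|, ties
  lexicographic, with sign direction.
* **Integrated gradients** — per-token attribution along the straight
  embedding-space path from an all-padding baseline (zero embedding
  row), trapezoid rule over `steps` points evaluated as one batch,
  attributing the sigmoid score by default (`output="logit"`
  available).  Completeness (Σ attributions = score(doc) −
  score(baseline)) holds within 1e-2 at 50 steps; with max-pooling
  score functions the residual has a kink-induced noise floor around
  1e-4, so strict step-wise monotonicity of the residual is a property
  of smooth scores only.
* **Attribution-filtered topics** — documents are trimmed to their
  first 1500 tokens; sentences (split on ./!/? + whitespace +
  uppercase, with a clinical-abbreviation exception list) whose mean
  token attribution exceeds 0.01 are retained (positive attributions
  only — the analysis targets positive predictors; both the threshold
  and its raw-attribution scale are parameters).  Retained sentences
  are embedded as TF-IDF term vectors, clustered agglomeratively under
  cosine distance with a 0.7 threshold, merged down to at most
  `n_topics` (default 20) by clustering cluster centroids, and clusters
  smaller than `min_topic_size` (default 5) become outliers.  Topics
  are represented by their top-10 terms under class-based TF-IDF
  (class term frequency × log(1 + A/tf_t), A the average class word
  count).  The backend is pluggable; natural-language topic naming is
  out of scope.

## Desk-scale experiment sizes

The packaged presets pin the problem sizes the tests and the
reproduction script run at: parameter recovery on 20,000 patients at
1.4% prevalence (signal planted within the first 240 tokens; word
models truncated at 256 tokens, the transformer slot at 512); the
truncation experiment on 600 patients with ~660-token documents whose
only signal sits in word positions 525–595, comparing token limits 512
and 2048; null and order-sensitive-bigram corpora of 3–4k patients with
shorter documents.  Neural presets use embedding width 12–16 and hidden
widths 8–16.  These sizes are the package's chosen desk-scale
conditions; the architecture accepts the full-scale settings.

## Known limitations

* The transformer slot is trained from scratch; it exercises the
  interface and the truncation mechanism, not pretrained-encoder
  quality.
* Synthetic filler text is i.i.d.; no syntax, negation or coreference.
  Order-sensitive effects exist only where planted as phrases.
* Performance numbers from the confidential clinical corpus are not
  reproducible here by design; the pipeline's correctness is
  established through planted-signal recovery, oracle agreement and
  calibration instead.
* Undersampling at very low prevalence leaves few training documents;
  run-to-run SD of the neural families is accordingly large at desk
  scale.
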