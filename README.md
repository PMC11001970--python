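# psychonc

Predicting which patients with cancer will see a **psychiatrist** or a
**counsellor** within 12 months, from the text of their initial oncology
consultation document.

Cancer centres employ psychosocial-oncology clinicians, but treating
oncologists detect only a fraction of distressed patients.  A model that
flags likely referrals from a document every patient already has — the
initial oncology consultation — could help close that gap.  `psychonc`
packages the full analysis pipeline for this prognostic task: cohort
construction, a model zoo for imbalanced binary text classification, a
repeated-run statistical comparison protocol, and an attribution-guided
topic-interpretation method.  Because real consultation corpora are
confidential, the package includes a calibrated synthetic-corpus
generator with plantable token→outcome effects, so every stage is
testable end to end.

## What is inside

| Stage | Module | Core idea |
|---|---|---|
| Synthetic corpus | `psychonc.corpus` | Latent psychosocial need *z* ~ N(0, 1) drives signal-token emission; labels are Bernoulli, P(y=1\|e) = σ(b + Σ β_t e_t), with *b* solved so the marginal prevalence is exact (1.4% psychiatry, 21.1% counselling by default) |
| Cohort prep | `psychonc.cohort` | Exclusions (single cancer start, oncology consult within [0, 180] days of diagnosis), index document closest to diagnosis, labels in the (0, 365]-day window, 70/10/20 patient-level split, three tokenization dialects (stemmed bag-of-words, word, subword) |
| Models | `psychonc.models` | Rule-based comparator (trigger-token presence), count-feature L2 logistic regression, and numpy CNN / BiLSTM / single-head transformer with hand-written backprop; loss weighting or 1:1 undersampling; patience-5 early stopping on dev balanced accuracy |
| Evaluation | `psychonc.metrics`, `psychonc.stats`, `psychonc.protocol` | Accuracy, BAC, AUC (Mann–Whitney, midrank ties), F1, sensitivity, specificity; 10 repeated runs with reshuffled training data; dependent t-tests with Bonferroni correction and Cohen's d_z; OLS of performance on token limits |
| Interpretation | `psychonc.interpret`, `psychonc.topics` | \|coefficient\| ranking; integrated gradients over the embedding path (completeness-checked); sentences with mean attribution > 0.01 from the first 1500 tokens, clustered into ≤ 20 topics with class-based TF-IDF term lists |
| Driver | `psychonc.study`, `psychonc.workbench`, CLI `psychonc` | `ReferralStudy(...).fit()` → results object with `summary()`; YAML-configured `run-all` pipeline with manifest and resume |

The model notation follows the field's convention: balanced accuracy
BAC = (sensitivity + specificity)/2 is the tuning and early-stopping
criterion; AUC is the probability a random positive outscores a random
negative.

## Worked example

```python
from psychonc import ReferralStudy
from psychonc.presets import ig_demo_config, toy_spec

config = ig_demo_config(n_patients=4000, seed=7)   # planted-signal corpus
specs = [toy_spec(f, target="psychiatrist", seed=7)
         for f in ("rule", "bow", "cnn")]
study = ReferralStudy.from_config(config, "psychiatrist", specs)
print(study.fit(n_runs=3).summary())
```

prints

```
Referral prediction study — target: psychiatrist
3 repeated runs per family (mean (SD) on the holdout test set)

            accuracy            bac            auc             f1    sensitivity    specificity
model
rule   0.776 (0.000)  0.647 (0.000)  0.647 (0.000)  0.391 (0.000)  0.460 (0.000)  0.835 (0.000)
bow    0.757 (0.000)  0.673 (0.000)  0.764 (0.000)  0.415 (0.000)  0.550 (0.000)  0.796 (0.000)
cnn    0.735 (0.057)  0.748 (0.022)  0.789 (0.000)  0.478 (0.035)  0.767 (0.078)  0.729 (0.079)

Comparisons (dependent t-tests):
       pair metric         t      p  tails  bonferroni_m  adjusted_alpha  significant  cohens_d
 bow vs cnn    bac   -5.8479 0.0280      2             1           0.050         True   -3.3763
 bow vs cnn    auc -117.2167 0.0001      2             1           0.050         True  -67.6751
bow vs rule    bac       inf 0.0000      1             2           0.025         True       inf
cnn vs rule    bac    7.8382 0.0079      1             2           0.025         True    4.5254
bow vs rule    auc       inf 0.0000      1             2           0.025         True       inf
cnn vs rule    auc  669.2705 0.0000      1             2           0.025         True  386.4035
```

Reading the table: the rule baseline (flag documents that already
contain the token "psychiatrist") reaches BAC 0.647 with zero run-to-run
variance; the bag-of-words model beats it one-tailed (infinite t because
its loss-weighted fit is deterministic, so the per-run differences have
zero spread); the CNN beats both, trading specificity for the higher
sensitivity that a screening application wants.  On this corpus the
planted mental-health token is the dominant signal, and
`rank_coefficients` recovers it as the top coefficient of the BoW model.

The same pipeline runs from the shell:

```sh
psychonc simulate --out data/ --seed 1
psychonc prepare  --data data/ --target psychiatrist
psychonc evaluate --data data/ --target psychiatrist --family rule --family bow
psychonc run-all  --out experiment/ --seed 1
```

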