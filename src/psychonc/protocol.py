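"""The repeated-run evaluation protocol.

Each model family is trained ``n_runs`` times (default 10) with the same
hyperparameters but reshuffled training data (run *i* uses seed
``spec.seed + i``), always evaluated on the same holdout test partition;
the mean (SD) of each metric over runs is reported.  Deterministic
families (rule; BoW under loss weighting) produce SD exactly 0.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

from .cohort import LabelledDataset
from .metrics import confusion_metrics
from .models import ModelSpec, make_model
from .stats import ComparisonResult, RunSeries, paired_t

__all__ = ["repeated_runs", "compare_models", "compare_to_rule"]


def _prepared(dataset: LabelledDataset, dialect: str, subword_vocab=None):
    return {part: (dataset.tokens(dialect, part, subword_vocab=subword_vocab),
                   dataset.labels(part))
            for part in ("train", "dev", "test")}


def repeated_runs(spec: ModelSpec, dataset: LabelledDataset,
                  n_runs: int = 10, subword_vocab=None,
                  prepared=None) -> RunSeries:
    """Train/evaluate ``n_runs`` replicates of one spec on a fixed split.

    ``prepared`` optionally carries pre-tokenized
    ``{part: (token_seqs, labels)}`` to avoid re-tokenizing when several
    specs share a dialect.  Any failing run aborts with its run index.
    """
    if not dataset.partition:
        raise ValueError("dataset has no partition; run split first")
    data = prepared or _prepared(dataset, spec.dialect, subword_vocab)
    (tr, ytr), (dv, ydv), (te, yte) = (data[p] for p in ("train", "dev",
                                                         "test"))
    runs = []
    for i in range(n_runs):
        run_spec = replace(spec, seed=spec.seed + i)
        try:
            model = make_model(run_spec).fit(tr, ytr, dv, ydv)
            scores = model.predict_proba(te)
            runs.append(confusion_metrics(yte, scores, run_spec.threshold))
        except Exception as exc:
            raise RuntimeError(
                f"run {i} of family {spec.family!r} failed: {exc}") from exc
    return RunSeries(family=spec.family, target=spec.target, runs=runs)


def compare_models(series: dict[str, RunSeries], metric: str,
                   tails: int = 2) -> list[ComparisonResult]:
    """All pairwise dependent t-tests among trained families on one
    metric, Bonferroni-corrected for the number of pairs."""
    names = sorted(series)
    pairs = list(combinations(names, 2))
    m = max(1, len(pairs))
    return [paired_t(series[a], series[b], metric, tails=tails, m=m)
            for a, b in pairs]


def compare_to_rule(series: dict[str, RunSeries], rule_series: RunSeries,
                    metric: str) -> list[ComparisonResult]:
    """One-tailed tests of each trained family beating the rule-based
    comparator (alternative: model > rule)."""
    names = sorted(series)
    m = max(1, len(names))
    return [paired_t(series[name], rule_series, metric, tails=1, m=m)
            for name in names]
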