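"""Study objects: fit a model zoo to a labelled corpus, summarize runs.

:class:`ReferralStudy` is the modelling front door: build it from a
registry (or straight from a generator config), call :meth:`fit`, and
get a :class:`StudyResults` carrying per-family run series (mean and SD
of accuracy, BAC, AUC, F1, sensitivity, specificity over the repeated
runs), pairwise model comparisons with Bonferroni-adjusted dependent
t-tests and Cohen's d, and one-tailed comparisons against the rule-based
baseline.  ``summary()`` prints the run table in the familiar
"mean (SD)" layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import LabelledDataset, apply_exclusions, assign_labels, split_ids
from .config import GeneratorConfig
from .corpus import generate_registry
from .datatypes import Registry
from .metrics import METRIC_NAMES
from .models import ModelSpec
from .protocol import compare_models, compare_to_rule, repeated_runs
from .stats import ComparisonResult, RunSeries
from .subword import SubwordVocab

__all__ = ["ReferralStudy", "StudyResults"]


@dataclass
class StudyResults:
    """Fitted study: run series per family plus statistical comparisons."""

    target: str
    n_runs: int
    series: dict[str, RunSeries]
    comparisons: list[ComparisonResult] = field(default_factory=list)
    rule_comparisons: list[ComparisonResult] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [self.series[name].summary_row() for name in self.series]
        return pd.DataFrame(rows).set_index("model")

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons + self.rule_comparisons:
            rows.append({
                "pair": " vs ".join(c.pair), "metric": c.metric,
                "t": c.t, "p": c.p, "tails": c.tails,
                "bonferroni_m": c.bonferroni_m,
                "adjusted_alpha": c.adjusted_alpha,
                "significant": c.significant, "cohens_d": c.cohens_d})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Referral prediction study — target: {self.target}",
            f"{self.n_runs} repeated runs per family "
            "(mean (SD) on the holdout test set)", ""]
        lines.append(self.summary_frame().to_string())
        if self.comparisons or self.rule_comparisons:
            lines += ["", "Comparisons (dependent t-tests):"]
            with pd.option_context("display.width", 120):
                lines.append(self.comparisons_frame().round(4).to_string(
                    index=False))
        return "\n".join(lines)


class ReferralStudy:
    """Predicting clinician-contact outcomes from consultation documents.

    Parameters
    ----------
    dataset:
        A labelled, partitioned :class:`LabelledDataset`.
    specs:
        Model specs to evaluate, one per family.
    """

    def __init__(self, dataset: LabelledDataset, specs: list[ModelSpec],
                 subword_vocab: SubwordVocab | None = None):
        if not dataset.partition:
            raise ValueError("dataset needs a train/dev/test partition")
        targets = {s.target for s in specs}
        if targets - {dataset.target}:
            raise ValueError(
                f"specs target {targets} but dataset is {dataset.target!r}")
        self.dataset = dataset
        self.specs = list(specs)
        if subword_vocab is None and any(
                s.dialect == "transformer" for s in specs):
            subword_vocab = SubwordVocab.build(
                tok for seq in dataset.tokens("neural", "train")
                for tok in seq.tokens)
        self.subword_vocab = subword_vocab

    @classmethod
    def from_registry(cls, registry: Registry, target: str,
                      specs: list[ModelSpec],
                      fractions=(0.7, 0.1, 0.2), split_seed: int = 0,
                      window_days: int = 365) -> "ReferralStudy":
        cohort = apply_exclusions(registry)
        dataset = assign_labels(cohort, target, window_days=window_days)
        dataset.partition = split_ids(
            [it.doc_id for it in dataset.items], fractions, rng=split_seed)
        return cls(dataset, specs)

    @classmethod
    def from_config(cls, config: GeneratorConfig, target: str,
                    specs: list[ModelSpec], **kwargs) -> "ReferralStudy":
        return cls.from_registry(generate_registry(config), target, specs,
                                 **kwargs)

    def fit(self, n_runs: int = 10, compare_metrics=("bac", "auc")
            ) -> StudyResults:
        """Run the repeated-run protocol for every spec and compare."""
        series: dict[str, RunSeries] = {}
        prepared_cache: dict[str, dict] = {}
        for spec in self.specs:
            if spec.dialect not in prepared_cache:
                prepared_cache[spec.dialect] = {
                    part: (self.dataset.tokens(
                        spec.dialect, part, subword_vocab=self.subword_vocab),
                        self.dataset.labels(part))
                    for part in ("train", "dev", "test")}
            series[spec.family] = repeated_runs(
                spec, self.dataset, n_runs=n_runs,
                prepared=prepared_cache[spec.dialect])
        trained = {k: v for k, v in series.items() if k != "rule"}
        comparisons, rule_comparisons = [], []
        for metric in compare_metrics:
            if metric not in METRIC_NAMES:
                raise ValueError(f"unknown metric {metric!r}")
            if len(trained) > 1:
                comparisons += compare_models(trained, metric)
            if "rule" in series and trained:
                rule_comparisons += compare_to_rule(
                    trained, series["rule"], metric)
        return StudyResults(target=self.dataset.target, n_runs=n_runs,
                            series=series, comparisons=comparisons,
                            rule_comparisons=rule_comparisons)
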