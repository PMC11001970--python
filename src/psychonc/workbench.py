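"""End-to-end experiment driver: simulate -> prepare -> train -> evaluate
-> compare -> interpret, with a manifest for reproducibility.

A single :class:`ExperimentConfig` pins every interacting constant
(generator conditions, targets, model families, run count, seeds).  The
driver writes all outputs under one directory, records a manifest with
the config hash and per-stage status, never mutates its inputs, and can
resume: stages whose outputs already exist are skipped when
``resume=True``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import apply_exclusions, assign_labels, split_ids
from .config import ConfigError, GeneratorConfig
from .corpus import generate_registry
from .datatypes import Registry
from .interpret import attribution_html, integrated_gradients, salient_sentences
from .models import FAMILIES, make_model
from .presets import toy_spec
from .stats import token_limit_regression
from .study import ReferralStudy
from .topics import topic_summarize

log = logging.getLogger("psychonc")

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, serializable to YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    targets: tuple[str, ...] = ("psychiatrist", "counsellor")
    families: tuple[str, ...] = ("rule", "bow", "cnn")
    n_runs: int = 10
    seed: int = 0
    spec_overrides: dict = field(default_factory=dict)
    token_limit_study: bool = False
    token_limits: tuple[int, ...] = (512, 1024, 2048)
    interpret: bool = True
    interpret_family: str = "cnn"
    n_topics: int = 20
    attribution_threshold: float = 0.01
    trim: int = 1500

    def validate(self) -> "ExperimentConfig":
        self.generator.validate()
        for fam in self.families:
            if fam not in FAMILIES:
                raise ConfigError(f"unimplemented model family {fam!r}")
        for t in self.targets:
            if t not in ("psychiatrist", "counsellor"):
                raise ConfigError(f"unknown target {t!r}")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("targets", "families", "token_limits"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    def digest(self) -> str:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _spec_for(config: ExperimentConfig, family: str, target: str):
    overrides = dict(config.spec_overrides.get(family, {}))
    return toy_spec(family, target=target, seed=config.seed, **overrides)


class _Manifest:
    def __init__(self, outdir: Path, config: ExperimentConfig):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.state = json.loads(self.path.read_text())
        else:
            self.state = {"config_hash": config.digest(), "seed": config.seed,
                          "stages": {}}
        if self.state.get("config_hash") != config.digest():
            self.state = {"config_hash": config.digest(), "seed": config.seed,
                          "stages": {}}

    def done(self, stage: str) -> bool:
        return self.state["stages"].get(stage, {}).get("status") == "done"

    def mark(self, stage: str, status: str, **extra) -> None:
        self.state["stages"][stage] = {
            "status": status, "time": time.time(), **extra}
        self.path.write_text(json.dumps(self.state, indent=2, sort_keys=True))


def run_experiment(config: ExperimentConfig, outdir,
                   resume: bool = False) -> dict:
    """Run the full pipeline; returns a bundle of per-target results.

    Partial failures leave the manifest recording which stages finished,
    so a rerun with ``resume=True`` picks up where it stopped.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    bundle: dict = {"outdir": str(out)}
    t_start = time.time()

    # ---- simulate ---------------------------------------------------------
    stage = "simulate"
    if resume and manifest.done(stage) and (out / "corpus.jsonl").exists():
        log.info("[%s] skipped (resume)", stage)
        registry = Registry.read(out)
    else:
        manifest.mark(stage, "running")
        registry = generate_registry(config.generator)
        registry.write(out)
        manifest.mark(stage, "done", n_patients=len(registry),
                      seed=config.generator.seed,
                      elapsed=round(time.time() - t_start, 2))
        log.info("[%s] %d patients (seed %d, %.1fs)", stage, len(registry),
                 config.generator.seed, time.time() - t_start)

    # ---- prepare ----------------------------------------------------------
    cohort = apply_exclusions(registry)
    datasets = {}
    for target in config.targets:
        ds = assign_labels(cohort, target)
        ds.partition = split_ids([it.doc_id for it in ds.items],
                                 rng=config.seed)
        ds.to_frame().to_csv(out / f"labels_{target}.csv", index=False)
        datasets[target] = ds
    manifest.mark("prepare", "done", n_cohort=len(cohort))
    log.info("[prepare] cohort %d of %d", len(cohort), len(registry))

    # ---- train / evaluate / compare --------------------------------------
    for target in config.targets:
        stage = f"evaluate_{target}"
        t0 = time.time()
        specs = [_spec_for(config, fam, target) for fam in config.families]
        study = ReferralStudy(datasets[target], specs)
        results = study.fit(n_runs=config.n_runs)
        results.summary_frame().to_csv(
            out / f"metrics_{target}.tsv", sep="\t")
        if not results.comparisons_frame().empty:
            results.comparisons_frame().to_csv(
                out / f"comparisons_{target}.csv", index=False)
        bundle[target] = results
        manifest.mark(stage, "done", elapsed=round(time.time() - t0, 2),
                      seed=config.seed)
        log.info("[%s] %d families x %d runs (%.1fs)", stage,
                 len(specs), config.n_runs, time.time() - t0)

    # ---- token-limit study ------------------------------------------------
    if config.token_limit_study:
        target = config.targets[0]
        t0 = time.time()
        points = []
        rows = []
        ds = datasets[target]
        for limit in config.token_limits:
            spec = _spec_for(config, "transformer", target)
            spec = type(spec)(**{**asdict(spec), "max_tokens": limit,
                                 "n_positions": max(limit, spec.n_positions)})
            from .protocol import repeated_runs

            series = repeated_runs(spec, ds, n_runs=max(2, config.n_runs // 2))
            rows.append({"max_tokens": limit,
                         **{m: f"{series.mean(m):.3f} ({series.sd(m):.3f})"
                            for m in ("bac", "auc")}})
            points += [(limit, v) for v in series.values("bac")]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / f"token_limit_{target}.tsv",
                                  sep="\t", index=False)
        slope, p, r2 = token_limit_regression(points)
        (out / f"token_limit_regression_{target}.json").write_text(
            json.dumps({"metric": "bac", "slope": slope, "p": p, "r2": r2}))
        bundle["token_limit"] = {"slope": slope, "p": p, "r2": r2}
        manifest.mark("token_limit_study", "done",
                      elapsed=round(time.time() - t0, 2))

    # ---- interpret --------------------------------------------------------
    if config.interpret and config.interpret_family in config.families:
        for target in config.targets:
            t0 = time.time()
            ds = datasets[target]
            spec = _spec_for(config, config.interpret_family, target)
            model = make_model(spec).fit(
                ds.tokens(spec.dialect, "train"), ds.labels("train"),
                ds.tokens(spec.dialect, "dev"), ds.labels("dev"))
            test_items = ds.subset("test")
            # per-document heat view for the first few test documents
            from .cohort import tokenize as _tok

            for it in test_items[:3]:
                amap = integrated_gradients(
                    model, _tok(it.text, spec.dialect), doc_id=it.doc_id)
                (out / f"attribution_{target}_{it.doc_id}.html").write_text(
                    attribution_html(amap))
            sset = salient_sentences(
                model, [(it.doc_id, it.text) for it in test_items],
                threshold=config.attribution_threshold, trim=config.trim)
            summary = topic_summarize(sset, n_topics=config.n_topics)
            summary.to_frame().to_csv(
                out / f"topics_{target}.tsv", sep="\t", index=False)
            bundle[f"topics_{target}"] = summary
            manifest.mark(f"interpret_{target}", "done",
                          n_sentences=summary.n_sentences,
                          elapsed=round(time.time() - t0, 2))
            log.info("[interpret_%s] %d salient sentences -> %d topics "
                     "(%.1fs)", target, summary.n_sentences,
                     len(summary.topics), time.time() - t0)

    manifest.mark("all", "done", elapsed=round(time.time() - t_start, 2))
    return bundle
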