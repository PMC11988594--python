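"""End-to-end orchestration: generate -> screen -> split/scale -> train ->
evaluate -> explain, as one reproducible, logged run.

A single global seed deterministically derives one seed per stage
(seed, seed+1, ...), so one integer reproduces the whole experiment;
individual stage seeds can be overridden through the stage configs.  All
numeric artifacts are written with 17 significant digits so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cnn import Cnn1DClassifier, count_flops, count_params, save_model
from .cohort import CohortConfig, generate_cohort, write_cohort
from .evaluation import (SplitSpec, apply_scaler, evaluate, fit_scaler,
                         stratified_split)
from .reference import load_reference_table
from .screening import screen_features
from .shapley import Background, ShapleyExplainer, global_importance

log = logging.getLogger("kelptrace")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "kelptrace_run"
    reference_path: str | None = None  # default: packaged table

    # cohort
    n_per_origin: int = 30
    sd_scale: float = 1.0
    clip_at_zero: bool = False

    # screening
    alpha: float = 0.05

    # split
    train_fraction: float = 0.7
    stratified: bool = True

    # network
    conv_filters: tuple[int, ...] = (4, 8)
    kernel_len: int = 3
    pool_len: int = 3
    dense_units: int = 32
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 16

    # explanation
    shap_method: str = "permutation"
    shap_n_permutations: int = 4
    shap_background_mode: str = "sample-average"
    shap_max_test_samples: int | None = None  # None: explain every test row

    # derived stage seeds (overridable); None -> seed, seed+1, ...
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        order = ["cohort", "split", "train", "explain"]
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        return int(self.seed) + order.index(stage)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "conv_filters" in d:
            d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    artifacts: dict
    stage_seconds: dict
    version: str = __version__

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seconds: dict[str, float] = {}
    seeds = {s: config.seed_for(s) for s in
             ("cohort", "split", "train", "explain")}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            seconds[name] = time.perf_counter() - t0
            return result
        return wrap

    # 1. cohort -------------------------------------------------------- #
    def _cohort():
        ref = load_reference_table(config.reference_path)
        cohort = generate_cohort(ref, CohortConfig(
            n_per_origin=config.n_per_origin, seed=seeds["cohort"],
            clip_at_zero=config.clip_at_zero, sd_scale=config.sd_scale))
        write_cohort(cohort, out / "cohort.tsv")
        artifacts["cohort"] = str(out / "cohort.tsv")
        return cohort
    cohort = stage("cohort")(_cohort)

    # 2. screening ----------------------------------------------------- #
    def _screen():
        report, reduced = screen_features(cohort, alpha=config.alpha)
        if not report.selected_ids:
            raise StageError("screen", "0 features selected")
        report.write(out / "screen_report.tsv", out / "screen_summary.json")
        artifacts["screen_report"] = str(out / "screen_report.tsv")
        return reduced
    reduced = stage("screen")(_screen)

    # 3. split + scale ------------------------------------------------- #
    def _split():
        train, test = stratified_split(reduced, SplitSpec(
            train_fraction=config.train_fraction,
            stratified=config.stratified, seed=seeds["split"]))
        with open(out / "split_indices.json", "w", encoding="utf-8") as fh:
            json.dump({"train": train.sample_ids, "test": test.sample_ids},
                      fh, indent=1)
        artifacts["split_indices"] = str(out / "split_indices.json")
        scaler = fit_scaler(train)
        with open(out / "scaler.json", "w", encoding="utf-8") as fh:
            json.dump({"mu": scaler.mu.tolist(),
                       "sigma": scaler.sigma.tolist(),
                       "sd_convention": "population"}, fh, indent=1)
        artifacts["scaler"] = str(out / "scaler.json")
        return train, test, scaler
    train, test, scaler = stage("split")(_split)
    Xtr = apply_scaler(scaler, train)
    Xte = apply_scaler(scaler, test)

    # 4. train --------------------------------------------------------- #
    def _train():
        clf = Cnn1DClassifier(
            conv_filters=config.conv_filters, kernel_len=config.kernel_len,
            pool_len=config.pool_len, dense_units=config.dense_units,
            learning_rate=config.learning_rate, epochs=config.epochs,
            batch_size=config.batch_size, random_state=seeds["train"],
        ).fit(Xtr, train.labels)
        artifacts["model"] = str(save_model(clf, out / "model.npz"))
        clf.history_.to_csv(out / "history.csv", index=False,
                            float_format="%.17g")
        artifacts["history"] = str(out / "history.csv")
        return clf
    clf = stage("train")(_train)

    # 5. evaluate ------------------------------------------------------ #
    def _evaluate():
        report = evaluate(test.labels, clf.predict_proba(Xte))
        payload = report.to_dict()
        payload["n_params"] = count_params(clf)
        payload["flops"] = count_flops(clf)
        with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        artifacts["evaluation"] = str(out / "evaluation.json")
        return report
    stage("evaluate")(_evaluate)

    # 6. explain ------------------------------------------------------- #
    def _explain():
        explainer = ShapleyExplainer(
            clf.predict_proba, Background(
                Xtr, summary_mode=config.shap_background_mode),
            method=config.shap_method,
            n_permutations=config.shap_n_permutations,
            random_state=seeds["explain"])
        k = config.shap_max_test_samples
        rows = np.arange(Xte.shape[0]) if k is None else np.arange(min(k, Xte.shape[0]))
        expl = explainer.explain(Xte[rows], feature_ids=test.feature_ids)
        expl.write(out / "explanation.tsv", out / "explanation.json",
                   sample_ids=[test.sample_ids[i] for i in rows])
        ranked = global_importance(expl)
        ranked.to_csv(out / "importance.csv", index=False,
                      float_format="%.17g")
        artifacts["explanation"] = str(out / "explanation.tsv")
        artifacts["importance"] = str(out / "importance.csv")
        log.info("top stacked features: %s",
                 ", ".join(ranked["feature_id"].head(5)))
        return expl
    stage("explain")(_explain)

    manifest = RunManifest(
        config=asdict(config), stage_seeds=seeds, artifacts=artifacts,
        stage_seconds=seconds)
    manifest.write(out / "manifest.json")
    return manifest
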