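"""End-to-end screening workflow: generate/load -> featurize -> rank ->
split -> train -> evaluate -> GA screen -> report.

One :class:`WorkflowConfig` drives every stage. A single global seed is
fanned out through a seed-sequence scheme so that rerunning an identical
config reproduces byte-identical artifacts, and each artifact is stamped
with the config hash and the seed that produced it. A failing stage aborts
with its name; artifacts already written by earlier stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .descriptors import DEFAULT_FEATURES, CoformerFeaturizer
from .ga import ConstraintSet, GAConfig, run_ga
from .library import CoformerLibrary, read_library, split_library, write_library
from .models import (
    BPClassifier,
    RFConfig,
    evaluate,
    rank_features_rf,
    save_model,
    select_top_features,
)
from .synthetic import GeneratorConfig, generate_candidate_pool, generate_library

__all__ = ["WorkflowConfig", "WorkflowStageError", "run_workflow"]


class WorkflowStageError(RuntimeError):
    """A stage failed; carries the stage name, upstream artifacts are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class WorkflowConfig:
    """Configuration for one full screening run.

    Either ``library_path`` (a labeled CSV) or the synthetic ``generator``
    supplies the training library; likewise ``pool_path`` or a generated
    pool of ``pool_size`` candidates supplies the GA search space. The
    global ``seed`` is fanned out to the generator, split, forest, network
    and GA unless those configs are given explicitly.
    """

    outdir: str = "scout_out"
    seed: int = 0
    library_path: str | None = None
    generator: GeneratorConfig | None = None
    features: tuple = DEFAULT_FEATURES
    k: int = 32
    n_select: int = 5
    train_size: int = 120
    stratified: bool = True
    rf: RFConfig | None = None
    bp_params: dict = field(default_factory=dict)
    ga: GAConfig | None = None
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    pool_path: str | None = None
    pool_size: int = 1000

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            gd = dict(d["generator"])
            from .synthetic import PlantedRule

            if "rule" in gd and isinstance(gd["rule"], dict):
                rd = dict(gd["rule"])
                for key in ("hbd_range", "tpsa_range"):
                    if key in rd:
                        rd[key] = tuple(rd[key])
                gd["rule"] = PlantedRule(**rd)
            for key in ("mw_range", "hbd_range", "tpsa_range", "tyr_range"):
                if key in gd:
                    gd[key] = tuple(gd[key])
            d["generator"] = GeneratorConfig(**gd)
        if "rf" in d and isinstance(d["rf"], dict):
            d["rf"] = RFConfig(**d["rf"])
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        if "constraints" in d and isinstance(d["constraints"], dict):
            cd = dict(d["constraints"])
            if "bounds" in cd:
                cd["bounds"] = {k: tuple(v) for k, v in cd["bounds"].items()}
            d["constraints"] = ConstraintSet(**cd)
        if "features" in d:
            d["features"] = tuple(d["features"])
        return cls(**d)


def _config_hash(cfg: WorkflowConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir", None)  # where artifacts land is not part of the run identity
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("generator", "pool", "split", "rf", "bp", "ga")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _write_json(path: Path, payload: dict) -> Path:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    return path


def run_workflow(cfg: WorkflowConfig) -> dict:
    """Execute the full screen; returns a report dict with artifact paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": _config_hash(cfg), "seed": cfg.seed, "version": __version__}
    seeds = _stage_seeds(cfg.seed)
    report: dict = {"stamp": stamp, "artifacts": {}, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise WorkflowStageError(name, exc) from exc

        return deco

    # -- input library -----------------------------------------------------
    @stage("library")
    def lib() -> CoformerLibrary:
        if cfg.library_path:
            return read_library(cfg.library_path)
        gen = cfg.generator or GeneratorConfig(seed=seeds["generator"])
        library = generate_library(gen)
        write_library(library, outdir / "library.csv")
        report["artifacts"]["library"] = str(outdir / "library.csv")
        return library

    # -- featurize (full spec) and rank -----------------------------------
    @stage("featurize")
    def full_features():
        featurizer = CoformerFeaturizer(features=cfg.features, k=cfg.k, seed=cfg.seed)
        fm = featurizer.fit_transform(lib)
        import pandas as pd

        df = pd.DataFrame(fm.X, columns=list(fm.columns))
        df.insert(0, "id", list(fm.ids))
        df.to_csv(outdir / "features.csv", index=False)
        report["artifacts"]["features"] = str(outdir / "features.csv")
        return fm

    @stage("rank_features")
    def ranking():
        rf_cfg = cfg.rf or RFConfig(seed=seeds["rf"])
        imp = rank_features_rf(full_features, lib.labels, rf_cfg)
        selected = select_top_features(imp, min(cfg.n_select, len(imp.ranking)))
        _write_json(
            outdir / "importance.json",
            {"stamp": stamp, "importance": imp.as_dict(), "selected": list(selected)},
        )
        report["artifacts"]["importance"] = str(outdir / "importance.json")
        report["stages"]["selected_features"] = list(selected)
        return selected

    # -- split -------------------------------------------------------------
    @stage("split")
    def split():
        sp = split_library(
            lib, min(cfg.train_size, len(lib)), seed=seeds["split"], stratified=cfg.stratified
        )
        _write_json(
            outdir / "split.json",
            {
                "stamp": stamp,
                "train_ids": list(sp.train_ids),
                "test_ids": list(sp.test_ids),
                "n_train": len(sp.train_ids),
                "n_test": len(sp.test_ids),
                "stratified": sp.stratified,
                "split_seed": sp.seed,
            },
        )
        report["artifacts"]["split"] = str(outdir / "split.json")
        report["stages"]["n_train"] = len(sp.train_ids)
        report["stages"]["n_test"] = len(sp.test_ids)
        return sp

    # -- train -------------------------------------------------------------
    @stage("train")
    def trained():
        order = [f for f in cfg.features if f in ranking]
        featurizer = CoformerFeaturizer(features=order, k=cfg.k, seed=cfg.seed)
        train_lib = lib.subset(split.train_ids)
        fm_train = featurizer.fit_transform(train_lib)
        bp_params = {"random_state": seeds["bp"], **cfg.bp_params}
        model = BPClassifier(**bp_params)
        model.fit(fm_train, train_lib.labels)
        save_model(outdir / "model.json", model, featurizer)
        report["artifacts"]["model"] = str(outdir / "model.json")
        return model, featurizer

    model, featurizer = trained

    # -- evaluate ----------------------------------------------------------
    @stage("evaluate")
    def confusion():
        test_lib = lib.subset(split.test_ids)
        cm = evaluate(model, featurizer.transform(test_lib), test_lib.labels)
        _write_json(outdir / "confusion.json", {"stamp": stamp, **cm.as_dict()})
        report["artifacts"]["confusion"] = str(outdir / "confusion.json")
        report["stages"]["confusion"] = cm.as_dict()
        return cm

    # -- GA screen ---------------------------------------------------------
    @stage("ga_screen")
    def ga_report():
        if cfg.pool_path:
            pool = read_library(cfg.pool_path)
        else:
            gen = cfg.generator or GeneratorConfig()
            from dataclasses import replace

            pool = generate_candidate_pool(replace(gen, seed=seeds["pool"]), cfg.pool_size)
            write_library(pool, outdir / "pool.csv")
            report["artifacts"]["pool"] = str(outdir / "pool.csv")
        ga_cfg = cfg.ga or GAConfig(seed=seeds["ga"])
        result = run_ga(model, featurizer, cfg.constraints, ga_cfg, pool=pool)
        payload = {
            "stamp": stamp,
            "best_candidate_id": result.best_record.id,
            "best_candidate_smiles": result.best_record.smiles,
            "best_fitness": result.best_fitness,
            "best_feasible": result.best_feasible,
            "convergence_generation": result.trace.convergence_generation,
            "ga_seed": result.seed,
            "trace_best": result.trace.best,
            "trace_mean": result.trace.mean,
        }
        _write_json(outdir / "ga_report.json", payload)
        report["artifacts"]["ga_report"] = str(outdir / "ga_report.json")
        report["stages"]["ga"] = {
            k: payload[k]
            for k in ("best_candidate_id", "best_fitness", "convergence_generation")
        }
        return payload

    # -- summary -----------------------------------------------------------
    cm = confusion
    lines = [
        f"coformer-scout workflow (seed {cfg.seed}, config {stamp['config_hash']})",
        f"library: {len(lib)} records "
        f"({report['stages']['n_train']} train / {report['stages']['n_test']} test)",
        f"selected features: {', '.join(report['stages']['selected_features'])}",
        f"test accuracy: {cm.accuracy} %  "
        f"(sensitivity {cm.sensitivity} %, specificity {cm.specificity} %)",
        f"confusion: tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn}",
        f"GA best candidate: {ga_report['best_candidate_id']} "
        f"(fitness {ga_report['best_fitness']:.4f}, "
        f"converged at generation {ga_report['convergence_generation']})",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    report["artifacts"]["summary"] = str(outdir / "summary.txt")
    return report
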