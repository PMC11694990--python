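"""End-to-end orchestration: simulate -> preprocess -> quantize -> features
-> balance -> classify -> report.

A run is driven by a single :class:`RunConfig` (nestable from a YAML mapping)
and a single seed that fans out to per-stage random streams.  Every run
directory receives the feature table, the augmented table, the metrics table,
ROC points, a log, and a manifest listing each artifact with a checksum plus
the configuration hash and seed, so identical configurations reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .balancing import AugmentationPlan, augment_table
from .compression import COMPRESSOR_NAME, FCMConfig
from .features import FEATURE_SET_DEFS, cohort_feature_table
from .modeling import ClassifierSpec, run_tests
from .preprocessing import TrendConfig
from .quantization import DEFAULT_ALPHABET
from .synthetic import ACIDEMIC, CohortConfig, generate_cohort, write_cohort

log = logging.getLogger("ctgcompress")

CLASSIFIER_ALIASES = {"svm": "svm_rbf", "rf": "random_forest",
                      "gbt": "gradient_boosted_trees"}


class PipelineError(RuntimeError):
    """A stage failed; the run manifest records which one and why."""


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    fcm: FCMConfig = field(default_factory=FCMConfig)
    alphabet_size: int = DEFAULT_ALPHABET
    augmentation: AugmentationPlan = field(default_factory=AugmentationPlan)
    classifiers: tuple = ("svm",)
    tests: tuple = tuple("ABCDEFGHI")
    cv: str = "custom"
    n_splits: int = 20
    collinearity_threshold: float = 0.5
    write_signals: bool = False
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key, klass in (("cohort", CohortConfig), ("trend", TrendConfig),
                           ("fcm", FCMConfig), ("augmentation", AugmentationPlan)):
            if key in kwargs and isinstance(kwargs[key], dict):
                try:
                    kwargs[key] = klass(**kwargs[key])
                except TypeError as exc:
                    raise ValueError(f"invalid config under {key!r}: {exc}") from exc
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict:
    """Fan one global seed out to independent per-stage integer seeds."""
    names = ("cohort", "augment", "cv")
    states = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31 - 1)
    return dict(zip(names, states.tolist()))


def pooled_custom_cv_auc(effect_size: float, seed: int, test_id: str = "I",
                         classifier: str = "svm_rbf") -> float:
    """Run the whole analysis on one synthetic cohort and return the pooled
    replica-aware cross-validation AUC for one feature-set test.

    Generates the default study-condition cohort (54 non-acidemic / 7
    acidemic, 4 Hz, ~2 h) at the given ``effect_size``, extracts only the
    index families the chosen feature-set test uses, balances with SMOTE and
    evaluates the default SVM under the custom folds.
    """
    seeds = _stage_seeds(seed)
    cohort_cfg = CohortConfig(effect_size=effect_size, seed=seeds["cohort"])
    subjects = generate_cohort(cohort_cfg)
    families = FEATURE_SET_DEFS[test_id][0]
    table = cohort_feature_table(subjects, families=families)
    table = table.drop(columns=[c for c in table.columns
                                if table[c].isna().any()])
    plan = AugmentationPlan(seed=seeds["augment"])
    augmented = augment_table(table, ACIDEMIC, plan)
    spec = ClassifierSpec(kind=classifier, seed=seeds["cv"])
    results, _ = run_tests(augmented, test_ids=[test_id], specs=[spec],
                           seed=seeds["cv"], cv="custom")
    return float(results.loc[classifier, (test_id, "auc")])


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure the manifest is still written, flagging the failed
    stage and the partial outputs, and a :class:`PipelineError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seeds = _stage_seeds(config.seed)
    manifest = {
        "config": config.to_dict(), "config_hash": config.config_hash(),
        "seed": config.seed, "compressor": COMPRESSOR_NAME,
        "status": "running", "stages": {}, "files": {},
    }

    def record(name: str, path: Path):
        manifest["files"][str(path.relative_to(out))] = hashlib.sha256(
            path.read_bytes()).hexdigest()

    def finish(status, failed_stage=None, error=None):
        manifest["status"] = status
        if failed_stage:
            manifest["failed_stage"] = failed_stage
            manifest["error"] = str(error)
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        log.removeHandler(handler)
        handler.close()

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
        subjects = generate_cohort(cohort_cfg)
        log.info("simulated %d subjects (%d acidemic)", len(subjects),
                 sum(s.group == ACIDEMIC for s in subjects))
        if config.write_signals:
            write_cohort(subjects, out / "cohort", seed=seeds["cohort"])
            record("simulate", out / "cohort" / "manifest.csv")
        manifest["stages"]["simulate"] = {"n_subjects": len(subjects)}

        stage = "features"
        table = cohort_feature_table(
            subjects, trend_cfg=config.trend, fcm_cfg=config.fcm,
            alphabet_size=config.alphabet_size)
        # keep only columns every subject has: duration jitter can leave a
        # segment column undefined for the shortest recordings (the same
        # rationale as dropping the first 30 minutes)
        incomplete = [c for c in table.columns if table[c].isna().any()]
        if incomplete:
            log.info("dropping %d incomplete feature columns", len(incomplete))
            table = table.drop(columns=incomplete)
        fpath = out / "features.csv"
        table.to_csv(fpath)
        record(stage, fpath)
        (out / "features_meta.json").write_text(json.dumps({
            "config_hash": manifest["config_hash"], "seed": config.seed,
            "n_rows": len(table), "n_columns": table.shape[1],
        }, indent=2))
        record(stage, out / "features_meta.json")
        manifest["stages"]["features"] = {"shape": list(table.shape)}

        stage = "balance"
        plan = dataclasses.replace(config.augmentation, seed=seeds["augment"])
        augmented = augment_table(table, ACIDEMIC, plan)
        apath = out / "features_augmented.csv"
        augmented.to_csv(apath)
        record(stage, apath)
        manifest["stages"]["balance"] = {
            "n_minority": int((augmented["group"] == ACIDEMIC).sum()),
            "n_total": len(augmented),
        }

        stage = "classify"
        specs = [ClassifierSpec(kind=CLASSIFIER_ALIASES.get(k, k),
                                seed=seeds["cv"])
                 for k in config.classifiers]
        results, rocs = run_tests(
            augmented, test_ids=config.tests, specs=specs, seed=seeds["cv"],
            cv=config.cv, n_splits=config.n_splits,
            collinearity_threshold=config.collinearity_threshold)
        rpath = out / "metrics.csv"
        results.to_csv(rpath)
        record(stage, rpath)
        (out / "metrics.json").write_text(json.dumps(
            {f"{clf}/{tid}": results.loc[clf, tid].to_dict()
             for clf, tid in
             ((c, t) for c in results.index
              for t in results.columns.get_level_values(0).unique())},
            indent=2))
        record(stage, out / "metrics.json")
        roc_dir = out / "roc"
        roc_dir.mkdir(exist_ok=True)
        for (kind, tid), roc in rocs.items():
            p = roc_dir / f"roc_{kind}_{tid}.csv"
            roc.to_csv(p, index=False)
            record(stage, p)
        manifest["stages"]["classify"] = {"tests": list(config.tests)}
    except Exception as exc:
        finish("failed", failed_stage=stage, error=exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finish("complete")
    return out
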