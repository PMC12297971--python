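"""Orchestration: configuration, fixture loading, screening and full reports.

The full analysis mirrors the study workflow: extract the 12 ROI colour
components per subject and class, standardize, screen every single
component with the bagged-tree classifier under stratified CV, evaluate the
configured component combinations (the two-component h + a* model and the
three-component h + a* + H model by default), and run the statistical
evaluation (Shapiro-Wilk, paired t, Cohen's d, Pearson matrix, PCA,
permutation importance). CSV/JSON reports are the canonical outputs; every
seed and option is recorded in the run log.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import BaggingConfig, auc_band, cross_validate, roc_auc
from .colour import derive_viewing_conditions
from .features import FeatureTable, ProtocolTiming, build_feature_table, standardize
from .imaging import COMPONENT_NAMES, Landmarks, ROIBox, read_frames
from .model import PressureResponseModel
from .synthetic import FeatureSimParams, simulate_feature_dataset

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "load_fixture_table",
    "run_component_screen",
    "run_full_analysis",
    "validate_report",
    "REPORT_SCHEMA",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Input data missing or malformed (CLI exit code 3)."""


#: Required keys of the JSON report written by :func:`run_full_analysis`.
REPORT_SCHEMA = {
    "required": ["config", "screen", "models", "stats", "pca", "seeds"],
    "model_required": ["components", "auc", "band", "per_fold_auc", "confusion", "metrics"],
}


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    mode : ``simulate`` (feature-level generator), ``fixtures`` (a directory
        written by :func:`perfcolour.synthetic.write_fixture_set`) or
        ``external`` (the same layout from real recordings).
    feature_sets : component combinations to evaluate in addition to the
        per-component screen; defaults to the two- and three-component hue
        models.
    vc_mode : CIECAM02 dialect used during extraction. The literal dialect
        is the default because its hue axis matches the sign structure the
        pressure-response features are defined by.
    """

    mode: str = "simulate"
    input_dir: str | None = None
    out_dir: str = "perfcolour_out"
    seed: int = 0
    vc_mode: str = "literal"
    vc_LA: float = 4.07
    vc_Yb: float = 20.0
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    sim: FeatureSimParams = field(default_factory=FeatureSimParams)
    feature_sets: tuple = (("h", "astar"), ("h", "astar", "H"))
    importance_repeats: int = 30

    def __post_init__(self):
        if self.mode not in ("simulate", "fixtures", "external"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode in ("fixtures", "external"):
            if not self.input_dir:
                raise ConfigError(f"mode {self.mode!r} requires input_dir")
            if not os.path.isdir(self.input_dir):
                raise ConfigError(f"input_dir {self.input_dir!r} does not exist")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path!r}: {exc}") from exc
        kwargs = dict(raw)
        if "timing" in kwargs:
            kwargs["timing"] = ProtocolTiming(**kwargs["timing"])
        if "bagging" in kwargs:
            kwargs["bagging"] = BaggingConfig(**kwargs["bagging"])
        if "sim" in kwargs:
            kwargs["sim"] = FeatureSimParams(**kwargs["sim"])
        if "feature_sets" in kwargs:
            kwargs["feature_sets"] = tuple(tuple(fs) for fs in kwargs["feature_sets"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def viewing_conditions(self):
        return derive_viewing_conditions(LA=self.vc_LA, Yb=self.vc_Yb, mode=self.vc_mode)


def load_fixture_table(input_dir: str, config: RunConfig) -> FeatureTable:
    """Read a fixture manifest and extract the feature table from its TIFFs."""
    manifest_path = os.path.join(input_dir, "manifest.json")
    if not os.path.isfile(manifest_path):
        raise DataError(f"no manifest.json in {input_dir!r}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    roi = ROIBox(**manifest["roi"])
    lm = Landmarks(tuple(manifest["landmarks"]["wrist"]), tuple(manifest["landmarks"]["elbow"]))
    # the manifest's recorded protocol overrides the config default so that
    # frame selection matches what was actually generated/acquired
    mt = manifest.get("timing", {})
    timing = replace(
        config.timing,
        fps=manifest.get("fps", config.timing.fps),
        baseline_s=mt.get("baseline_s", config.timing.baseline_s),
        compression_s=mt.get("compression_s", config.timing.compression_s),
        post_s=mt.get("post_s", config.timing.post_s),
    )
    sequences = {}
    for sid, info in sorted(manifest["subjects"].items()):
        sdir = os.path.join(input_dir, info["dir"])
        try:
            sequences[sid] = read_frames(sdir, fps=timing.fps)
        except (IOError, ValueError) as exc:
            raise DataError(f"subject {sid}: {exc}") from exc
    try:
        return build_feature_table(sequences, roi, config.viewing_conditions(), timing, lm)
    except RuntimeError as exc:
        raise DataError(str(exc)) from exc


def _get_table(config: RunConfig) -> FeatureTable:
    if config.mode == "simulate":
        sim = replace(config.sim, seed=config.sim.seed + config.seed)
        return simulate_feature_dataset(sim)
    return load_fixture_table(config.input_dir, config)


def run_component_screen(
    table: FeatureTable, config: BaggingConfig = BaggingConfig(), components=None
) -> pd.DataFrame:
    """Evaluate every single component alone; CSV-ready table sorted by AUC.

    Ties in AUC are broken by component name so the ordering is
    deterministic for a given seed.
    """
    table = table if table.standardized else standardize(table)
    comps = list(components) if components is not None else table.components
    groups = table.data["subject_id"].to_numpy()
    rows = []
    for c in comps:
        cv = cross_validate(table.X([c]), table.y, config, groups=groups)
        auc = roc_auc(cv.scores, table.y).auc
        rows.append({"component": c, "auc": auc, "band": auc_band(auc)})
    df = pd.DataFrame(rows).sort_values(
        ["auc", "component"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Writes to ``config.out_dir``: the (raw and standardized) feature tables,
    the per-component screen, one ROC point file per evaluated model, the
    Pearson/PCA/importance CSVs and a single ``report.json`` tying
    everything together. Returns the report dict. Identical config and
    seeds reproduce identical reports.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "extract"
    try:
        table = _get_table(config)
        table.to_csv(os.path.join(config.out_dir, "feature_table.csv"))
        ztable = standardize(table)
        ztable.to_csv(
            os.path.join(config.out_dir, "feature_table_standardized.csv"),
            sidecar=os.path.join(config.out_dir, "standardization.json"),
        )
        stage = "screen"
        bag = replace(config.bagging, seed=config.bagging.seed + config.seed)
        screen = run_component_screen(ztable, bag)
        screen.to_csv(os.path.join(config.out_dir, "component_screen.csv"), index=False)
        stage = "models"
        models = []
        sets = [(c,) for c in ztable.components] + [tuple(fs) for fs in config.feature_sets]
        stats_out = None
        for comps in sets:
            comps = [c for c in comps if c in ztable.components]
            if not comps:
                continue
            m = PressureResponseModel(ztable, components=comps, config=bag)
            res = m.fit(
                with_importance=len(comps) > 1, importance_repeats=config.importance_repeats
            )
            name = "+".join(comps)
            pd.DataFrame(
                {"fpr": res.roc.fpr, "tpr": res.roc.tpr, "threshold": res.roc.thresholds}
            ).to_csv(os.path.join(config.out_dir, f"roc_{name}.csv"), index=False)
            entry = {
                "components": list(comps),
                "auc": res.auc,
                "band": res.auc_band,
                "per_fold_auc": [float(a) for a in res.per_fold_auc],
                "confusion": {
                    "TP": res.metrics.TP, "FP": res.metrics.FP,
                    "FN": res.metrics.FN, "TN": res.metrics.TN,
                },
                "metrics": {
                    "precision": res.metrics.precision,
                    "recall": res.metrics.recall,
                    "f1": res.metrics.f1,
                },
            }
            if res.importance is not None:
                entry["permutation_importance"] = {
                    k: {"mean": float(v["importance_mean"]), "sd": float(v["importance_sd"])}
                    for k, v in res.importance.iterrows()
                }
                res.importance.to_csv(os.path.join(config.out_dir, f"importance_{name}.csv"))
            models.append(entry)
            if set(comps) == set(ztable.components) or (
                stats_out is None and len(comps) == len(ztable.components)
            ):
                stats_out = res
        stage = "stats"
        if stats_out is None:
            full = PressureResponseModel(ztable, config=bag)
            stats_out = full.fit(
                with_importance=len(ztable.components) > 1,
                importance_repeats=config.importance_repeats,
            )
        sf = stats_out.stats_frame()
        sf.to_csv(os.path.join(config.out_dir, "class_stats.csv"))
        if stats_out.pearson is not None:
            stats_out.pearson.to_csv(os.path.join(config.out_dir, "pearson.csv"))
        pca = pd.DataFrame(
            {
                "eigenvalue": stats_out.pca_eigenvalues,
                "explained_ratio": stats_out.pca_ratios,
            }
        )
        pca.to_csv(os.path.join(config.out_dir, "pca.csv"), index=False)
        report = {
            "config": {
                "mode": config.mode,
                "seed": config.seed,
                "vc_mode": config.vc_mode,
                "bagging": asdict(bag),
                "feature_sets": [list(fs) for fs in config.feature_sets],
            },
            "screen": screen.to_dict(orient="records"),
            "models": models,
            "stats": {c: row.to_dict() for c, row in sf.iterrows()},
            "pca": {
                "eigenvalues": [float(v) for v in stats_out.pca_eigenvalues],
                "explained_ratio": [float(v) for v in stats_out.pca_ratios],
                "top_two_cumulative": float(np.sum(stats_out.pca_ratios[:2])),
            },
            "seeds": {"run": config.seed, "bagging": bag.seed, "sim": config.sim.seed},
        }
        validate_report(report)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc


def validate_report(report: dict) -> None:
    """Check the report dict against :data:`REPORT_SCHEMA`; raises on failure."""
    missing = [k for k in REPORT_SCHEMA["required"] if k not in report]
    if missing:
        raise DataError(f"report is missing keys {missing}")
    for m in report["models"]:
        bad = [k for k in REPORT_SCHEMA["model_required"] if k not in m]
        if bad:
            raise DataError(f"model entry {m.get('components')} missing keys {bad}")
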