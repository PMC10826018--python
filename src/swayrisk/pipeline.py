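"""End-to-end orchestration: generate -> filter -> extract -> select ->
classify -> explain, from a single config with a master seed.

Every artifact is a plain CSV/JSON file, and a provenance manifest
records the config hash, package versions, and all derived seeds so a
run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, SplitSpec, fit_classifier, fit_minmax, run_grid, split_dataset
from .cohort import CohortSpec, generate_cohort, read_participants_csv, read_trials_csv, write_cohort_csv
from .explain import explain_model, summarize
from .features import FeatureConfig, PERSONAL_COLUMNS, build_feature_table, posturographic_columns
from .signal import FilterConfig

log = logging.getLogger("swayrisk")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    criteria: tuple[str, ...] = ("criteria_I", "criteria_II")
    selections: tuple[str, ...] = ("none", "SMA", "HHO", "ABC")
    classifiers: tuple[str, ...] = (
        "balanced_bagging",
        "complement_nb",
        "easy_ensemble",
    )
    population: int = 100
    epochs: int = 100
    filter_k: int = 30
    shap_top_k: int = 15
    shap_permutations: int = 20
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        kwargs: dict[str, Any] = {"seed": seed}
        if "cohort" in raw:
            c = dict(raw.pop("cohort"))
            c.setdefault("seed", seed)
            if "condition_gain" in c:
                c["condition_gain"] = dict(c["condition_gain"])
            kwargs["cohort"] = CohortSpec(**c)
        else:
            kwargs["cohort"] = CohortSpec(seed=seed)
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw.pop("filter"))
        if "features" in raw:
            f = dict(raw.pop("features"))
            if "band" in f:
                f["band"] = tuple(f["band"])
            kwargs["features"] = FeatureConfig(**f)
        if "split" in raw:
            s = dict(raw.pop("split"))
            s.setdefault("seed", seed)
            if "fractions" in s:
                s["fractions"] = tuple(s["fractions"])
            kwargs["split"] = SplitSpec(**s)
        else:
            kwargs["split"] = SplitSpec(seed=seed)
        for key in (
            "criteria",
            "selections",
            "classifiers",
            "population",
            "epochs",
            "filter_k",
            "shap_top_k",
            "shap_permutations",
        ):
            if key in raw:
                val = raw.pop(key)
                kwargs[key] = tuple(val) if isinstance(val, (list, tuple)) else val
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Read a YAML or JSON run config; ``seed`` overrides the file's seed."""
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text)
    if seed is not None:
        raw["seed"] = seed
        cohort = dict(raw.get("cohort", {}))
        cohort["seed"] = seed
        raw["cohort"] = cohort
        split = dict(raw.get("split", {}))
        split["seed"] = seed
        raw["split"] = split
    return RunConfig.from_dict(raw)


def _write_manifest(out_dir: Path, config: RunConfig, stage: str, timings: dict) -> None:
    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "swayrisk_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stage_seconds": timings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def cmd_generate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the synthetic cohort and write participant/trajectory CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    participants, trials = generate_cohort(config.cohort)
    paths = {
        "participants": out_dir / "participants.csv",
        "trajectories": out_dir / "trajectories.csv",
    }
    write_cohort_csv(participants, trials, paths["participants"], paths["trajectories"])
    _write_manifest(out_dir, config, "generate", {"generate": time.perf_counter() - t0})
    log.info("wrote %d participants, %d trials", len(participants), len(trials))
    return paths


def cmd_features(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Build the feature table from the generated CSVs (generating if absent)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ppath = out_dir / "participants.csv"
    tpath = out_dir / "trajectories.csv"
    t0 = time.perf_counter()
    if ppath.exists() and tpath.exists():
        participants = read_participants_csv(ppath)
        trials = read_trials_csv(tpath)
    else:
        participants, trials = generate_cohort(config.cohort)
    table, exclusions = build_feature_table(participants, trials, config.features)
    fpath = out_dir / "features.csv"
    table.to_csv(fpath)
    sidecar = {
        "filter": dataclasses.asdict(config.filter),
        "features": dataclasses.asdict(config.features),
        "excluded": exclusions.excluded,
        "n_rows": len(table),
        "n_posturographic_columns": len(posturographic_columns()),
    }
    (out_dir / "features_meta.json").write_text(json.dumps(sidecar, indent=2))
    _write_manifest(out_dir, config, "features", {"features": time.perf_counter() - t0})
    return {"features": fpath, "meta": out_dir / "features_meta.json"}


def cmd_run(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Full pipeline: features -> selection x classification grid -> SHAP."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    fpath = out_dir / "features.csv"
    if fpath.exists():
        table = pd.read_csv(fpath, index_col="participant_id")
    else:
        participants, trials = generate_cohort(config.cohort)
        table, _ = build_feature_table(participants, trials, config.features)
        table.to_csv(fpath)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = run_grid(
        table,
        criteria=config.criteria,
        selections=config.selections,
        classifiers=config.classifiers,
        split=config.split,
        population=config.population,
        epochs=config.epochs,
        filter_k=config.filter_k,
        seed=config.seed,
    )
    report_path = out_dir / "metrics.csv"
    report.to_csv(report_path, index=False)
    timings["grid"] = time.perf_counter() - t0

    # explain the best (selection, classifier) pair per criterion by test AUC
    t0 = time.perf_counter()
    shap_tables = {}
    posturo = [c for c in posturographic_columns() if c in table.columns]
    personal = [c for c in PERSONAL_COLUMNS if c in table.columns]
    for criterion in config.criteria:
        sub = report[report["criterion"] == criterion]
        best = sub.loc[sub["auc"].idxmax()]
        y = table[criterion].to_numpy(int)
        train_idx, _, test_idx = split_dataset(
            y, SplitSpec(config.split.fractions, seed=config.seed)
        )
        cols = posturo + personal
        scaler = fit_minmax(table.iloc[train_idx][cols])
        X_train = scaler.transform(table.iloc[train_idx][cols])
        X_test = scaler.transform(table.iloc[test_idx][cols])
        model = fit_classifier(
            ClassifierSpec(name=best["classifier"], seed=config.seed),
            X_train,
            y[train_idx],
        )
        n_explain = min(len(X_test), 20)
        summary = explain_model(
            model,
            X_train,
            X_test[:n_explain],
            feature_names=cols,
            max_background=50,
            n_permutations=config.shap_permutations,
            seed=config.seed,
        )
        ranked = summarize(summary, top_k=config.shap_top_k)
        ranked.insert(0, "criterion", criterion)
        ranked.insert(1, "model", best["classifier"])
        shap_tables[criterion] = ranked
    shap_path = out_dir / "shap_summary.csv"
    pd.concat(shap_tables.values(), ignore_index=True).to_csv(shap_path, index=False)
    timings["shap"] = time.perf_counter() - t0

    _write_manifest(out_dir, config, "run", timings)
    return {
        "features": fpath,
        "metrics": report_path,
        "shap": shap_path,
        "manifest": out_dir / "manifest.json",
    }


def cmd_report(run_dir: str | Path) -> str:
    """Render the metrics CSV of a completed run as per-criterion tables."""
    run_dir = Path(run_dir)
    mpath = run_dir / "metrics.csv"
    if not mpath.exists():
        raise FileNotFoundError(f"no metrics report at {mpath}")
    report = pd.read_csv(mpath)
    blocks = []
    for criterion, sub in report.groupby("criterion"):
        cols = ["selection", "classifier", "accuracy", "recall", "specificity", "auc"]
        block = sub[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}")
        blocks.append(f"== {criterion} ==\n{block}")
    return "\n\n".join(blocks)
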