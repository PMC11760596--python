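"""Stage orchestration: versioned CSV/JSON artifacts and a manifest.

Stages mirror the analysis workflow: ``simulate`` -> ``preprocess`` ->
``screen`` -> ``associate`` -> ``select`` -> ``build`` -> ``evaluate``;
``all`` chains them.  Each stage reads its upstream artifacts from the
output directory and writes its own, so a pipeline can be resumed or
re-run stage by stage.  Every run updates ``manifest.json`` with the
config hash, seed, library versions and per-stage row/feature counts;
no timestamps are written, so identical (config, seed) runs produce
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import lmm, preprocess, selection
from .simulate import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

STAGES = ("simulate", "preprocess", "screen", "associate", "select",
          "build", "evaluate", "all")

_UPSTREAM = {
    "preprocess": ("simulate", "cohort.csv"),
    "screen": ("preprocess", "qc_data.csv"),
    "associate": ("screen", "screening.csv"),
    "select": ("screen", "screening.csv"),
    "build": ("select", "selection.json"),
    "evaluate": ("build", "composite_model.json"),
}


class MissingArtifactError(FileNotFoundError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "digiprog_out"
    input_csv: str | None = None        # external cohort; None -> simulate
    cohort: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    covariates: list = field(default_factory=lambda: ["age"])
    candidate_covariates: list = field(default_factory=lambda: ["age", "sex"])
    lam_grid: list = field(default_factory=lambda: list(selection.DEFAULT_LAMBDA_GRID))
    n_folds: int = 10
    k_max: int = 20
    seed: int = 0
    positive_group: str = "de_novo_pd"
    negative_group: str = "hc"

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) \
                else json.load(fh)
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # analysis identity, not artifact location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float)
                    + "\n", encoding="utf-8")


def _require(out: Path, stage: str) -> Path:
    up, artifact = _UPSTREAM[stage]
    p = out / artifact
    if not p.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs {artifact!r}; run stage {up!r} first")
    return p


def _update_manifest(out: Path, cfg: PipelineConfig, stage: str, counts: dict):
    import sklearn
    import scipy
    import statsmodels
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__,
        },
        "stages": {},
    }
    manifest["stages"][stage] = counts
    _write_json(mpath, manifest)


def run_stage(stage: str, config: PipelineConfig) -> int:
    """Run one pipeline stage (or ``all``); returns 0 on success."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage == "all":
        for s in STAGES[:-1]:
            run_stage(s, config)
        return 0
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if stage == "simulate":
        if config.input_csv:
            data = pd.read_csv(config.input_csv)
        else:
            cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
            data = generate_cohort(cohort_cfg)
            _write_json(out / "cohort_config.json", cohort_cfg.to_dict())
        data.to_csv(out / "cohort.csv", index=False)
        counts = {"rows": len(data),
                  "features": len(preprocess.feature_columns(data))}

    elif stage == "preprocess":
        data = pd.read_csv(_require(out, stage))
        clean, report = preprocess.run_qc_pipeline(
            data, preprocess.QCConfig(**config.qc))
        clean.to_csv(out / "qc_data.csv", index=False)
        report.to_frame().to_csv(out / "qc_report.csv", index=False)
        counts = {"rows": len(clean),
                  "features": len(preprocess.feature_columns(clean)),
                  "imputed_cells": report.imputed_cells,
                  "removed_outlier_values": report.removed_outlier_values}

    elif stage == "screen":
        data = pd.read_csv(_require(out, stage))
        th = lmm.ScreeningThresholds(**config.thresholds)
        covs = lmm.select_covariates(data, config.candidate_covariates)
        if not covs:
            covs = list(config.covariates)
        _write_json(out / "covariates.json", {"selected": covs})
        table = lmm.screen_panel(data, preprocess.feature_columns(data),
                                 covariates=covs, thresholds=th)
        table.to_csv(out / "screening.csv", index=False)
        counts = {"screened": len(table), "passed": int(table["passed"].sum())}

    elif stage == "associate":
        _require(out, stage)
        data = pd.read_csv(out / "qc_data.csv")
        screening = pd.read_csv(out / "screening.csv")
        covs = json.loads((out / "covariates.json").read_text())["selected"]
        covs = [c for c in covs if c != "sex"] or ["age"]
        passed = screening.loc[screening["passed"], "feature"].tolist()
        recs = []
        for f in passed:
            est, se, p = lmm.association_test(data, f, covariates=covs)
            recs.append({"feature": f, "estimate": est, "se": se, "p": p})
        pd.DataFrame.from_records(
            recs, columns=["feature", "estimate", "se", "p"]
        ).to_csv(out / "association.csv", index=False)
        counts = {"tested": len(recs),
                  "significant": int(sum(r["p"] < 0.05 for r in recs))}

    elif stage == "select":
        _require(out, stage)
        data = pd.read_csv(out / "qc_data.csv")
        screening = pd.read_csv(out / "screening.csv")
        covs = json.loads((out / "covariates.json").read_text())["selected"]
        covs = [c for c in covs if c != "sex"] or ["age"]
        passed = screening.loc[screening["passed"], "feature"].tolist()
        if not passed:
            raise RuntimeError("no features passed screening")
        result = selection.select_final_features(
            data, passed, covariates=covs, k_max=config.k_max,
            n_folds=min(config.n_folds, 5), seed=config.seed,
            lam_grid=tuple(config.lam_grid),
            positive_group=config.positive_group,
            negative_group=config.negative_group)
        curves = []
        sel = {}
        for endpoint in ("progression", "classification"):
            curve = result[endpoint]["curve"]
            for f in range(curve.fold_scores.shape[0]):
                for i, k in enumerate(curve.counts):
                    curves.append({"endpoint": endpoint, "fold": f, "k": int(k),
                                   "metric": curve.metric,
                                   "score": curve.fold_scores[f, i]})
            sel[endpoint] = {"chosen_p": result[endpoint]["chosen_p"],
                             "features": result[endpoint]["features"]}
        final = result["final_features"]
        sel["final_features"] = final
        sel["covariates"] = covs
        pd.DataFrame.from_records(curves).to_csv(out / "cv_curves.csv", index=False)
        _write_json(out / "selection.json", sel)
        counts = {"progression_p": sel["progression"]["chosen_p"],
                  "classification_p": sel["classification"]["chosen_p"],
                  "final_features": len(final)}

    elif stage == "build":
        sel = json.loads(_require(out, stage).read_text())
        data = pd.read_csv(out / "qc_data.csv")
        model = ev.fit_composite(data, sel["final_features"], sel["covariates"])
        (out / "composite_model.json").write_text(model.to_json() + "\n")
        counts = {"features": len(model.features)}

    elif stage == "evaluate":
        _require(out, stage)
        sel = json.loads((out / "selection.json").read_text())
        data = pd.read_csv(out / "qc_data.csv")
        scored = ev.crossvalidated_scores(
            data, sel["final_features"], sel["covariates"],
            n_folds=config.n_folds, seed=config.seed)
        scored.to_csv(out / "scored.csv", index=False)
        try:
            ev.roc_points(scored, positive_group=config.positive_group,
                          negative_group=config.negative_group
                          ).to_csv(out / "roc.csv", index=False)
        except Exception:
            pass  # one-class cohorts have no ROC
        report = ev.evaluate_composite(scored, sel["covariates"],
                             positive_group=config.positive_group)
        (out / "evaluation.json").write_text(report.to_json() + "\n")
        counts = {"rows_scored": int(scored["composite_score"].notna().sum())}

    _update_manifest(out, config, stage, counts)
    return 0

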