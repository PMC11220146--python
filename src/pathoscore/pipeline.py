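"""Pipeline orchestration: configuration, stages, artifacts, manifest.

A run directory is append-only: each stage reads the artifacts of earlier
stages and writes its own CSV/JSON outputs plus an entry in
``manifest.json`` (config hash, seeds, registry version), so a run is
reproducible from its manifest and resumable stage by stage.

Stage order: simulate -> extract -> select -> train -> evaluate ->
survival -> enrich.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pathoscore import evaluation, models, survival as surv, texture
from pathoscore.enrichment import gsea_permutation, rank_genes, read_gmt
from pathoscore.selection import mrmr_rank, rfe
from pathoscore.synthetic import CohortConfig, generate_cohort, write_cohort
from pathoscore.tiling import SlideImage

logger = logging.getLogger(__name__)

STAGES = ["simulate", "extract", "select", "train", "evaluate", "survival",
          "enrich"]


class StageError(RuntimeError):
    """A stage failed or its upstream artifact is missing."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable).

    Defaults are the pipeline's standard operating constants: 1024-px tiles
    at 40x / 512-px upsampled at 20x, strict >50% white exclusion, 10
    sampled tiles per slide, 32 gray levels, top-20 mRMR then 6 RFE
    features, tenfold CV, 1000 enrichment permutations, and the p < 0.05 &
    FDR < 0.25 significance gates.
    """

    out_dir: str = "run"
    slides_dir: str | None = None
    clinical_csv: str | None = None
    expression_tsv: str | None = None
    gmt_file: str | None = None
    magnification: int = 20
    tile_k: int = 10
    max_white: float = 0.5
    ng: int = 32
    mrmr_m: int = 20
    rfe_target: int = 6
    model_kind: str = "svm"
    svm_c: float = 1.0
    cv_folds: int = 10
    minprop: float = 0.1
    n_perm: int = 1000
    significance_p: float = 0.05
    significance_fdr: float = 0.25
    seed: int = 0
    simulate: dict | None = None   # CohortConfig overrides, enables simulate

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2**31))


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(config: RunConfig, stage: str, *paths) -> None:
    for p in paths:
        if p is None or not Path(p).exists():
            raise StageError(stage, f"missing upstream artifact {p!r}")


def _update_manifest(config: RunConfig, stage: str, outputs: dict) -> None:
    path = _out(config) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config": config.to_dict(), "config_hash": config.content_hash(),
        "registry_version": texture.REGISTRY_VERSION, "stages": {}}
    manifest["stages"][stage] = {"seed": config.stage_seed(stage),
                                 "outputs": {k: str(v) for k, v in outputs.items()}}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def stage_simulate(config: RunConfig) -> dict:
    if config.simulate is None:
        raise StageError("simulate", "no 'simulate' section in the config")
    cc = CohortConfig(**{"seed": config.stage_seed("simulate"),
                         **config.simulate})
    cohort = generate_cohort(cc)
    out = _out(config)
    paths = write_cohort(cohort, out)
    config.slides_dir = paths["slides_dir"]
    config.clinical_csv = paths["clinical"]
    config.expression_tsv = paths["expression"]
    config.gmt_file = paths["gmt"]
    config.magnification = cc.magnification
    _update_manifest(config, "simulate", paths)
    return paths


def _load_slides(config: RunConfig):
    from PIL import Image

    slides_dir = Path(config.slides_dir)
    for path in sorted(slides_dir.iterdir()):
        if path.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        pixels = np.asarray(Image.open(path).convert("RGB"))
        yield SlideImage(pixels, config.magnification, path.stem)


def stage_extract(config: RunConfig) -> dict:
    _require(config, "extract", config.slides_dir)
    fm = texture.feature_matrix(_load_slides(config), k=config.tile_k,
                                seed=config.stage_seed("extract"),
                                ng=config.ng, max_white=config.max_white)
    out = _out(config) / "features.csv"
    fm.to_csv(out)
    side = _out(config) / "features_meta.json"
    side.write_text(json.dumps({"registry_version": texture.REGISTRY_VERSION,
                                "features": list(fm.columns)}, indent=2))
    _update_manifest(config, "extract", {"features": out, "meta": side})
    return {"features": out}


def _load_features_labels(config: RunConfig, stage: str):
    feats = _out(config) / "features.csv"
    _require(config, stage, feats, config.clinical_csv)
    fm = pd.read_csv(feats, index_col=0)
    clin = pd.read_csv(config.clinical_csv).set_index("patient_id")
    shared = fm.index.intersection(clin.index)
    fm = fm.loc[shared]
    labels = clin.loc[shared, "class"].astype(int)
    return fm, labels, clin.loc[shared]


def stage_select(config: RunConfig) -> dict:
    fm, labels, _ = _load_features_labels(config, "select")
    scaler = texture.zscore_fit(fm)
    z = scaler.transform(fm)
    ranked = mrmr_rank(z, labels.to_numpy(), m=config.mrmr_m)
    kept = [name for name, _ in ranked]
    selected, eliminated = rfe(z[kept], labels.to_numpy(),
                               target=config.rfe_target, C=config.svm_c)
    out = _out(config)
    pd.DataFrame(ranked, columns=["feature", "mrmr_score"]).to_csv(
        out / "mrmr_ranking.csv", index=False)
    (out / "selected_features.json").write_text(json.dumps(
        {"selected": selected, "elimination_order": eliminated}, indent=2))
    _update_manifest(config, "select", {
        "mrmr": out / "mrmr_ranking.csv",
        "selected": out / "selected_features.json"})
    return {"selected": selected}


def stage_train(config: RunConfig) -> dict:
    fm, labels, _ = _load_features_labels(config, "train")
    sel_path = _out(config) / "selected_features.json"
    _require(config, "train", sel_path)
    selected = json.loads(sel_path.read_text())["selected"]
    scaler = texture.zscore_fit(fm)
    z = scaler.transform(fm)[selected]
    clf = models.PathomicsClassifier(kind=config.model_kind, C=config.svm_c)
    clf.fit(z, labels.to_numpy())
    ps = models.pathomics_score(clf.model_, z)
    out = _out(config)
    ps.rename("pathomics_score").to_csv(out / "pathomics_scores.csv")
    coefs = clf.model_.coefficients
    (out / "model.json").write_text(json.dumps({
        "kind": config.model_kind, "features": selected,
        "coefficients": None if coefs is None else coefs.to_dict(),
        "intercept": clf.model_.intercept}, indent=2))
    _update_manifest(config, "train", {"scores": out / "pathomics_scores.csv",
                                       "model": out / "model.json"})
    return {"scores": ps}


def stage_evaluate(config: RunConfig) -> dict:
    fm, labels, _ = _load_features_labels(config, "evaluate")
    ps_path = _out(config) / "pathomics_scores.csv"
    _require(config, "evaluate", ps_path)
    train_ps = pd.read_csv(ps_path, index_col=0)["pathomics_score"]
    y = labels.to_numpy()
    seed = config.stage_seed("evaluate")
    cv_scores, cv_roc = evaluation.kfold_cv(
        fm, y, k=config.cv_folds, seed=seed, model_kind=config.model_kind,
        mrmr_m=config.mrmr_m, rfe_target=config.rfe_target, C=config.svm_c)
    train_roc = evaluation.auc(train_ps.to_numpy(), y)
    thresh = evaluation.youden_threshold(train_ps.to_numpy(), y)
    metrics = {
        "train_auc": train_roc.auc, "train_auc_ci": list(train_roc.ci),
        "cv_auc": cv_roc.auc, "cv_auc_ci": list(cv_roc.ci),
        "threshold": thresh,
        "train": evaluation.threshold_metrics(train_ps.to_numpy(), y, thresh),
        "cv": evaluation.threshold_metrics(cv_scores.to_numpy(), y, thresh),
        "hosmer_lemeshow": dict(zip(("chi2", "df", "p"),
                                    evaluation.hosmer_lemeshow(
                                        cv_scores.to_numpy(), y))),
        "brier": evaluation.brier_score(cv_scores.to_numpy(), y),
    }
    out = _out(config)
    cv_scores.rename("cv_pathomics_score").to_csv(out / "cv_scores.csv")
    evaluation.decision_curve(cv_scores.to_numpy(), y).to_csv(
        out / "decision_curve.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    _update_manifest(config, "evaluate", {
        "cv_scores": out / "cv_scores.csv", "metrics": out / "metrics.json",
        "dca": out / "decision_curve.csv"})
    return metrics


def stage_survival(config: RunConfig) -> dict:
    ps_path = _out(config) / "cv_scores.csv"
    _require(config, "survival", ps_path, config.clinical_csv)
    ps = pd.read_csv(ps_path, index_col=0)["cv_pathomics_score"]
    clin = pd.read_csv(config.clinical_csv).set_index("patient_id")
    shared = ps.index.intersection(clin.index)
    clin = clin.loc[shared]
    ps = ps[shared]
    records = clin[["time_months", "event"]]
    ps_group = (ps > ps.median()).astype(int)
    chi2, dof, logrank_p = surv.logrank_test(records, ps_group)
    km_high = surv.km_estimate(records[ps_group == 1])
    km_low = surv.km_estimate(records[ps_group == 0])
    cut = surv.optimal_cutpoint(clin["marker"].to_numpy(), records,
                                minprop=config.minprop)
    cox_df = records.copy()
    cox_df["ps_group"] = ps_group
    cox = surv.cox_fit(cox_df, ["ps_group"])
    out = _out(config)
    cox.table.to_csv(out / "cox.csv", index=False)
    km_high.curve.to_csv(out / "km_high.csv", index=False)
    km_low.curve.to_csv(out / "km_low.csv", index=False)
    results = {
        "logrank_chi2": chi2, "logrank_p": logrank_p,
        "median_high_ps": km_high.median_months,
        "median_low_ps": km_low.median_months,
        "marker_cutoff": cut.cutoff, "marker_cutoff_p": cut.p_value,
        "ps_group_hr": cox.hr("ps_group"), "ps_group_p": cox.p("ps_group"),
    }
    (out / "survival.json").write_text(json.dumps(results, indent=2))
    _update_manifest(config, "survival", {
        "cox": out / "cox.csv", "summary": out / "survival.json"})
    return results


def stage_enrich(config: RunConfig) -> dict:
    ps_path = _out(config) / "cv_scores.csv"
    _require(config, "enrich", ps_path, config.expression_tsv, config.gmt_file)
    ps = pd.read_csv(ps_path, index_col=0)["cv_pathomics_score"]
    expr = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
    sets = read_gmt(config.gmt_file)
    ranked = rank_genes(expr, ps)
    res = gsea_permutation(ranked, sets, n_perm=config.n_perm,
                           seed=config.stage_seed("enrich"))
    out = _out(config)
    ranked.to_csv(out / "ranked_genes.tsv", sep="\t", index=False)
    res.to_csv(out / "gsea.csv", index=False)
    _update_manifest(config, "enrich", {"ranked": out / "ranked_genes.tsv",
                                        "gsea": out / "gsea.csv"})
    return {"gsea": res}


STAGE_FUNCS = {
    "simulate": stage_simulate, "extract": stage_extract,
    "select": stage_select, "train": stage_train,
    "evaluate": stage_evaluate, "survival": stage_survival,
    "enrich": stage_enrich,
}


def run_pipeline(config: RunConfig, stages: list | None = None) -> dict:
    """Run the pipeline stages in order; returns per-stage results."""
    if stages is None:
        stages = STAGES if config.simulate is not None else STAGES[1:]
    results = {}
    for stage in stages:
        if stage not in STAGE_FUNCS:
            raise StageError(stage, "unknown stage")
        logger.info("running stage %s", stage)
        results[stage] = STAGE_FUNCS[stage](config)
    return results
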