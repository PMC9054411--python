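"""End-to-end orchestration: generate/ingest -> extract -> assemble -> select
-> train -> evaluate.

The default run generates a phantom cohort, extracts the 43-feature block
per phase per case, assembles 115 static + 108 delta features, picks one
of the five feature sets, and evaluates a selection-cascade + kernel-SVM
model under the configured validation scheme. By default the full
selection cascade is refit inside every training split (leak-free nested
evaluation); setting ``paper_mode`` performs selection once on the whole
cohort before splitting, which reproduces the common-but-leaky design.

Every run writes its resolved config alongside its outputs, and a rerun
with the same config and seed reproduces the summary exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, multiphase, phantom, radiomics, selection, svm
from .imaging_io import PHASE_ORDER, VOIStack, load_manifest

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    # cohort source: generate a phantom unless a manifest is given
    manifest: str | None = None
    n_per_class: int = 24
    grid: int = 48
    radius_min_mm: float = 8.0
    radius_max_mm: float = 15.0
    # extraction
    G: int = 64
    distance: int = 1
    # feature set (S1 morphology, S2 per-phase, S3 delta, S4 static, S5 all)
    feature_set: str = "S5"
    # selection cascade
    corr_threshold: float = 0.9
    alpha: float = 0.05
    lasso_folds: int = 5
    # classifier
    kernel: str = "rbf"
    degree: int = 3
    gamma: float | None = None
    C: float = 1.0
    svm_tol: float = 1e-3
    # evaluation
    scheme: str = "kfold"
    k: int = 5
    test_fraction: float = 0.25
    n_bootstrap: int = 50
    paper_mode: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def kernel_spec(self) -> svm.KernelSpec:
        return svm.KernelSpec(family=self.kernel, degree=self.degree, gamma=self.gamma)


def extract_cohort(
    stacks: list[VOIStack], G: int = 64, distance: int = 1
) -> tuple[pd.DataFrame, pd.Series]:
    """All 223 features (115 static + 108 delta) for every case."""
    vectors = []
    for stack in stacks:
        blocks = {pid: radiomics.phase_block(stack, pid, G=G, distance=distance)
                  for pid in PHASE_ORDER}
        label = evaluation.map_recist(stack.recist)
        vectors.append(multiphase.assemble_case(stack.case_id, blocks, label))
    return multiphase.cohort_table(vectors)


def _fit_fold(
    X_tr: pd.DataFrame, y_tr: np.ndarray, cfg: RunConfig, fold_seed: int,
    preselected: list[str] | None = None,
) -> tuple[svm.SVMModel, list[str], np.ndarray, np.ndarray, selection.SelectionReport | None]:
    """Selection (unless preselected) + standardization + SVM on one train split."""
    report = None
    if preselected is None:
        X_sel, report = selection.run_cascade(
            X_tr, y_tr, corr_threshold=cfg.corr_threshold, alpha=cfg.alpha,
            folds=cfg.lasso_folds, seed=fold_seed,
        )
        cols = list(X_sel.columns)
        if not cols:  # nothing survived: fall back to the full table
            logger.warning("selection removed every column; using all features")
            cols = list(X_tr.columns)
    else:
        cols = preselected
    vals = X_tr[cols].to_numpy(dtype=float)
    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = svm.train(
        (vals - mu) / sd, y_tr, kernel=cfg.kernel_spec(), C=cfg.C, tol=cfg.svm_tol,
    )
    return model, cols, mu, sd, report


def cross_validated_scores(
    X: pd.DataFrame, y: np.ndarray, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Out-of-fold decision scores under the configured scheme.

    Returns (scores, labels, per-fold records). With ``paper_mode`` the
    cascade runs once on the whole cohort; otherwise it is refit per fold.
    """
    y = np.asarray(y)
    splits = evaluation.split(
        y, cfg.scheme, seed=cfg.seed, test_fraction=cfg.test_fraction,
        k=cfg.k, n_bootstrap=cfg.n_bootstrap,
    )
    preselected = None
    if cfg.paper_mode:
        X_sel, _ = selection.run_cascade(
            X, y, corr_threshold=cfg.corr_threshold, alpha=cfg.alpha,
            folds=cfg.lasso_folds, seed=cfg.seed,
        )
        preselected = list(X_sel.columns) or list(X.columns)
    all_scores, all_labels, per_fold = [], [], []
    for f, (tr, te) in enumerate(splits):
        model, cols, mu, sd, _ = _fit_fold(
            X.iloc[tr], y[tr], cfg, fold_seed=cfg.seed + 1000 + f, preselected=preselected,
        )
        scores = svm.decision(model, (X.iloc[te][cols].to_numpy(dtype=float) - mu) / sd)
        all_scores.append(scores)
        all_labels.append(y[te])
        rec = {"fold": f, "n_train": len(tr), "n_test": len(te),
               "n_selected": len(cols), "selected": cols}
        if len(np.unique(y[te])) == 2:
            rec["auc"] = evaluation.roc_auc(scores, y[te]).auc
        per_fold.append(rec)
    return np.concatenate(all_scores), np.concatenate(all_labels), per_fold


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and persist all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")

    if cfg.manifest:
        stacks = load_manifest(cfg.manifest)
    else:
        pcfg = phantom.PhantomConfig(
            n_per_class=cfg.n_per_class, grid=(cfg.grid,) * 3,
            radius_range_mm=(cfg.radius_min_mm, cfg.radius_max_mm), seed=cfg.seed,
        )
        stacks, truth = phantom.generate_cohort(pcfg)
        truth.to_csv(outdir / "ground_truth.csv", index=False)

    X, y = extract_cohort(stacks, G=cfg.G, distance=cfg.distance)
    X.to_csv(outdir / "features.csv")
    sets = multiphase.build_feature_sets(X)
    Xset = sets[cfg.feature_set]
    yv = y.to_numpy()

    scores, labels, per_fold = cross_validated_scores(Xset, yv, cfg)
    report = evaluation.roc_auc(scores, labels, scheme=cfg.scheme)
    report.per_fold = per_fold
    report.to_json(outdir / "eval_report.json")
    pd.DataFrame({"fpr": report.fpr, "tpr": report.tpr}).to_csv(
        outdir / "roc_points.csv", index=False)

    # final deliverable model: cascade + SVM on the full cohort
    model, cols, mu, sd, sel_report = _fit_fold(Xset, yv, cfg, fold_seed=cfg.seed)
    model.to_json(outdir / "model.json")
    if sel_report is not None:
        sel_report.to_json(outdir / "selection_report.json")

    summary = {
        "n_cases": int(X.shape[0]),
        "static_feature_count": multiphase.N_STATIC,
        "delta_feature_count": multiphase.N_DELTA,
        "feature_set": cfg.feature_set,
        "feature_set_columns": int(Xset.shape[1]),
        "final_selected_features": cols,
        "auc": report.auc,
        "auc_grade": report.auc_grade,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "scheme": cfg.scheme,
        "paper_mode": cfg.paper_mode,
        "per_fold": per_fold,
        "seed": cfg.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
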