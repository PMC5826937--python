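"""End-to-end orchestration of the storage-stability analysis.

Stage order: zero conversion -> QC filters -> preprocessing -> univariate
statistics (repeated-measures ANOVA, paired t vs day 0) and moderated
Hotelling T^2 ranking -> train/test split -> lambda (optionally alpha)
selection by cross-validation on the training set -> final elastic-net
Poisson fit -> evaluation on train and test -> feature ranking -> summary
artifacts (heat-map matrix of per-day means, PCA scores of the selected
features). Every artifact is written deterministically so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import elasticnet as enet
from . import meba as meba_mod
from . import qc, univariate
from .preprocess import PreprocessedMatrix, preprocess as preprocess_matrix
from .containers import FeatureTable, FilterReport, write_json
from .simulate import SyntheticConfig, SyntheticTruth, generate_experiment, config_to_dict


@dataclass
class PipelineConfig:
    """Everything a run needs; seed is mandatory for any stochastic step."""

    input_dir: str | None = None  # FeatureTable trio on disk, or None
    synthetic: SyntheticConfig | None = None  # generate instead of load
    r2_threshold: float = 0.5
    cv_threshold: float = 30.0
    max_missing: float = 0.20
    knn_k: int = 10
    glog_a: float | str = "auto"
    alpha: float = 0.5
    screen_alpha: bool = False
    alpha_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    cv_folds: int | str = 10  # int k, or "loo"
    lambda_rule: str = "1se"  # "1se" | "min"
    n_lambda: int = 100
    split_fraction: float = 0.75
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_dir / synthetic")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")
        for name, lo, hi in (("r2_threshold", 0, 1), ("max_missing", 0, 1),
                             ("alpha", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class StabilityReport:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    filter_report: FilterReport
    stage_counts: pd.DataFrame
    preprocessed: PreprocessedMatrix
    anova: univariate.AnovaResult
    pairwise: univariate.PairwiseResult
    meba: meba_mod.MEBAResult
    cv: enet.CVResult
    model: enet.ElasticNetModel
    selection_cv: enet.CVResult
    selection_model: enet.ElasticNetModel
    eval_train: enet.PredictionEval
    eval_test: enet.PredictionEval
    selected: pd.DataFrame
    heatmap: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_explained: np.ndarray
    predictions: pd.DataFrame
    alpha_used: float
    truth: SyntheticTruth | None = None
    alpha_screen: dict = field(default_factory=dict)


def heatmap_matrix(
    pm: PreprocessedMatrix, selected: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Selected-features x days matrix of per-day mean autoscaled intensity.

    Rows follow the |coefficient| ranking of the selected features.
    """
    days = np.sort(design["storage_day"].unique())
    feats = selected["feature_id"].tolist()
    out = pd.DataFrame(index=pd.Index(feats, name="feature_id"),
                       columns=[int(d) for d in days], dtype=float)
    for d in days:
        ids = design.index[design["storage_day"] == d]
        out[int(d)] = pm.values.loc[ids, feats].mean(axis=0).to_numpy()
    return out


def pca_scores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal-component scores of the column-centered matrix.

    Returns (scores DataFrame indexed by sample, explained-variance
    fractions for all components, descending).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 features")
    Xc = matrix.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * s
    frac = s**2 / np.sum(s**2)
    df = pd.DataFrame(scores[:, :2], index=matrix.index, columns=["PC1", "PC2"])
    return df, frac


def run_pipeline(config: PipelineConfig) -> StabilityReport:
    """Execute every stage; write artifacts if config.outdir is set."""
    config.validate()
    truth = None
    if config.synthetic is not None:
        table, truth = generate_experiment(config.synthetic)
    else:
        table = FeatureTable.from_dir(config.input_dir)

    n_input = len(table.feature_ids)
    filtered, report = qc.apply_filters(
        table, config.r2_threshold, config.cv_threshold, config.max_missing
    )

    design = filtered.study_design()
    pm = preprocess_matrix(filtered.study_matrix(), k=config.knn_k,
                               glog_a=config.glog_a)

    anova = univariate.rm_anova(pm.values, design)
    pairwise = univariate.paired_t_vs_day0(pm.values, design)
    meba_res = meba_mod.rank_features_t2(pm.values, design)

    # --- modeling on the training split ----------------------------------
    train_ids, test_ids = enet.split_train_test(
        filtered.samples, fraction=config.split_fraction, seed=config.seed
    )
    y_train = design.loc[train_ids, "storage_day"].to_numpy(dtype=float)
    y_test = design.loc[test_ids, "storage_day"].to_numpy(dtype=float)
    X_all = pm.values
    # re-center on the training split so the solver's centered-input
    # contract holds exactly on the data it sees
    mu_train = X_all.loc[train_ids].mean(axis=0)
    X_train = (X_all.loc[train_ids] - mu_train).to_numpy(dtype=float)
    X_test = (X_all.loc[test_ids] - mu_train).to_numpy(dtype=float)

    alpha_screen: dict = {}
    if config.screen_alpha:
        alpha_used, per_alpha = enet.select_alpha(
            X_train, y_train, alpha_grid=config.alpha_grid,
            folds=config.cv_folds, seed=config.seed, n_lambda=config.n_lambda,
        )
        alpha_screen = {a: r.to_frame() for a, r in per_alpha.items()}
        cv = per_alpha[alpha_used]
    else:
        alpha_used = config.alpha
        cv = enet.cross_validate_lambda(
            X_train, y_train, alpha_used, folds=config.cv_folds,
            seed=config.seed, n_lambda=config.n_lambda,
        )
    lam = cv.lambda_1se if config.lambda_rule == "1se" else cv.lambda_min
    # warm-start the final fit down the path to the chosen lambda
    path_lams = cv.lambdas[cv.lambdas >= lam]
    models = enet.fit_lambda_path(
        X_train, y_train, alpha_used, path_lams,
        feature_names=list(X_all.columns),
    )
    model = models[-1]

    yhat_train = enet.predict_storage_days(model, X_train)
    yhat_test = enet.predict_storage_days(model, X_test)
    eval_train = enet.evaluate_predictions(y_train, yhat_train)
    eval_test = enet.evaluate_predictions(y_test, yhat_test)

    # --- feature-extraction fit on all study samples ----------------------
    # the split exists to validate prediction; selection uses the full data
    y_all = design["storage_day"].to_numpy(dtype=float)
    X_full = (X_all - X_all.mean(axis=0)).to_numpy(dtype=float)
    sel_cv = enet.cross_validate_lambda(
        X_full, y_all, alpha_used, folds=config.cv_folds,
        seed=config.seed, n_lambda=config.n_lambda,
    )
    sel_lam = sel_cv.lambda_1se if config.lambda_rule == "1se" else sel_cv.lambda_min
    sel_model = enet.fit_lambda_path(
        X_full, y_all, alpha_used, sel_cv.lambdas[sel_cv.lambdas >= sel_lam],
        feature_names=list(X_all.columns),
    )[-1]
    selected = enet.rank_selected_features(sel_model)
    if len(selected):
        hm = heatmap_matrix(pm, selected, design)
        pca_df, pca_frac = pca_scores(pm.values[selected["feature_id"].tolist()])
    else:
        hm = pd.DataFrame()
        pca_df, pca_frac = pd.DataFrame(columns=["PC1", "PC2"]), np.array([])

    predictions = pd.DataFrame(
        {
            "sample_id": list(train_ids) + list(test_ids),
            "actual_day": np.concatenate([y_train, y_test]).astype(int),
            "predicted_day": np.concatenate([yhat_train, yhat_test]),
            "split": ["train"] * len(train_ids) + ["test"] * len(test_ids),
        }
    )

    counts = report.stage_counts
    result = StabilityReport(
        config=config, filter_report=report, stage_counts=counts,
        preprocessed=pm, anova=anova, pairwise=pairwise, meba=meba_res,
        cv=cv, model=model, selection_cv=sel_cv, selection_model=sel_model,
        eval_train=eval_train, eval_test=eval_test,
        selected=selected, heatmap=hm, pca_scores=pca_df,
        pca_explained=pca_frac, predictions=predictions,
        alpha_used=alpha_used, truth=truth, alpha_screen=alpha_screen,
    )
    # consistency bookkeeping: each stage consumed the previous stage's output
    _assert_stage_chain(counts, n_input)
    if config.outdir is not None:
        write_artifacts(result, Path(config.outdir))
    return result


def _assert_stage_chain(counts: pd.DataFrame, n_input: int) -> None:
    order = ["zero_conversion", "dilution", "qc_cv", "missingness"]
    tab = counts.set_index("stage")
    expect = n_input
    for stage in order:
        total = int(tab.loc[stage, "retained"] + tab.loc[stage, "removed"])
        if total != expect:
            raise RuntimeError(f"stage bookkeeping broken at {stage}: "
                               f"{total} features entered, expected {expect}")
        expect = int(tab.loc[stage, "retained"])


def write_artifacts(result: StabilityReport, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    result.filter_report.to_tsv(outdir / "filter_report.tsv")
    result.stage_counts.to_csv(outdir / "stage_counts.tsv", sep="\t", index=False)
    result.preprocessed.values.to_csv(outdir / "preprocessed.csv",
                                      index_label="sample_id", float_format=ff)
    write_json(result.preprocessed.provenance(), outdir / "provenance.json")
    result.anova.table.to_csv(outdir / "anova.tsv", sep="\t",
                              index_label="feature_id", float_format=ff)
    result.pairwise.table.to_csv(outdir / "pairwise.tsv", sep="\t", index=False,
                                 float_format=ff)
    result.pairwise.counts.to_csv(outdir / "pairwise_counts.tsv", sep="\t",
                                  index=False)
    result.meba.table.to_csv(outdir / "meba.tsv", sep="\t",
                             index_label="feature_id", float_format=ff)
    result.cv.to_frame().to_csv(outdir / "cv_curve.tsv", sep="\t", index=False,
                                float_format=ff)
    result.selection_cv.to_frame().to_csv(outdir / "selection_cv_curve.tsv",
                                          sep="\t", index=False, float_format=ff)
    sel_info = result.selection_model.to_dict()
    sel_info.update({"lambda_min": result.selection_cv.lambda_min,
                     "lambda_1se": result.selection_cv.lambda_1se})
    write_json(sel_info, outdir / "selection_model.json")
    model_info = result.model.to_dict()
    model_info.update(
        {
            "alpha_used": result.alpha_used,
            "lambda_min": result.cv.lambda_min,
            "lambda_1se": result.cv.lambda_1se,
            "lambda_rule": result.config.lambda_rule,
            "seed": result.config.seed,
            "rmse_train": result.eval_train.rmse,
            "rmsep_test": result.eval_test.rmse,
            "r2_train": result.eval_train.r2,
            "r2_test": result.eval_test.r2,
        }
    )
    write_json(model_info, outdir / "model.json")
    result.predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False,
                              float_format=ff)
    result.selected.to_csv(outdir / "selected_features.tsv", sep="\t",
                           index=False, float_format=ff)
    result.heatmap.to_csv(outdir / "heatmap.tsv", sep="\t", float_format=ff)
    result.pca_scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                             index_label="sample_id", float_format=ff)
    if result.truth is not None:
        result.truth.to_tsv(outdir / "truth.tsv")
    cfg = asdict(result.config)
    if result.config.synthetic is not None:
        cfg["synthetic"] = config_to_dict(result.config.synthetic)
    cfg["alpha_grid"] = list(cfg["alpha_grid"])
    cfg.pop("outdir", None)  # where the run lives, not what it computes
    write_json(cfg, outdir / "config.json")
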