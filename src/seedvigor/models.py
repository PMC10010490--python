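"""Calibration/prediction modelling stage.

The labelled seed set is split 7:3 into a calibration (training) and a
prediction (held-out) set. Viability classification compares four
algorithms — XGBoost, LightGBM, an RBF-kernel SVM and a random forest —
and SOD-activity regression compares partial least squares regression
(PLSR) against XGBoost. :func:`run_grid` crosses every preprocessing
method with the full grid and both band selectors and every model,
mirroring the usual chemometrics results table, with all fitting
(preprocessing references, band ranking, model training, PLSR component
choice) done on the calibration set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

from .band_select import rank_bands, subset_to_ranking
from .dataset import SpectralDataset
from .preprocess import Preprocessor

__all__ = [
    "SplitSpec",
    "ModelReport",
    "PLSRModel",
    "split_dataset",
    "train_classifier",
    "evaluate_classifier",
    "plsr_fit",
    "train_regressor",
    "evaluate_regression",
    "run_grid",
    "GridResult",
    "CLASSIFIER_ALGORITHMS",
    "REGRESSOR_ALGORITHMS",
]

CLASSIFIER_ALGORITHMS = ("xgboost", "lightgbm", "svm-rbf", "random-forest")
REGRESSOR_ALGORITHMS = ("plsr", "xgboost")


@dataclass
class SplitSpec:
    """Calibration/prediction split: 7:3, optionally stratified."""

    ratio: float = 0.7
    rng_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("split ratio must lie in (0, 1)")


def split_dataset(
    dataset: SpectralDataset, spec: SplitSpec, labels: np.ndarray | None = None
) -> tuple[SpectralDataset, SpectralDataset]:
    """Random disjoint calibration/prediction split, deterministic by seed.

    With the default 0.7 ratio on n seeds the calibration set holds
    floor(0.7 n) seeds and the prediction set the remainder.
    ``labels`` (default: the viability labels) drive stratification.
    """
    n = dataset.n_seeds
    strat = None
    if spec.stratified:
        strat = dataset.viable if labels is None else np.asarray(labels)
    idx_cal, idx_pred = train_test_split(
        np.arange(n),
        train_size=spec.ratio,
        random_state=spec.rng_seed,
        stratify=strat,
        shuffle=True,
    )
    return dataset.select_seeds(np.sort(idx_cal)), dataset.select_seeds(np.sort(idx_pred))


def train_classifier(X, y, algorithm: str, params: dict | None = None, seed: int = 0):
    """Fit one of the four viability classifiers with a fixed seed.

    Hyperparameters default to the library defaults (recorded on the
    fitted object) except the SVM, which uses an RBF kernel with C=1 and
    gamma = 1 / (n_bands * Var(X)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration set holds a single class")
    params = dict(params or {})
    if algorithm == "xgboost":
        model = XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0, **params,
        )
    elif algorithm == "lightgbm":
        model = LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, **params,
        )
    elif algorithm == "svm-rbf":
        params.setdefault("C", 1.0)
        params.setdefault("gamma", "scale")  # 1 / (n_features * Var(X))
        model = SVC(kernel="rbf", random_state=seed, **params)
    elif algorithm == "random-forest":
        model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        raise ValueError(f"unknown algorithm '{algorithm}'")
    model.fit(X, y)
    return model


@dataclass
class ModelReport:
    """Metrics for one (preprocess, selector, model) cell.

    ``calibration``/``prediction`` are metric dicts — ``accuracy`` (%)
    for classification, ``r2`` and ``rmse`` for regression. Confusion
    matrices have rows = true class, columns = predicted class.
    """

    cell: tuple[str, str, str]
    calibration: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    confusion_calibration: np.ndarray | None = None
    confusion_prediction: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _accuracy_pct(n_correct: int, n_total: int) -> float:
    """Share of correct decisions on the 0-100 scale, 2-decimal rounding."""
    return round(100.0 * n_correct / n_total, 2)


def evaluate_classifier(model, X, y, cell=("", "", "")) -> ModelReport:
    """Accuracy (percent, 2 decimals) and the full confusion matrix."""
    y = np.asarray(y)
    pred = model.predict(np.asarray(X, dtype=float))
    labels = np.unique(np.concatenate([y, pred]))
    cm = _sk_confusion(y, pred, labels=labels)
    correct = int(np.trace(cm))
    report = ModelReport(cell=tuple(cell))
    report.prediction = {
        "accuracy": _accuracy_pct(correct, len(y)),
        "n_correct": correct,
        "n": int(len(y)),
    }
    report.confusion_prediction = cm
    return report


class PLSRModel:
    """Mean-centered partial least squares regression.

    Thin wrapper over a NIPALS-equivalent PLS fit (SIMPLS-style
    deflation) exposing the latent structure: ``x_weights_``,
    ``x_loadings_``, ``x_scores_`` and the folded regression
    coefficients, with prediction = (X - x_mean) @ coef + y_mean.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components
        self._pls = PLSRegression(n_components=n_components, scale=False)

    def fit(self, X, y) -> "PLSRModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("X has zero variance")
        self._pls.fit(X, y)
        self.x_mean_ = self._pls._x_mean
        self.y_mean_ = float(np.ravel(self._pls.intercept_)[0])
        self.coef_ = self._pls.coef_.ravel()
        self.x_weights_ = self._pls.x_weights_
        self.x_loadings_ = self._pls.x_loadings_
        self.x_scores_ = self._pls.x_scores_
        return self

    def predict(self, X) -> np.ndarray:
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()


def plsr_fit(
    X,
    y,
    n_components: int | None = None,
    max_components: int = 15,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSRModel:
    """Fit PLSR; if ``n_components`` is None, choose it by k-fold CV RMSE.

    Candidate counts run 1..min(max_components, n_samples - 1, n_bands);
    the count with the lowest cross-validated RMSE on the calibration
    set wins (smallest count on ties).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    cap = min(max_components, X.shape[0] - 1, X.shape[1])
    if cap < 1:
        raise ValueError("not enough samples/bands for PLSR")
    if n_components is None:
        if np.allclose(y, y[0]):
            n_components = 1  # constant target: any component count is equal
        else:
            folds = KFold(n_splits=min(cv_folds, X.shape[0]), shuffle=True,
                          random_state=seed)
            split_idx = list(folds.split(X))
            best_rmse, n_components = np.inf, 1
            for nc in range(1, cap + 1):
                sse, n_obs = 0.0, 0
                for tr, te in split_idx:
                    nc_fold = min(nc, len(tr) - 1)
                    m = PLSRegression(n_components=nc_fold, scale=False)
                    m.fit(X[tr], y[tr])
                    resid = m.predict(X[te]).ravel() - y[te]
                    sse += float(resid @ resid)
                    n_obs += len(te)
                rmse = np.sqrt(sse / n_obs)
                if rmse < best_rmse - 1e-12:
                    best_rmse, n_components = rmse, nc
    n_components = min(n_components, cap)
    return PLSRModel(n_components=n_components).fit(X, y)


def train_regressor(X, y, algorithm: str = "plsr", params: dict | None = None,
                    seed: int = 0):
    """Fit a SOD regressor: PLSR or XGBoost."""
    params = dict(params or {})
    if algorithm == "plsr":
        return plsr_fit(X, y, seed=seed, **params)
    if algorithm == "xgboost":
        model = XGBRegressor(random_state=seed, n_jobs=1, tree_method="hist",
                             verbosity=0, **params)
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return model
    raise ValueError(f"unknown regressor '{algorithm}'")


def evaluate_regression(model, X, y, cell=("", "", "")) -> ModelReport:
    """R-squared (1 - SSres/SStot) and RMSE of the model on a set."""
    y = np.asarray(y, dtype=float).ravel()
    pred = np.asarray(model.predict(np.asarray(X, dtype=float))).ravel()
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt(np.mean(resid**2)))
    report = ModelReport(cell=tuple(cell))
    report.prediction = {"r2": r2, "rmse": rmse, "n": int(len(y))}
    return report


@dataclass
class GridResult:
    """All cell reports plus the flattened results table and best cell."""

    reports: list[ModelReport]
    table: pd.DataFrame
    best: ModelReport

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_grid(
    dataset: SpectralDataset,
    target: str = "viability",
    preprocess_list=("raw", "SG", "MSC", "MF"),
    selector_list=("full", "catboost", "gbdt"),
    model_list=None,
    split: SplitSpec | None = None,
    k: int = 15,
    seed: int = 0,
    select_on: str = "calibration",
) -> GridResult:
    """Evaluate every (preprocess x band-set x model) cell.

    ``select_on`` controls whether band ranking sees the calibration set
    only (leakage-safe default) or the full dataset.
    """
    if target not in ("viability", "sod"):
        raise ValueError("target must be 'viability' or 'sod'")
    if model_list is None:
        model_list = CLASSIFIER_ALGORITHMS if target == "viability" else REGRESSOR_ALGORITHMS
    if not (len(preprocess_list) and len(selector_list) and len(model_list)):
        raise ValueError("grid axes must be non-empty")
    if select_on not in ("calibration", "all"):
        raise ValueError("select_on must be 'calibration' or 'all'")
    split = split or SplitSpec(rng_seed=seed)
    labels = dataset.viable if target == "viability" else None
    cal, pred = split_dataset(dataset, split, labels=labels)

    reports: list[ModelReport] = []
    rows = []
    for pre_name in preprocess_list:
        prep = Preprocessor(pre_name).fit(cal.spectra)
        cal_p = cal.with_spectra(prep.transform(cal.spectra))
        pred_p = pred.with_spectra(prep.transform(pred.spectra))
        for sel_name in selector_list:
            if sel_name == "full":
                cal_s, pred_s = cal_p, pred_p
            else:
                if select_on == "calibration":
                    rank_input = cal_p
                else:
                    rank_input = dataset.with_spectra(prep.transform(dataset.spectra))
                ranking = rank_bands(rank_input, target=target, method=sel_name,
                                     k=min(k, cal_p.n_bands), seed=seed)
                cal_s = subset_to_ranking(cal_p, ranking)
                pred_s = subset_to_ranking(pred_p, ranking)
            for model_name in model_list:
                cell = (pre_name, sel_name, model_name)
                if target == "viability":
                    model = train_classifier(
                        cal_s.spectra, cal_s.viable.astype(int), model_name,
                        seed=seed,
                    )
                    rep_cal = evaluate_classifier(
                        model, cal_s.spectra, cal_s.viable.astype(int), cell)
                    rep_pred = evaluate_classifier(
                        model, pred_s.spectra, pred_s.viable.astype(int), cell)
                else:
                    model = train_regressor(cal_s.spectra, cal_s.sod,
                                            model_name, seed=seed)
                    rep_cal = evaluate_regression(model, cal_s.spectra,
                                                  cal_s.sod, cell)
                    rep_pred = evaluate_regression(model, pred_s.spectra,
                                                   pred_s.sod, cell)
                report = ModelReport(
                    cell=cell,
                    calibration=rep_cal.prediction,
                    prediction=rep_pred.prediction,
                    confusion_calibration=rep_cal.confusion_prediction,
                    confusion_prediction=rep_pred.confusion_prediction,
                    params={"seed": seed, "n_components": getattr(model, "n_components", None)},
                )
                reports.append(report)
                row = {"preprocess": pre_name, "selector": sel_name,
                       "model": model_name}
                row.update({f"cal_{k_}": v for k_, v in report.calibration.items()})
                row.update({f"pre_{k_}": v for k_, v in report.prediction.items()})
                rows.append(row)

    table = pd.DataFrame(rows)
    metric = "accuracy" if target == "viability" else "r2"
    best_idx = int(np.argmax([r.prediction[metric] for r in reports]))
    return GridResult(reports=reports, table=table, best=reports[best_idx])


def plot_confusion(report: ModelReport, which: str = "prediction", path=None,
                   class_names=("non-viable", "viable")):
    """Heat-map rendering of a confusion matrix."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cm = (report.confusion_prediction if which == "prediction"
          else report.confusion_calibration)
    if cm is None:
        raise ValueError("report holds no confusion matrix")
    fig, ax = plt.subplots(figsize=(3.5, 3))
    ax.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks(range(len(class_names)), class_names)
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"{'-'.join(report.cell)} ({which})")
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
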