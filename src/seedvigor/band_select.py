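"""Feature-band (characteristic wavelength) selection.

Hyperspectral grids are heavily redundant; a gradient-boosted tree
ensemble fitted on the full grid provides per-wavelength importance
scores (total gain, i.e. summed loss reduction of splits on that band),
and the top-k wavelengths are retained for the downstream models.

Two ranker flavors are exposed:

* ``catboost`` — an ordered-boosting-style histogram GBM (XGBoost's
  hist tree method); the contract is the ranking procedure, not a
  particular brand of booster.
* ``gbdt`` — the classic gradient-boosted decision tree of
  scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from xgboost import XGBClassifier, XGBRegressor

from .dataset import SpectralDataset

__all__ = ["BandRanking", "rank_bands", "subset_to_ranking", "SELECTOR_METHODS"]

SELECTOR_METHODS = ("catboost", "gbdt")

#: booster settings shared by both flavors (none are tuned per dataset)
DEFAULT_TREES = 500
DEFAULT_DEPTH = 6
DEFAULT_LEARNING_RATE = 0.1


@dataclass
class BandRanking:
    """Top-k wavelengths sorted by non-increasing importance weight."""

    wavelengths: np.ndarray
    weights: np.ndarray
    method: str
    k: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.wavelengths) != self.k or len(self.weights) != self.k:
            raise ValueError("ranking length must equal k")
        if len(np.unique(self.wavelengths)) != self.k:
            raise ValueError("ranked wavelengths must be unique")
        if np.any(self.weights < 0):
            raise ValueError("importance weights must be non-negative")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "weight": self.weights,
                "rank": np.arange(1, self.k + 1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_weights(self, path=None, ax=None):
        """Stem plot of importance weight against wavelength."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.2))
        ax.stem(self.wavelengths, self.weights, basefmt=" ")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("importance weight")
        ax.set_title(f"top-{self.k} bands ({self.method})")
        if path is not None:
            ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def _fit_ranker(X, y, target: str, method: str, seed: int):
    common = dict(
        n_estimators=DEFAULT_TREES,
        max_depth=DEFAULT_DEPTH,
        learning_rate=DEFAULT_LEARNING_RATE,
        random_state=seed,
    )
    if method == "catboost":
        xgb_args = dict(common, tree_method="hist", n_jobs=1,
                        importance_type="total_gain", verbosity=0)
        model = (XGBClassifier(**xgb_args) if target == "viability"
                 else XGBRegressor(**xgb_args))
    elif method == "gbdt":
        model = (GradientBoostingClassifier(**common) if target == "viability"
                 else GradientBoostingRegressor(**common))
    else:
        raise ValueError(f"method must be one of {SELECTOR_METHODS}")
    model.fit(X, y)
    return model


def rank_bands(
    dataset: SpectralDataset,
    target: str = "viability",
    method: str = "catboost",
    k: int = 15,
    seed: int = 0,
) -> BandRanking:
    """Rank wavelengths by boosted-tree importance and keep the top k.

    ``target`` is ``"viability"`` (binary classification on the
    germination label) or ``"sod"`` (regression on SOD activity). The
    ensemble is fitted on the full grid with fixed hyperparameters and
    seed; per-band total-gain importances are sum-normalized and the k
    largest kept, ties broken by ascending wavelength. Deterministic
    given the seed.
    """
    if k > dataset.n_bands:
        raise ValueError("k exceeds the number of bands")
    X = dataset.spectra
    if target == "viability":
        y = dataset.viable.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("viability target has a single class")
    elif target == "sod":
        y = dataset.sod
        if np.all(y == y[0]):
            raise ValueError("sod target is constant")
    else:
        raise ValueError("target must be 'viability' or 'sod'")

    model = _fit_ranker(X, y, target, method, seed)
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    # round away float jitter (~1e-16, e.g. from sample-order permutations)
    # so the wavelength tie-break below governs near-ties deterministically
    imp = np.round(imp, 12)
    # ties broken by ascending wavelength
    order = np.lexsort((dataset.wavelengths, -imp))[:k]
    return BandRanking(
        wavelengths=dataset.wavelengths[order],
        weights=imp[order],
        method=method,
        k=k,
    )


def subset_to_ranking(dataset: SpectralDataset, ranking: BandRanking) -> SpectralDataset:
    """Restrict the dataset to the ranked wavelengths.

    Columns are returned in ascending-wavelength order (the container
    keeps a monotone grid); the set of columns is exactly the ranking's.
    """
    idx = []
    for w in ranking.wavelengths:
        hit = np.flatnonzero(np.isclose(dataset.wavelengths, w))
        if hit.size == 0:
            raise ValueError(f"ranked wavelength {w} nm not in dataset grid")
        idx.append(hit[0])
    return dataset.select_bands(np.sort(np.asarray(idx)))
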