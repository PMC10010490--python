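"""Group-level correlation of bands, vigor indices and SOD activity.

The five aging groups are summarized by their mean reflectance at the
top-ranked wavelengths, the six vigor indices, and the group-mean SOD
activity; a Pearson matrix across the five group rows links spectral
behaviour to physiology. With n = 5 rows these coefficients are
descriptive only (no p-values are attached), which the API flags with a
warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GROUPS, SpectralDataset
from .phenotype import VigorIndices

__all__ = ["build_group_summary", "pearson_matrix", "plot_heatmap"]

INDEX_COLS = ["GP", "GE", "GI", "MGT", "VI", "SVI"]


def build_group_summary(
    dataset: SpectralDataset,
    indices_by_group: dict[str, VigorIndices],
    sod_by_group: dict[str, float] | None = None,
    top_bands=None,
) -> pd.DataFrame:
    """One row per aging group: vigor indices, mean SOD, band means.

    ``sod_by_group`` defaults to group means of the dataset's SOD
    column; ``top_bands`` is the wavelength list whose group-mean
    reflectances are tabulated (typically the union of the top-5
    classification and top-5 regression bands).

    Column order: vigor indices, SOD, then wavelengths ascending.
    """
    missing = [g for g in GROUPS if g not in set(dataset.group)]
    if missing:
        raise ValueError(f"dataset lacks groups: {missing}")
    for g in GROUPS:
        if g not in indices_by_group:
            raise ValueError(f"no vigor indices for group {g}")
    if top_bands is None:
        top_bands = dataset.wavelengths
    top_bands = np.sort(np.asarray(top_bands, dtype=float))

    band_idx = []
    for w in top_bands:
        hit = np.flatnonzero(np.isclose(dataset.wavelengths, w))
        if hit.size == 0:
            raise ValueError(f"wavelength {w} nm not in dataset grid")
        band_idx.append(hit[0])

    rows = []
    for g in GROUPS:
        in_g = dataset.group == g
        row = indices_by_group[g].as_dict()
        if sod_by_group is not None:
            row["SOD"] = sod_by_group[g]
        else:
            row["SOD"] = float(np.nanmean(dataset.sod[in_g]))
        for w, j in zip(top_bands, band_idx):
            row[format(w, "g")] = float(dataset.spectra[in_g, j].mean())
        rows.append(row)
    summary = pd.DataFrame(rows, index=list(GROUPS))
    if summary.isna().any().any():
        raise ValueError("group summary has missing cells")
    return summary


def pearson_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation over the group rows.

    Constant columns have no defined correlation; they are flagged with
    a warning and their entries set to NaN (the diagonal stays 1).
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    values = summary.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant columns, correlation undefined: "
            f"{list(summary.columns[constant])}"
        )
    warnings.warn(
        f"Pearson coefficients over only n={len(summary)} group rows are "
        "descriptive; no significance is implied"
    )
    corr = summary.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def plot_heatmap(corr: pd.DataFrame, path=None, ax=None):
    """Annotated correlation heat map (indices, SOD, then wavelengths)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        size = 0.5 * len(corr.columns) + 2
        _, ax = plt.subplots(figsize=(size, size * 0.85))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr.index)), corr.index)
    for (i, j), v in np.ndenumerate(corr.to_numpy()):
        if np.isfinite(v):
            ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("bands, vigor indices and SOD (n = 5 groups)")
    if path is not None:
        ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
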