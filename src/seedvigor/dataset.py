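"""Per-seed spectral dataset container and its CSV dialect.

A :class:`SpectralDataset` holds one mean reflectance spectrum per seed
together with the phenotype annotations used downstream: the aging group
(A0 = unaged through A4 = 96 h accelerated aging), the binary viability
label from the germination test, and the measured superoxide-dismutase
(SOD) activity in U/g fresh weight.

The on-disk form is a flat CSV with columns
``seed_id, group, viable, sod`` followed by one reflectance column per
wavelength, named by its nm value (e.g. ``650.35``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("A0", "A1", "A2", "A3", "A4")

_META_COLS = ["seed_id", "group", "viable", "sod"]


@dataclass
class SpectralDataset:
    """Mean spectra for a set of seeds plus phenotype labels.

    Parameters
    ----------
    spectra : (n_seeds, n_bands) float array of reflectance.
    wavelengths : (n_bands,) strictly increasing nm grid.
    group : (n_seeds,) aging-group labels drawn from ``GROUPS``.
    viable : (n_seeds,) boolean viability labels (germ > 1.5 cm in 8 d).
    sod : (n_seeds,) SOD activity values, U/g FW (NaN where unmeasured).
    seed_id : (n_seeds,) integer identifiers; defaults to 0..n-1.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    group: np.ndarray
    viable: np.ndarray
    sod: np.ndarray
    seed_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.group = np.asarray(self.group)
        self.viable = np.asarray(self.viable, dtype=bool)
        self.sod = np.asarray(self.sod, dtype=float)
        if self.seed_id is None:
            self.seed_id = np.arange(len(self.spectra))
        self.seed_id = np.asarray(self.seed_id)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (seeds x bands)")
        n, b = self.spectra.shape
        if self.wavelengths.shape != (b,):
            raise ValueError("wavelength grid length must match band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("group", "viable", "sod", "seed_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match number of seeds")

    @property
    def n_seeds(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def select_seeds(self, idx) -> "SpectralDataset":
        """Row subset (copy) by boolean mask or index array."""
        idx = np.asarray(idx)
        return SpectralDataset(
            spectra=self.spectra[idx].copy(),
            wavelengths=self.wavelengths.copy(),
            group=self.group[idx].copy(),
            viable=self.viable[idx].copy(),
            sod=self.sod[idx].copy(),
            seed_id=self.seed_id[idx].copy(),
        )

    def select_bands(self, band_idx) -> "SpectralDataset":
        """Column subset (copy) by band index array; order follows ``band_idx``.

        The wavelength grid of the result must remain strictly increasing
        only when the caller keeps grid order; ranked-order subsets are
        produced via :func:`seedvigor.band_select.subset_to_ranking`, which
        re-sorts into grid order.
        """
        band_idx = np.asarray(band_idx)
        return replace(
            self,
            spectra=self.spectra[:, band_idx].copy(),
            wavelengths=self.wavelengths[band_idx].copy(),
        )

    def with_spectra(self, spectra: np.ndarray) -> "SpectralDataset":
        """Same annotations, new spectra matrix (e.g. after preprocessing)."""
        return replace(self, spectra=np.asarray(spectra, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "seed_id": self.seed_id,
            "group": self.group,
            "viable": self.viable.astype(int),
            "sod": self.sod,
        }
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.spectra, columns=[format(w, "g") for w in self.wavelengths]
        )
        return pd.concat([frame, spec.set_index(frame.index)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        frame = pd.read_csv(path)
        missing = [c for c in _META_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        wl_cols = [c for c in frame.columns if c not in _META_COLS]
        return cls(
            spectra=frame[wl_cols].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            group=frame["group"].to_numpy(),
            viable=frame["viable"].to_numpy(dtype=bool),
            sod=frame["sod"].to_numpy(dtype=float),
            seed_id=frame["seed_id"].to_numpy(),
        )
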