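"""Hyperspectral cube handling for push-broom reflectance imagery.

Covers the image-side plumbing of the pipeline: ENVI-style I/O,
conversion of raw counts to reflectance with dark/white reference
frames, threshold-based seed segmentation on the tray image, per-seed
mean spectra, and trimming of the noisy grid edges to the 400-1000 nm
working range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataset import SpectralDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Hypercube",
    "SeedMask",
    "black_white_correct",
    "segment_seeds",
    "mean_spectrum",
    "mean_spectra",
    "trim_bands",
    "read_envi",
    "write_envi",
]


@dataclass
class Hypercube:
    """A rows x cols x bands reflectance (or raw-count) array.

    ``kind`` records whether the cube has been through black/white
    correction ("corrected") or still holds camera counts ("raw").
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] < 2:
            raise ValueError("cube must have at least 2 bands")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError("wavelength grid length must equal band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if self.kind not in ("raw", "corrected"):
            raise ValueError("kind must be 'raw' or 'corrected'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, band_nm: float) -> int:
        """Index of the grid wavelength nearest to ``band_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - band_nm)))


@dataclass
class SeedMask:
    """Pixel set of one seed; ``ordinal`` is its row-major tray position."""

    pixels: np.ndarray  # (n_pix, 2) int array of (row, col), 0-based
    ordinal: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (row, col)")
        if self.pixels.shape[0] == 0:
            raise ValueError("seed mask must be non-empty")

    @property
    def area(self) -> int:
        return self.pixels.shape[0]

    def centroid(self) -> tuple[float, float]:
        cy, cx = self.pixels.mean(axis=0)
        return float(cy), float(cx)


def _broadcast_reference(ref: Hypercube, shape: tuple[int, int, int]) -> np.ndarray:
    """Allow row-replicated reference frames (a 1-row cube) to broadcast."""
    if ref.data.shape == shape:
        return ref.data
    if ref.data.shape == (1, shape[1], shape[2]):
        return np.broadcast_to(ref.data, shape)
    raise ValueError(
        f"reference shape {ref.data.shape} incompatible with sample {shape}"
    )


def black_white_correct(
    sample: Hypercube, dark: Hypercube, white: Hypercube
) -> Hypercube:
    """Reflectance from raw counts: R = (Sample - dark) / (White - dark).

    All three cubes must share the wavelength grid; dark and white may be
    single-row reference frames replicated along the scan axis. A zero
    white-minus-dark value anywhere is an acquisition fault and raises.
    """
    for ref in (dark, white):
        if not np.allclose(ref.wavelengths, sample.wavelengths):
            raise ValueError("wavelength grids of sample and references differ")
    d = _broadcast_reference(dark, sample.shape)
    w = _broadcast_reference(white, sample.shape)
    denom = w - d
    if np.any(denom == 0):
        raise ValueError("white - dark is zero at some pixel/band")
    refl = (sample.data - d) / denom
    return Hypercube(data=refl, wavelengths=sample.wavelengths.copy(), kind="corrected")


def segment_seeds(
    cube: Hypercube,
    band_nm: float = 800.0,
    threshold: float = 0.2,
    min_area: int = 10,
    expected: int | None = None,
) -> list[SeedMask]:
    """Threshold one NIR band and label connected components as seeds.

    Seeds are bright against the black tray cardboard, so a single
    global threshold at a NIR band separates them. Components are
    ordered row-major: centroids are clustered into tray rows (a new row
    starts when the centroid row coordinate jumps by more than the
    median component height) and sorted left-to-right within each.
    """
    plane = cube.data[:, :, cube.band_index(band_nm)]
    binary = plane > threshold
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    comps = []
    for lab in range(1, n_comp + 1):
        pix = np.argwhere(labels == lab)
        if pix.shape[0] >= min_area:
            comps.append(pix)
    if not comps:
        raise ValueError("no component found")
    if expected is not None and len(comps) != expected:
        logger.warning(
            "expected %d seeds but found %d components", expected, len(comps)
        )

    heights = [pix[:, 0].max() - pix[:, 0].min() + 1 for pix in comps]
    row_tol = float(np.median(heights))
    cents = np.array([pix.mean(axis=0) for pix in comps])
    order_by_y = np.argsort(cents[:, 0], kind="stable")
    rows: list[list[int]] = []
    last_y = None
    for idx in order_by_y:
        y = cents[idx, 0]
        if last_y is None or y - last_y > row_tol:
            rows.append([idx])
        else:
            rows[-1].append(idx)
        last_y = y
    ordered: list[int] = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda i: cents[i, 1]))
    return [SeedMask(pixels=comps[i], ordinal=k) for k, i in enumerate(ordered)]


def mean_spectrum(cube: Hypercube, mask: SeedMask) -> np.ndarray:
    """Arithmetic mean over the mask pixels at every band."""
    r, c = mask.pixels[:, 0], mask.pixels[:, 1]
    if r.max() >= cube.shape[0] or c.max() >= cube.shape[1] or r.min() < 0 or c.min() < 0:
        raise ValueError("mask extends outside cube bounds")
    return cube.data[r, c, :].mean(axis=0)


def mean_spectra(cube: Hypercube, masks: list[SeedMask]) -> np.ndarray:
    """Stack of per-mask mean spectra, (n_masks, n_bands)."""
    return np.stack([mean_spectrum(cube, m) for m in masks])


def trim_bands(
    dataset: SpectralDataset, lo_nm: float = 400.0, hi_nm: float = 1000.0
) -> SpectralDataset:
    """Drop the noisy grid edges, keeping wavelengths in [lo_nm, hi_nm].

    The camera's 384-400 nm and 1000-1034 nm extremes carry mostly
    sensor noise; the analysis retains 400-1000 nm. Idempotent.
    """
    keep = (dataset.wavelengths >= lo_nm) & (dataset.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError("wavelength grid does not overlap the retained range")
    return dataset.select_bands(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# ENVI-style I/O: plain-text .hdr plus raw binary (BSQ or BIL interleave)

_DTYPE_BY_ENVI = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_BY_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: Hypercube, path_base, dtype=np.float32) -> Path:
    """Write ``<base>.hdr`` + ``<base>.raw`` (BSQ, little-endian).

    Returns the header path.
    """
    base = Path(path_base)
    hdr_path = base.with_suffix(".hdr")
    raw_path = base.with_suffix(".raw")
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_BY_DTYPE:
        raise ValueError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.shape
    wl = ", ".join(format(w, ".10g") for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{seedvigor {cube.kind} reflectance cube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_BY_DTYPE[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header)
    # BSQ: band-sequential = (bands, lines, samples) on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0)).astype(
        dtype.newbyteorder("<")
    )
    bsq.tofile(raw_path)
    return hdr_path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key = key.strip().lower()
            buf = val.strip()
        else:
            buf += " " + line
        if buf.count("{") > buf.count("}"):
            continue  # multi-line brace value
        fields[key] = buf.strip().strip("{}").strip()
        key = None
    return fields


def read_envi(hdr_path) -> Hypercube:
    """Read an ENVI header + raw pair (BSQ or BIL, byte order 0)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPE_BY_ENVI[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])

    raw_path = None
    for suffix in (".raw", ".img", ".dat", ""):
        cand = hdr_path.with_suffix(suffix)
        if cand != hdr_path and cand.exists():
            raw_path = cand
            break
    if raw_path is None:
        raise FileNotFoundError(f"no raw file next to {hdr_path}")
    flat = np.fromfile(raw_path, dtype=np.dtype(dtype).newbyteorder("<"), offset=offset)
    if flat.size != rows * cols * bands:
        raise ValueError("raw file size does not match header dimensions")
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols)
        data = np.moveaxis(data, 0, 2)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols)
        data = np.moveaxis(data, 1, 2)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    return Hypercube(data=data.astype(float), wavelengths=wl, kind="corrected")
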