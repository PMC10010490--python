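"""Synthetic hyperspectral / phenotype data with the structure of an
accelerated-aging peanut seed-vigor study.

Five aging groups (A0 unaged .. A4 = 96 h at 40 degC / 90 % RH) are
emulated. The generative model for one seed in group ``g``:

* a standard-normal latent vigor deviate ``e`` drives everything that is
  seed-specific: viability is the indicator ``e > -probit(p_g)`` (so the
  group germination probability is exactly ``p_g``), absorption-feature
  depths shrink linearly in ``e``, and SOD activity rises linearly in
  ``e`` around the group mean;
* the clean spectrum is an upward-tilted group baseline (overall
  reflectance increases with aging as storage compounds degrade) minus
  Gaussian absorption dips at 450 / 550 / 920 / 970 nm (pigment, soluble
  sugar, protein and O-H overtone features) whose depths decrease with
  aging;
* measurement corruption is per-seed multiplicative scatter gain,
  per-seed additive offset, and per-band white noise.

Because viability and SOD are functions of the same latent that sets the
dip depths, spectra carry recoverable signal for both the classification
and the regression stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .dataset import GROUPS, SpectralDataset
from .hypercube import Hypercube, SeedMask
from .phenotype import GerminationRecord

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_spectra",
    "generate_cube",
    "generate_germination",
    "group_mean_curves",
    "save_simulation",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Group-indexed sequences run A0..A4. Reflectance units throughout;
    wavelengths in nm; SOD in U/g FW.
    """

    n_per_group: int = 80
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(384.0, 1034.0, 256)
    )
    #: broadband reflectance level per group, increasing with aging
    baseline_level_by_group: Sequence[float] = (0.38, 0.42, 0.46, 0.50, 0.54)
    #: additional reflectance gained linearly from the blue to the NIR end
    baseline_tilt: float = 0.20
    feature_centers: Sequence[float] = (450.0, 550.0, 920.0, 970.0)
    #: dip depth at each center for a depth multiplier of 1
    feature_base_depths: Sequence[float] = (0.08, 0.06, 0.06, 0.09)
    #: Gaussian sigma of each dip, nm
    feature_widths: Sequence[float] = (18.0, 20.0, 18.0, 22.0)
    #: group-mean depth multipliers, decreasing with aging
    feature_depths_by_group: Sequence[float] = (1.0, 0.85, 0.70, 0.55, 0.40)
    #: sd of the log multiplicative scatter gain (gain = exp(sd * z))
    scatter_sd: float = 0.05
    #: sd of the per-seed additive baseline offset
    offset_sd: float = 0.01
    #: sd of per-band white noise on a mean seed spectrum
    noise_sd: float = 0.004
    #: within-group spread of the latent vigor deviate fed to depths/SOD
    vigor_sd: float = 0.35
    #: per-feature depth-multiplier change per unit of (scaled) latent
    #: vigor; the NIR protein/O-H features (920/970 nm) respond strongly,
    #: the pigment/sugar features (450/550 nm) mostly track the group
    vigor_depth_coupling: Sequence[float] = (0.15, 0.15, 0.6, 0.6)
    #: germination probability per group (8-day germination rate)
    germ_prob_by_group: Sequence[float] = (0.9625, 0.85, 0.65, 0.3875, 0.225)
    sod_mean_by_group: Sequence[float] = (3.2, 2.7, 2.2, 1.7, 1.2)
    #: SOD change per unit of (scaled) latent vigor
    sod_slope: float = 0.5
    #: residual SOD sd after the latent coupling
    sod_sd: float = 0.08
    #: mean day of germination per group (later for older seed lots)
    germ_day_mean_by_group: Sequence[float] = (2.78, 3.24, 4.30, 5.74, 7.21)
    germ_day_sd: float = 1.0
    germ_max_day: int = 8
    #: group-mean seedling (root) mass after 8 d, g
    seedling_mass_by_group: Sequence[float] = (1.69, 1.77, 1.58, 1.57, 1.52)
    seedling_mass_cv: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        grid = self.wavelength_grid
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength_grid must be strictly increasing")
        for name in (
            "baseline_level_by_group",
            "feature_depths_by_group",
            "germ_prob_by_group",
            "sod_mean_by_group",
            "germ_day_mean_by_group",
            "seedling_mass_by_group",
        ):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (len(GROUPS),):
                raise ValueError(f"{name} must have one value per group")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} must be finite")
        probs = np.asarray(self.germ_prob_by_group, dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("germination probabilities must lie in [0, 1]")
        if np.any(np.asarray(self.baseline_level_by_group) < 0):
            raise ValueError("baselines must be non-negative")
        if np.any(np.asarray(self.feature_depths_by_group) < 0):
            raise ValueError("feature depths must be non-negative")
        n_feat = len(self.feature_centers)
        if not (len(self.feature_base_depths) == len(self.feature_widths)
                == len(self.vigor_depth_coupling) == n_feat):
            raise ValueError("feature center/depth/width/coupling lists must align")
        scalars = [
            self.baseline_tilt, self.scatter_sd, self.offset_sd, self.noise_sd,
            self.vigor_sd, self.sod_slope,
            self.sod_sd, self.germ_day_sd, self.seedling_mass_cv,
        ] + list(self.vigor_depth_coupling)
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("config scalars must be finite")
        if min(self.scatter_sd, self.offset_sd, self.noise_sd, self.vigor_sd,
               self.sod_sd, self.germ_day_sd, self.seedling_mass_cv) < 0:
            raise ValueError("spread parameters must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth for each generated seed (one row per seed)."""

    group: np.ndarray
    viable: np.ndarray
    sod: np.ndarray
    gain: np.ndarray
    offset: np.ndarray
    latent: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.group)
        for name in ("viable", "sod", "gain", "offset", "latent"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.gain <= 0):
            raise ValueError("scatter gains must be positive")

    def to_json(self, path) -> None:
        payload = {
            k: np.asarray(v).tolist() for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent streams per operation so e.g. germination draws do not
    # perturb the spectra for the same seed value
    return np.random.default_rng([stream, config.rng_seed])


def group_mean_curves(config: SimConfig) -> np.ndarray:
    """Noise-free clean spectrum of each aging group, (5, n_bands)."""
    wl = config.wavelength_grid
    ramp = (wl - wl[0]) / (wl[-1] - wl[0])
    curves = np.empty((len(GROUPS), wl.size))
    dips_unit = _unit_dips(config)
    for g in range(len(GROUPS)):
        base = config.baseline_level_by_group[g] + config.baseline_tilt * ramp
        curves[g] = base - config.feature_depths_by_group[g] * dips_unit
    return curves


def _feature_profiles(config: SimConfig) -> np.ndarray:
    """Per-feature Gaussian dip profiles, (n_features, n_bands), depth 1."""
    wl = config.wavelength_grid
    profiles = np.empty((len(config.feature_centers), wl.size))
    for i, (c, d, w) in enumerate(zip(
        config.feature_centers, config.feature_base_depths, config.feature_widths
    )):
        profiles[i] = d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return profiles


def _unit_dips(config: SimConfig) -> np.ndarray:
    """Summed Gaussian absorption dips for a depth multiplier of 1."""
    return _feature_profiles(config).sum(axis=0)


def _draw_seeds(config: SimConfig, group_idx: np.ndarray, rng: np.random.Generator):
    """Clean spectra and truth for seeds with the given group indices.

    Returns (clean_spectra, truth); measurement noise is added by the
    caller so the cube generator can re-noise per pixel instead.
    """
    n = group_idx.size
    wl = config.wavelength_grid
    ramp = (wl - wl[0]) / (wl[-1] - wl[0])
    profiles = _feature_profiles(config)  # (n_feat, n_bands)

    z = norm.ppf(np.asarray(config.germ_prob_by_group, dtype=float))
    e = rng.standard_normal(n)
    viable = e > -z[group_idx]
    u = config.vigor_sd * e  # centered latent vigor deviation

    coupling = np.asarray(config.vigor_depth_coupling, dtype=float)
    group_mult = np.asarray(config.feature_depths_by_group)[group_idx]
    # (n_seeds, n_feat) depth multipliers, one column per absorption feature
    depth_mult = np.clip(
        group_mult[:, None] + u[:, None] * coupling[None, :], 0.0, None
    )

    base = (
        np.asarray(config.baseline_level_by_group)[group_idx][:, None]
        + config.baseline_tilt * ramp[None, :]
    )
    clean = base - depth_mult @ profiles

    gain = np.exp(config.scatter_sd * rng.standard_normal(n))
    offset = config.offset_sd * rng.standard_normal(n)
    sod = (
        np.asarray(config.sod_mean_by_group)[group_idx]
        + config.sod_slope * u
        + config.sod_sd * rng.standard_normal(n)
    )
    truth = SyntheticTruth(
        group=np.asarray(GROUPS)[group_idx],
        viable=viable,
        sod=sod,
        gain=gain,
        offset=offset,
        latent=e,
    )
    return clean, truth


def generate_spectra(config: SimConfig) -> tuple[SpectralDataset, SyntheticTruth]:
    """Per-seed mean spectra for ``n_per_group`` seeds in each aging group."""
    config.validate()
    rng = _rng(config, 1)
    group_idx = np.repeat(np.arange(len(GROUPS)), config.n_per_group)
    clean, truth = _draw_seeds(config, group_idx, rng)
    noise = config.noise_sd * rng.standard_normal(clean.shape)
    spectra = truth.gain[:, None] * clean + truth.offset[:, None] + noise
    ds = SpectralDataset(
        spectra=spectra,
        wavelengths=config.wavelength_grid.copy(),
        group=truth.group.copy(),
        viable=truth.viable.copy(),
        sod=truth.sod.copy(),
    )
    return ds, truth


def generate_cube(
    config: SimConfig,
    layout: tuple[int, int] = (4, 5),
    n_seeds: int | None = None,
    cell_px: int = 16,
    seed_radius_px: tuple[float, float] = (4.5, 6.5),
    background_reflectance: float = 0.02,
) -> tuple[Hypercube, list[SeedMask], SyntheticTruth]:
    """Tray image: elliptical seeds on dark cardboard, row-major order.

    Each seed occupies one tray cell, so masks are disjoint by
    construction; a layout whose cells cannot contain the seed ellipses
    (or with fewer cells than seeds) is rejected.
    """
    config.validate()
    rows, cols = layout
    if n_seeds is None:
        n_seeds = rows * cols
    if n_seeds > rows * cols:
        raise ValueError(
            f"layout {rows}x{cols} cannot hold {n_seeds} seeds without overlap"
        )
    r_lo, r_hi = seed_radius_px
    if 2 * r_hi + 2 > cell_px:
        raise ValueError("seed radius too large for cell: seeds would overlap")

    rng = _rng(config, 2)
    group_idx = np.arange(n_seeds) % len(GROUPS)  # tray mixes the groups
    clean, truth = _draw_seeds(config, group_idx, rng)
    n_bands = config.wavelength_grid.size

    data = np.full(
        (rows * cell_px, cols * cell_px, n_bands), background_reflectance
    )
    data += config.noise_sd * rng.standard_normal(data.shape)

    masks: list[SeedMask] = []
    yy, xx = np.mgrid[0:rows * cell_px, 0:cols * cell_px]
    for i in range(n_seeds):
        r_cell, c_cell = divmod(i, cols)
        cy = r_cell * cell_px + cell_px / 2 + rng.uniform(-1.5, 1.5)
        cx = c_cell * cell_px + cell_px / 2 + rng.uniform(-1.5, 1.5)
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        pix = np.argwhere(inside)
        seed_spec = truth.gain[i] * clean[i] + truth.offset[i]
        data[inside] = seed_spec[None, :] + config.noise_sd * rng.standard_normal(
            (pix.shape[0], n_bands)
        )
        masks.append(SeedMask(pixels=pix, ordinal=i))

    cube = Hypercube(
        data=data, wavelengths=config.wavelength_grid.copy(), kind="corrected"
    )
    return cube, masks, truth


def generate_germination(
    config: SimConfig,
) -> dict[str, GerminationRecord]:
    """One germination-box record per aging group.

    Each of the ``n_per_group`` seeds germinates with its group
    probability; germination days follow a discretized normal around the
    group mean day, truncated to the 8-day test window. Seedling (root)
    mass is a lognormal draw around the group mean.
    """
    config.validate()
    rng = _rng(config, 3)
    records: dict[str, GerminationRecord] = {}
    max_day = config.germ_max_day
    for g, name in enumerate(GROUPS):
        m = config.n_per_group
        germinated = rng.random(m) < config.germ_prob_by_group[g]
        n_germ = int(germinated.sum())
        days = rng.normal(
            config.germ_day_mean_by_group[g], config.germ_day_sd, size=n_germ
        )
        days = np.clip(np.rint(days), 1, max_day).astype(int)
        counts = np.bincount(days, minlength=max_day + 1)[1:max_day + 1]
        cv = config.seedling_mass_cv
        sigma = math.sqrt(math.log(1.0 + cv**2))
        mu = math.log(config.seedling_mass_by_group[g]) - 0.5 * sigma**2
        mass = float(rng.lognormal(mu, sigma))
        records[name] = GerminationRecord(
            M=m, daily_counts=counts, S=mass
        )
    return records


def save_simulation(out_dir, dataset: SpectralDataset, truth: SyntheticTruth) -> None:
    """Write the per-seed spectra CSV and the JSON truth sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_csv(out / "spectra.csv")
    truth.to_json(out / "truth.json")
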