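"""Germination vigor indices and SOD-activity arithmetic.

The roll-paper germination test yields, per seed lot, the daily counts
of normally germinated seeds over an 8-day window plus the seedling
(root) mass after 8 days. Six standard indices summarize vigor:

* germination potential  GP  = m1 / M x 100   (m1 = germinated within 3 d)
* germination rate       GE  = m2 / M x 100   (m2 = germinated within 8 d)
* germination index      GI  = sum_t G_t / D_t
* mean germination time  MGT = sum_t G_t D_t / sum_t G_t  (days)
* vitality index         VI  = GI x S
* simple vitality index  SVI = GP x S  (GP as a fraction, see below)

with G_t the count germinating on day D_t and S the seedling mass. SVI
uses GP on the 0-1 scale: published SVI magnitudes (~0.3-1.6 for masses
near 1.5 g) are only consistent with the fraction convention.

Superoxide dismutase (SOD) activity from the nitroblue-tetrazolium
photoreduction assay, with one unit defined as 50 % inhibition:

    activity = [(A0 - Ab) - (As - Ab)] * VT / (1/2 * (A0 - Ab) * W * Vs)

in U/g fresh weight, where Ab/A0/As are the dark-control, light-control
and sample absorbances at 560 nm, VT the total extract volume (mL), Vs
the assayed volume (mL), and W the fresh sample mass (g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GerminationRecord",
    "VigorIndices",
    "SODAssay",
    "vigor_indices",
    "sod_activity",
]


@dataclass
class GerminationRecord:
    """Counts from one germination box.

    Either provide ``daily_counts`` (length ``max_day``, day 1 first),
    from which the 3-day and 8-day totals are derived, or only the
    totals ``m1``/``m2`` for records transcribed from summary tables.
    """

    M: int
    daily_counts: np.ndarray | None = None
    m1: int | None = None
    m2: int | None = None
    S: float | None = None  # seedling (root) mass after the test window, g
    early_window: int = 3  # days counted toward germination potential

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be positive")
        if self.daily_counts is not None:
            self.daily_counts = np.asarray(self.daily_counts, dtype=int)
            if self.daily_counts.ndim != 1:
                raise ValueError("daily_counts must be 1-D")
            if np.any(self.daily_counts < 0):
                raise ValueError("daily counts must be non-negative")
            total = int(self.daily_counts.sum())
            if self.m2 is not None and self.m2 != total:
                raise ValueError("m2 inconsistent with daily counts")
            self.m2 = total
            early = int(self.daily_counts[: self.early_window].sum())
            if self.m1 is not None and self.m1 != early:
                raise ValueError("m1 inconsistent with daily counts")
            self.m1 = early
        if self.m2 is None:
            raise ValueError("either daily_counts or m2 is required")
        if self.m1 is not None and self.m1 > self.m2:
            raise ValueError("m1 cannot exceed m2")
        if self.m2 > self.M:
            raise ValueError("germinated count cannot exceed seeds tested")

    @property
    def days(self) -> np.ndarray:
        """1-based day numbers matching ``daily_counts``."""
        if self.daily_counts is None:
            raise ValueError("record has no daily counts")
        return np.arange(1, self.daily_counts.size + 1)


@dataclass
class VigorIndices:
    """The six indices; entries are NaN where the record lacks the inputs."""

    gp: float
    ge: float
    gi: float
    mgt: float
    vi: float
    svi: float
    mgt_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "GP": self.gp, "GE": self.ge, "GI": self.gi,
            "MGT": self.mgt, "VI": self.vi, "SVI": self.svi,
        }


def vigor_indices(record: GerminationRecord) -> VigorIndices:
    """All six vigor indices from one germination record.

    GP/GE are percentages; MGT is flagged undefined (NaN) when nothing
    germinated. Indices needing daily counts or seedling mass are NaN
    when the record holds only totals.
    """
    ge = 100.0 * record.m2 / record.M
    gp = 100.0 * record.m1 / record.M if record.m1 is not None else math.nan

    if record.daily_counts is not None:
        gt = record.daily_counts.astype(float)
        dt = record.days.astype(float)
        gi = float(np.sum(gt / dt))
        if record.m2 > 0:
            mgt = float(np.sum(gt * dt) / np.sum(gt))
            mgt_defined = True
        else:
            mgt = math.nan
            mgt_defined = False
    else:
        gi = math.nan
        mgt = math.nan
        mgt_defined = record.m2 > 0

    if record.S is not None and not math.isnan(gi):
        vi = gi * record.S
    else:
        vi = math.nan
    if record.S is not None and not math.isnan(gp):
        svi = (gp / 100.0) * record.S  # GP enters as a fraction
    else:
        svi = math.nan
    return VigorIndices(gp=gp, ge=ge, gi=gi, mgt=mgt, vi=vi, svi=svi,
                        mgt_defined=mgt_defined)


@dataclass
class SODAssay:
    """Absorbances and volumes of one NBT photoreduction assay."""

    Ab: float  # dark-control absorbance
    A0: float  # light-control absorbance
    As: float  # sample absorbance
    VT: float  # total enzyme-extract volume, mL
    Vs: float  # volume assayed, mL
    W: float   # fresh sample weight, g

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.Ab, self.A0, self.As,
                                       self.VT, self.Vs, self.W))):
            raise ValueError("assay values must be finite")
        if self.A0 <= self.Ab:
            raise ValueError("light control A0 must exceed dark control Ab")
        if not (0 < self.Vs <= self.VT):
            raise ValueError("need 0 < Vs <= VT")
        if self.W <= 0:
            raise ValueError("fresh weight must be positive")


def sod_activity(assay: SODAssay) -> float:
    """SOD activity in U/g FW; one unit = 50 % NBT-reduction inhibition."""
    inhibition = (assay.A0 - assay.Ab) - (assay.As - assay.Ab)
    half_control = 0.5 * (assay.A0 - assay.Ab)
    return inhibition * assay.VT / (half_control * assay.W * assay.Vs)
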