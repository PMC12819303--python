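"""Forage feeding-value indices from fiber fractions.

Five standard indices are derived from the two measured detergent-fiber
fractions of forage dry matter (DM): neutral detergent fiber (NDF) and acid
detergent fiber (ADF, a chemical subset of NDF).

    DMI (% of body weight) = 120 / NDF
    DDM (% DM)             = 88.9 - 0.779 * ADF
    TDN (% DM)             = 82.38 - 0.7515 * ADF
    RFV (unitless)         = DMI * DDM / 1.29
    RFQ (unitless)         = DMI * TDN / 1.23

DMI predicts voluntary dry-matter intake, DDM/TDN digestibility; RFV and
RFQ combine intake and digestibility into composite quality indices (an
average-quality full-bloom alfalfa hay scores ~100).  All five decrease as
either fiber fraction rises.  The linear DDM/TDN approximations can go
non-positive at extreme ADF; such values are passed through with a warning
rather than floored.

Indices are computed per biological replicate (plot), never on cell means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "FiberMeasurement",
    "FeedingValues",
    "dmi_from_ndf",
    "ddm_from_adf",
    "tdn_from_adf",
    "compute_feeding_values",
    "add_feeding_values",
    "FEEDING_INDEX_COLUMNS",
]

logger = logging.getLogger(__name__)

FEEDING_INDEX_COLUMNS = ("DMI", "DDM", "TDN", "RFV", "RFQ")


@dataclass(frozen=True)
class FiberMeasurement:
    """ADF and NDF, each as a percentage of dry matter, with 0 <= ADF <= NDF <= 100."""

    adf: float
    ndf: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.adf) or not np.isfinite(self.ndf):
            raise ValidationError("adf/ndf must be finite")
        if not 0 < self.ndf <= 100:
            raise ValidationError(f"ndf must be in (0, 100], got {self.ndf}")
        if self.adf < 0:
            raise ValidationError(f"adf must be >= 0, got {self.adf}")
        if self.adf > self.ndf:
            raise ValidationError(
                f"adf ({self.adf}) exceeds ndf ({self.ndf}); ADF is a subset of NDF"
            )


@dataclass(frozen=True)
class FeedingValues:
    """The five derived indices for one sample."""

    dmi: float
    ddm: float
    tdn: float
    rfv: float
    rfq: float


def dmi_from_ndf(ndf):
    """Dry matter intake, % of body weight: 120/NDF."""
    ndf = np.asarray(ndf, dtype=float)
    if np.any(ndf <= 0):
        raise DomainError("ndf must be > 0 for DMI = 120/NDF")
    out = 120.0 / ndf
    return float(out) if out.ndim == 0 else out


def ddm_from_adf(adf):
    """Digestible dry matter, % DM: 88.9 - 0.779*ADF."""
    adf = np.asarray(adf, dtype=float)
    if np.any(adf < 0):
        raise DomainError("adf must be >= 0")
    out = 88.9 - 0.779 * adf
    return float(out) if out.ndim == 0 else out


def tdn_from_adf(adf):
    """Total digestible nutrients, % DM: 82.38 - 0.7515*ADF."""
    adf = np.asarray(adf, dtype=float)
    if np.any(adf < 0):
        raise DomainError("adf must be >= 0")
    out = 82.38 - 0.7515 * adf
    return float(out) if out.ndim == 0 else out


def compute_feeding_values(m: FiberMeasurement) -> FeedingValues:
    """All five indices for one ADF/NDF measurement."""
    dmi = dmi_from_ndf(m.ndf)
    ddm = ddm_from_adf(m.adf)
    tdn = tdn_from_adf(m.adf)
    if ddm <= 0 or tdn <= 0:
        logger.warning(
            "non-positive digestibility (DDM=%.3f, TDN=%.3f) at ADF=%.3f; "
            "linear approximation out of range, value passed through",
            ddm, tdn, m.adf,
        )
    return FeedingValues(dmi=dmi, ddm=ddm, tdn=tdn, rfv=dmi * ddm / 1.29, rfq=dmi * tdn / 1.23)


def add_feeding_values(
    df: pd.DataFrame, adf_col: str = "ADF", ndf_col: str = "NDF", overwrite: bool = False
) -> pd.DataFrame:
    """Append DMI, DDM, TDN, RFV, RFQ columns to a plot-level trait table.

    Vectorized over rows; identical to applying :func:`compute_feeding_values`
    row by row.  Returns a copy.
    """
    for col in (adf_col, ndf_col):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found in table")
    clash = [c for c in FEEDING_INDEX_COLUMNS if c in df.columns]
    if clash and not overwrite:
        raise ValidationError(f"feeding-value column(s) {clash} already present")
    adf = df[adf_col].to_numpy(dtype=float)
    ndf = df[ndf_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(adf)) or np.any(~np.isfinite(ndf)):
        raise ValidationError("ADF/NDF contain non-finite values")
    if np.any(adf > ndf):
        raise ValidationError("ADF exceeds NDF in at least one row")
    if np.any(adf < 0):
        raise ValidationError("negative ADF value(s)")
    if np.any(ndf <= 0):
        raise ValidationError("non-positive NDF value(s)")
    out = df.copy()
    out["DMI"] = dmi_from_ndf(ndf)
    out["DDM"] = ddm_from_adf(adf)
    out["TDN"] = tdn_from_adf(adf)
    if np.any(out["DDM"].to_numpy() <= 0) or np.any(out["TDN"].to_numpy() <= 0):
        logger.warning("non-positive DDM/TDN in table; linear approximation out of range")
    out["RFV"] = out["DMI"] * out["DDM"] / 1.29
    out["RFQ"] = out["DMI"] * out["TDN"] / 1.23
    return out
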