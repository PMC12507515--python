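"""Gel densitometry: dye-bias correction of band intensities.

Intercalating gel stains such as GelRed bind supercoiled, nicked and linear
plasmid topologies with different efficiency, so raw band intensities
under- or over-report each fraction.  A calibration gel with a dilution
series of equal parts of the three topologies yields per-topology response
slopes; multiplicative correction factors derived from those slopes
equalize corrected signal at equal DNA mass.  Corrected intensities are
then summed per lane and converted to topology percentages, the input of
the cleavage-kinetics fit.

Factor normalization convention: only factor *ratios* affect percentages
(they are invariant to a common scale), so the overall scale is a
convention.  Here ``factor_i = mean(slope) / slope_i``, which maps the
calibration slopes (nicked, linear, supercoiled) measured for GelRed to
factors matching the magnitudes 0.797, 0.855, 1.74 used in this assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TOPOLOGIES",
    "CorrectionFactors",
    "estimate_correction_factors",
    "correct_and_normalize",
    "read_band_table",
    "read_dilution_table",
]

#: Band order used throughout tabular interfaces.
TOPOLOGIES = ("nicked", "linear", "supercoiled")

BAND_COLUMNS = ["I_nicked", "I_linear", "I_supercoiled"]


@dataclass(frozen=True)
class CorrectionFactors:
    """Per-topology multiplicative correction factors (dimensionless)."""

    f_nicked: float
    f_linear: float
    f_supercoiled: float
    r_squared: tuple | None = None  # per-topology calibration fit quality

    def __post_init__(self) -> None:
        for name in ("f_nicked", "f_linear", "f_supercoiled"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_nicked, self.f_linear, self.f_supercoiled])


#: Correction factors determined for GelRed-stained pUC19 topologies
#: (nicked, linear, supercoiled).
GELRED_PUC19 = CorrectionFactors(0.797, 0.855, 1.74)


def estimate_correction_factors(table: pd.DataFrame) -> CorrectionFactors:
    """Estimate correction factors from a calibration dilution series.

    ``table`` has columns ``lane, amount, I_nicked, I_linear,
    I_supercoiled``, each lane loading equal amounts of all three
    topologies.  For each topology the response slope of intensity vs
    amount is fit by least squares through the origin (zero DNA gives zero
    signal); ``factor_i = mean(slope)/slope_i``.  The per-topology
    uncentered R-squared of the calibration fit is attached to the result.
    """
    _require_columns(table, ["amount"] + BAND_COLUMNS, "dilution table")
    amounts = table["amount"].to_numpy(float)
    if np.unique(amounts).size < 2:
        raise ValueError("dilution series needs at least 2 distinct amounts")
    if np.any(amounts <= 0):
        raise ValueError("amounts must be strictly positive")
    slopes = np.empty(3)
    r2 = np.empty(3)
    for i, col in enumerate(BAND_COLUMNS):
        y = table[col].to_numpy(float)
        # least-squares slope through the origin
        slopes[i] = float(amounts @ y / (amounts @ amounts))
        resid = y - slopes[i] * amounts
        ss_tot = float(y @ y)
        r2[i] = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
        if slopes[i] <= 0:
            raise ValueError(
                f"non-positive response slope for topology "
                f"{TOPOLOGIES[i]!r}: {slopes[i]:g}"
            )
    factors = slopes.mean() / slopes
    return CorrectionFactors(*factors, r_squared=tuple(r2))


def correct_and_normalize(
    bands: pd.DataFrame, factors: CorrectionFactors
) -> pd.DataFrame:
    """Convert raw band intensities into topology percentages.

    ``bands`` has columns ``replicate, time_s, I_nicked, I_linear,
    I_supercoiled``.  Each intensity is multiplied by its topology's
    factor; corrected intensities are summed per row and percentages
    computed from the sum.  Rows with zero total corrected signal are
    dropped with a warning.  Returns a time-course table with columns
    ``replicate, time_s, pct_supercoiled, pct_nicked, pct_linear`` in the
    original row order.
    """
    _require_columns(bands, ["replicate", "time_s"] + BAND_COLUMNS, "band table")
    raw = bands[BAND_COLUMNS].to_numpy(float)
    if np.any(raw < 0):
        raise ValueError("band intensities must be >= 0")
    corrected = raw * factors.as_array()
    totals = corrected.sum(axis=1)
    dead = totals <= 0
    if dead.any():
        lanes = bands.index[dead].tolist()
        warnings.warn(
            f"dropping {int(dead.sum())} lane(s) with zero corrected signal "
            f"(rows {lanes})",
            stacklevel=2,
        )
        bands = bands.loc[~dead]
        corrected = corrected[~dead]
        totals = totals[~dead]
    if totals.size == 0:
        raise ValueError("no lanes with nonzero corrected signal")
    pct = 100.0 * corrected / totals[:, None]
    out = pd.DataFrame(
        {
            "replicate": bands["replicate"].to_numpy(),
            "time_s": bands["time_s"].to_numpy(float),
            "pct_supercoiled": pct[:, 2],
            "pct_nicked": pct[:, 0],
            "pct_linear": pct[:, 1],
        }
    )
    return out


def read_band_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["replicate", "time_s"] + BAND_COLUMNS, str(path))
    return df


def read_dilution_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["lane", "amount"] + BAND_COLUMNS, str(path))
    return df


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns {missing}")
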