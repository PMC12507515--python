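"""Fluorescence assay curves: trans-cleavage rates and melt-curve Tm.

Target-activated Cas12a degrades single-stranded DNA indiscriminately
("trans" cleavage), read out as dequenching of a fluorophore–quencher
reporter.  Under reporter excess the early signal rise is linear, so the
pseudo-first-order trans rate is the ordinary-least-squares slope over the
first 300 s of the curve.

Thermal-shift (differential scanning fluorimetry) melt curves report
protein unfolding as a fluorescence peak on a 1 °C grid from 25 to 99 °C;
the melting temperature Tm is the temperature of that peak.  A curve with
no interior peak of sufficient prominence — e.g. a strictly rising trace
from an already-unfolded protein — yields an explicit no-peak outcome
rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransRate",
    "MeltResult",
    "NO_PEAK",
    "initial_rate",
    "background_subtract",
    "melting_temperature",
]

#: Default regression window for pseudo-first-order trans rates (seconds).
DEFAULT_WINDOW_S = 300.0

#: Minimum prominence of the melt peak over both curve endpoints, as a
#: fraction of the curve's dynamic range.  Operationalizes "no detectable
#: fluorescence peak" for degenerate curves; affine-invariant.
PEAK_PROMINENCE = 0.05


@dataclass(frozen=True)
class TransRate:
    """OLS fit of the early linear rise of a trans-cleavage curve."""

    slope: float  # RFU per second
    intercept: float  # RFU
    window_s: float
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class MeltResult:
    """Tm call from a melt curve; ``tm_C`` is None for a no-peak outcome."""

    tm_C: float | None
    peak_fluorescence: float | None = None

    @property
    def has_peak(self) -> bool:
        return self.tm_C is not None


NO_PEAK = MeltResult(tm_C=None)


def _curve_arrays(curve: pd.DataFrame, xcol: str, ycol: str):
    missing = {xcol, ycol} - set(curve.columns)
    if missing:
        raise ValueError(f"curve is missing columns {sorted(missing)}")
    x = curve[xcol].to_numpy(float)
    y = curve[ycol].to_numpy(float)
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{xcol} must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{ycol} contains non-finite values")
    return x, y


def initial_rate(curve: pd.DataFrame, window_s: float = DEFAULT_WINDOW_S) -> TransRate:
    """Pseudo-first-order trans rate: OLS slope over points with t <= window.

    ``curve`` has columns ``time_s`` and ``rfu``.  The window boundary is
    inclusive.  Negative slopes are reported as-is with a warning (no
    clamping), since a falling early signal is diagnostic of a problem
    with the assay rather than a rate of zero.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    t, y = _curve_arrays(curve, "time_s", "rfu")
    mask = t <= window_s
    if int(mask.sum()) < 3:
        raise ValueError(
            f"need >= 3 points with t <= {window_s:g}s, got {int(mask.sum())}"
        )
    res = stats.linregress(t[mask], y[mask])
    if res.slope < 0:
        warnings.warn(
            f"negative initial rate ({res.slope:g} RFU/s); reported as-is",
            stacklevel=2,
        )
    return TransRate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        window_s=float(window_s),
        n_points=int(mask.sum()),
        r_squared=float(res.rvalue**2),
    )


def background_subtract(curve: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Pointwise subtraction of a no-enzyme control curve.

    Both curves must share an identical time grid.  The returned curve
    carries a ``condition`` label annotated with the subtraction.
    """
    t, y = _curve_arrays(curve, "time_s", "rfu")
    tc, yc = _curve_arrays(control, "time_s", "rfu")
    if t.shape != tc.shape or not np.allclose(t, tc, rtol=0, atol=1e-9):
        raise ValueError("curve and control time grids do not match")
    out = pd.DataFrame({"time_s": t, "rfu": y - yc})
    label = curve["condition"].iloc[0] if "condition" in curve.columns else "curve"
    out["condition"] = f"{label} - background"
    return out


def melting_temperature(curve: pd.DataFrame) -> MeltResult:
    """Tm = temperature of the global fluorescence maximum, if it is a peak.

    ``curve`` has columns ``temperature_C`` and ``fluorescence``.  The
    maximum must be interior (not the first or last grid point) and exceed
    both endpoint values by at least 5% of the curve's dynamic range;
    otherwise the no-peak outcome is returned.  Equal maxima break to the
    lowest temperature.  The call is invariant to positive affine
    transforms of the fluorescence values.
    """
    temp, fl = _curve_arrays(curve, "temperature_C", "fluorescence")
    if temp.size < 3:
        raise ValueError("melt curve needs at least 3 points")
    i = int(np.argmax(fl))  # first occurrence = lowest temperature on a grid
    if i == 0 or i == temp.size - 1:
        return NO_PEAK
    span = float(fl.max() - fl.min())
    if span <= 0:
        return NO_PEAK
    prominence = (fl[i] - max(fl[0], fl[-1])) / span
    if prominence < PEAK_PROMINENCE:
        return NO_PEAK
    return MeltResult(tm_C=float(temp[i]), peak_fluorescence=float(fl[i]))
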