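"""Seasonal-climate predictors by first-order harmonic regression.

Each cell's 12-month climatology of a variable y_m is summarised by the
least-squares fit of

    y_m = a0 + a1*cos(2*pi*m/12) + b1*sin(2*pi*m/12),    m = 1..12

a0 is the annual mean level, (a1, b1) encode the annual cycle's amplitude
sqrt(a1^2 + b1^2) and phase.  Over a full cycle the basis is orthogonal, so
the coefficients have the closed form a0 = mean(y), a1 = (1/6) sum y_m c_m,
b1 = (1/6) sum y_m s_m.  Three coefficients for each of tmax, tmin and vpd
give the nine predictors used by all downstream modelling.
"""

from __future__ import annotations

import numpy as np

from .grids import CLIMATE_VARIABLES, ClimateGrid, PredictorStack

#: Month positions used in the harmonic basis (integers 1..12).
MONTHS = np.arange(1, 13)
_COS = np.cos(2 * np.pi * MONTHS / 12)
_SIN = np.sin(2 * np.pi * MONTHS / 12)


def monthly_climatology(series: np.ndarray) -> np.ndarray:
    """Average per-month-per-year values into a 12-month climatology.

    Parameters
    ----------
    series
        Array of shape (n_years, 12), or a mapping-free 2-D array where
        NaN marks a missing month in a given year.

    Returns
    -------
    12-vector of arithmetic monthly means.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != 12:
        raise ValueError("series must have 12 monthly columns")
    counts = np.sum(~np.isnan(arr), axis=0)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValueError(f"month {missing} has no observations")
    return np.nanmean(arr, axis=0)


def fit_harmonics(monthly: np.ndarray) -> tuple[float, float, float]:
    """Least-squares first-harmonic coefficients (a0, a1, b1) of a 12-month series.

    Orthogonality of the basis over months 1..12 makes the projection exact:
    no normal-equations solve is required.
    """
    y = np.asarray(monthly, dtype=float)
    if y.shape != (12,):
        raise ValueError("expected exactly 12 monthly values")
    if not np.all(np.isfinite(y)):
        raise ValueError("monthly values must be finite")
    a0 = float(np.mean(y))
    a1 = float(y @ _COS / 6.0)
    b1 = float(y @ _SIN / 6.0)
    return a0, a1, b1


def harmonic_series(a0: float, a1: float, b1: float) -> np.ndarray:
    """Evaluate the first-order harmonic model at months 1..12."""
    return a0 + a1 * _COS + b1 * _SIN


def build_predictors(grid: ClimateGrid) -> PredictorStack:
    """Fit harmonics cell-wise for all three variables -> 9-layer stack.

    Cells with any missing (NaN) monthly value are masked in all nine layers.
    """
    geom = grid.geometry
    layers = np.empty((9, geom.n_rows, geom.n_cols))
    mask = np.zeros((geom.n_rows, geom.n_cols), dtype=bool)
    for v, var in enumerate(CLIMATE_VARIABLES):
        values = grid.values[var]  # (12, nr, nc)
        bad = np.any(~np.isfinite(values), axis=0)
        mask |= bad
        flat = values.reshape(12, -1)
        a0 = flat.mean(axis=0)
        a1 = _COS @ flat / 6.0
        b1 = _SIN @ flat / 6.0
        for c, coef in enumerate((a0, a1, b1)):
            layers[3 * v + c] = coef.reshape(geom.n_rows, geom.n_cols)
    layers[:, mask] = np.nan
    return PredictorStack(geometry=geom, layers=layers, mask=mask)
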