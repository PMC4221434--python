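"""Removal of fish-length effects from wavelet shape coefficients.

Two stages:

1. :func:`ancova_screen` — per coefficient, fit
   ``coeff ~ group + length + group:length`` and exclude coefficients whose
   group x length interaction is significant: those cannot be adjusted by a
   common linear relationship on fish length.
2. :func:`allometric_scale` — rescale each retained coefficient to a common
   reference length with the regression-based allometric correction
   ``value * (L0 / length) ** b``, where b is the allometric exponent
   estimated on log scale. Coefficients whose values span zero (log
   undefined) fall back to a linear residual adjustment and are flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ancova_screen", "allometric_scale"]


def _rss(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y on design Z."""
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    R = Y - Z @ beta
    return np.sum(R**2, axis=0)


def ancova_screen(
    C,
    length,
    group,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANCOVA screen of coefficients against fish length by group.

    For every coefficient an F-test compares the parallel-slopes model
    (group + length) with the full interaction model; a significant
    interaction (p < alpha) marks the coefficient as not linearly
    adjustable and excludes it.

    Returns
    -------
    report : DataFrame
        One row per coefficient: interaction p, length-slope p, excluded
        flag. When some group has (near-)constant lengths the interaction
        is not estimable; tests are NA and the coefficient is retained
        with a warning.
    retained : DataFrame
        The input matrix restricted to retained columns, order preserved.
    """
    C = pd.DataFrame(C)
    y = C.to_numpy(dtype=float)
    length = np.asarray(length, dtype=float)
    group = np.asarray(group)
    levels, codes = np.unique(group, return_inverse=True)
    n, p = y.shape
    for lev in levels:
        if (group == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 fish")

    estimable = all(len(np.unique(length[group == lev])) > 1 for lev in levels)
    G = np.zeros((n, len(levels)))
    G[np.arange(n), codes] = 1.0
    Lc = length - length.mean()
    Z_red = np.column_stack([G, Lc])  # group intercepts + common slope
    Z_full = np.column_stack([G, G * Lc[:, None]])  # per-group slopes
    Z_null = G  # intercepts only (for the length-slope test)

    if estimable:
        rss_red = _rss(y, Z_red)
        rss_full = _rss(y, Z_full)
        df_int = len(levels) - 1
        df_resid = n - Z_full.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_int = ((rss_red - rss_full) / df_int) / (rss_full / df_resid)
        p_int = stats.f.sf(f_int, df_int, df_resid)
        rss_null = _rss(y, Z_null)
        df_len_resid = n - Z_red.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_len = (rss_null - rss_red) / (rss_red / df_len_resid)
        p_len = stats.f.sf(f_len, 1, df_len_resid)
        excluded = p_int < alpha
    else:
        warnings.warn(
            "length is constant within at least one group; interaction not "
            "estimable — all coefficients retained with NA tests",
            stacklevel=2,
        )
        p_int = np.full(p, np.nan)
        p_len = np.full(p, np.nan)
        excluded = np.zeros(p, dtype=bool)

    report = pd.DataFrame(
        {
            "coefficient": C.columns,
            "p_interaction": p_int,
            "p_length": p_len,
            "excluded": excluded,
        }
    )
    retained = C.loc[:, ~excluded]
    return report, retained


def allometric_scale(
    C,
    length,
    L0: float | np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale coefficients to a common reference fish length.

    Per coefficient j the allometric exponent ``b_j`` is the slope of
    ``log|value|`` on ``log(length)``; the corrected value is
    ``value * (L0 / length) ** b_j`` (signs are preserved). After scaling,
    the linear relation of each coefficient with length is removed in
    expectation. Coefficients with values of mixed sign (or zeros) use the
    linear fallback ``value - slope * (length - L0)`` instead and are
    flagged ``method="linear"``.

    ``L0`` defaults to the grand mean length; passing the length vector
    itself makes the transform the identity.
    """
    C = pd.DataFrame(C)
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("lengths must be positive")
    if L0 is None:
        L0 = float(length.mean())
    L0 = np.asarray(L0, dtype=float)

    scaled = {}
    info_rows = []
    logL = np.log(length)
    for col in C.columns:
        v = C[col].to_numpy(dtype=float)
        same_sign = np.all(v > 0) or np.all(v < 0)
        if same_sign:
            b = stats.linregress(logL, np.log(np.abs(v))).slope
            scaled[col] = v * (L0 / length) ** b
            info_rows.append({"coefficient": col, "b": b, "method": "allometric"})
        else:
            slope = stats.linregress(length, v).slope
            scaled[col] = v - slope * (length - L0)
            info_rows.append({"coefficient": col, "b": np.nan, "method": "linear"})
    return pd.DataFrame(scaled, index=C.index), pd.DataFrame(info_rows)
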