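"""Per-animal quadratic breeding-value trajectories and extrapolation.

Breeding values estimated independently at each recorded time point are
regressed, animal by animal, on time and time squared by ordinary least
squares; the fitted polynomial is then evaluated at an unobserved time
(default 600) to predict each animal's future breeding value.

Time is centred and scaled internally, ``t' = (t - mean) / scale``, because
raw ``t^2`` values up to ~2.8e5 make the design ill-conditioned; coefficients
are mapped back to the raw-time basis for reporting, so the returned
``beta0/beta1/beta2`` satisfy ``bv(t) = beta0 + beta1 t + beta2 t^2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

COEF_COLUMNS = ["beta0", "beta1", "beta2"]


def fit_quadratic(ebv: pd.DataFrame) -> pd.DataFrame:
    """OLS quadratic-in-time coefficients per animal.

    Parameters
    ----------
    ebv
        Wide table: index = animal id, one column per time point (numeric
        column labels).  At least 3 distinct time points are required.

    Returns
    -------
    DataFrame indexed by animal id with columns ``beta0, beta1, beta2`` in the
    raw-time basis.
    """
    times = np.asarray([float(t) for t in ebv.columns])
    if len(np.unique(times)) != len(times):
        raise DataError("duplicated time point in EBV table")
    if len(times) < 3:
        raise DataError(
            f"need >= 3 distinct time points for a quadratic, got {len(times)}"
        )
    m = times.mean()
    s = (times.max() - times.min()) / 2.0 or 1.0
    ts = (times - m) / s
    X = np.column_stack([np.ones_like(ts), ts, ts * ts])
    Y = ebv.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DataError("EBV table contains missing values")
    coef_scaled, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    c0, c1, c2 = coef_scaled
    # map beta(t') back to the raw basis: t' = (t - m)/s
    b2 = c2 / s**2
    b1 = c1 / s - 2.0 * c2 * m / s**2
    b0 = c0 - c1 * m / s + c2 * (m / s) ** 2
    return pd.DataFrame(
        {"beta0": b0, "beta1": b1, "beta2": b2}, index=ebv.index
    )


def extrapolate(coeffs: pd.DataFrame, t_star: float = 600.0) -> pd.Series:
    """Evaluate each animal's quadratic at ``t_star``."""
    missing = set(COEF_COLUMNS) - set(coeffs.columns)
    if missing:
        raise DataError(f"coefficient table lacks columns {sorted(missing)}")
    pred = (
        coeffs["beta0"]
        + coeffs["beta1"] * t_star
        + coeffs["beta2"] * t_star**2
    )
    pred.name = f"pred_bv_{t_star:g}"
    return pred
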