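"""Decoder-behavior linkage across sessions.

Relates per-rat, per-session population decoder accuracy to behavioral
accuracy: pooled OLS regressions, within-session slopes across rats, and a
Fisher-Z comparison of early- versus late-epoch session correlations (the
early-positive / late-negative reversal is the signature of an old rule
whose faithful neural representation predicts its behavioral suppression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def decoder_behavior_regression(x, y) -> RegressionResult:
    """OLS of behavioral accuracy on decoder accuracy across rat/session points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x.std(), 0):
        raise ValueError("zero variance in the predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), p=float(model.pvalues[1]), n=len(x),
    )


def per_session_slopes(summaries: pd.DataFrame, x: str, y: str,
                       session_col: str = "session_id") -> pd.DataFrame:
    """Within-session OLS slope and Pearson r across rats.

    Sessions with fewer than 3 points are skipped.  Returns a frame with
    session, slope, r, and n columns.
    """
    rows = []
    for sid, grp in summaries.groupby(session_col, sort=False):
        if len(grp) < 3:
            continue
        res = stats.linregress(grp[x].to_numpy(float), grp[y].to_numpy(float))
        rows.append(dict(session=sid, slope=res.slope, r=res.rvalue, n=len(grp)))
    return pd.DataFrame(rows, columns=["session", "slope", "r", "n"])


def _weighted_z(r_set, n_set):
    """(n-3)-weighted mean Fisher z and its standard error."""
    r = np.asarray(r_set, dtype=float)
    n = np.asarray(n_set, dtype=float)
    if np.any(n <= 3):
        raise ValueError("every correlation needs n > 3")
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| = 1 clamped for the Fisher transform")
        r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    w = n - 3.0
    zbar = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return zbar, se


def fisher_z_compare(r_set_1, n_1, r_set_2, n_2):
    """Two-tailed Fisher-Z comparison of two sets of correlations.

    Each epoch's r's are z-transformed and aggregated with (n-3) weights;
    the z-statistic is (zbar1 - zbar2) / sqrt(SE1^2 + SE2^2) against a
    standard normal.  Returns (z, p).
    """
    n_1 = np.broadcast_to(np.asarray(n_1), np.shape(r_set_1))
    n_2 = np.broadcast_to(np.asarray(n_2), np.shape(r_set_2))
    z1, se1 = _weighted_z(r_set_1, n_1)
    z2, se2 = _weighted_z(r_set_2, n_2)
    z = (z1 - z2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
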