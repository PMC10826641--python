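"""Landscape regressions: window statistics against genic fraction.

Selection against introgression predicts a negative slope of f_dM on the
fraction of window sites that are coding; discordance (RF) shows the
same sign, while dxy/FST go positive.  Ordinary least squares, windows
unweighted, NaN windows excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core import ValidationError


@dataclass
class LandscapeRegression:
    response: str
    covariate: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_windows: int
    n_excluded: int


def regress(
    table, response: str, covariate: str = "genic_fraction"
) -> LandscapeRegression:
    """OLS of a window statistic on a covariate (pandas DataFrame input)."""
    y = np.asarray(table[response], dtype=float)
    x = np.asarray(table[covariate], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValidationError(f"need >= 3 windows with data, got {n}")
    if np.ptp(x[ok]) == 0:
        raise ValidationError("covariate has zero variance")
    fit = sp_stats.linregress(x[ok], y[ok])
    return LandscapeRegression(
        response=response,
        covariate=covariate,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_windows=n,
        n_excluded=int(len(y) - n),
    )
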