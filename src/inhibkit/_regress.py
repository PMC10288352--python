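"""Thin OLS wrapper used by every linear fit in the package."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r: float
    r2: float
    n: int


def ols_line(x: np.ndarray, y: np.ndarray) -> LineFit:
    """Unweighted straight-line least squares with slope/intercept SEs.

    With exactly two points the line interpolates; SEs are 0 and the
    correlation coefficient is reported as 1 (the fit is exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points for a line fit")
    res = stats.linregress(x, y)
    if x.size == 2:
        return LineFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            slope_se=0.0,
            intercept_se=0.0,
            r=1.0,
            r2=1.0,
            n=2,
        )
    r = float(res.rvalue)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r=r,
        r2=r * r if math.isfinite(r) else float("nan"),
        n=int(x.size),
    )
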