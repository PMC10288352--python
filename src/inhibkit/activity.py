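"""Initial-rate extraction, relative activity, IC50 fitting and the
reversibility test on velocity-vs-enzyme lines."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._regress import ols_line
from .params import KineticParams
from .tables import DoseResponse, ProgressCurve, RateTable

__all__ = [
    "estimate_initial_rate",
    "relative_activity",
    "fit_ic50",
    "ic50_from_mixed_kinetics",
    "reversibility_test",
    "Ic50Fit",
    "ReversibilityVerdict",
]


@dataclass(frozen=True)
class Ic50Fit:
    """Two-parameter log-logistic dose-response fit (asymptotes fixed at 100/0)."""

    ic50: float  # μmol/L
    hill: float
    se_ic50: float
    se_hill: float
    r2: float

    def predict(self, inhibitor_uM: np.ndarray) -> np.ndarray:
        i = np.asarray(inhibitor_uM, dtype=float)
        return 100.0 / (1.0 + (i / self.ic50) ** self.hill)


@dataclass(frozen=True)
class LevelLine:
    """Per-inhibitor-level OLS of velocity on enzyme amount."""

    inhibitor_uM: float
    slope: float
    intercept: float
    intercept_se: float
    r2: float
    origin_ok: bool


@dataclass(frozen=True)
class ReversibilityVerdict:
    levels: tuple[LevelLine, ...]
    slopes_decreasing: bool
    verdict: Literal["reversible", "inconsistent"]

    @property
    def origin_ok(self) -> bool:
        return all(line.origin_ok for line in self.levels)


def estimate_initial_rate(
    curve: ProgressCurve,
    window: int | None = None,
    method: Literal["all", "max_r2"] = "all",
) -> tuple[float, float]:
    """OLS slope of absorbance on time: the initial velocity in ΔOD/s.

    ``method="all"`` (default) regresses over every recorded point — the
    assay is read in its linear early phase. ``method="max_r2"`` slides a
    window of ``window`` points and keeps the one with the highest R²,
    for curvature-contaminated traces.

    Returns ``(rate, standard_error)``.
    """
    t, od = curve.t, curve.od
    if method == "all":
        fit = ols_line(t, od)
        return fit.slope, fit.slope_se
    if method != "max_r2":
        raise ValueError(f"unknown method {method!r}")
    if window is None:
        window = min(5, t.size)
    if window < 3:
        raise ValueError("window must cover at least 3 points")
    if window > t.size:
        raise ValueError(
            f"window of {window} points exceeds the {t.size}-point curve"
        )
    best = None
    for start in range(t.size - window + 1):
        fit = ols_line(t[start : start + window], od[start : start + window])
        if best is None or fit.r2 > best.r2:
            best = fit
    return best.slope, best.slope_se


def relative_activity(ri: float, rc: float) -> float:
    """Relative activity in percent: ``100 * Ri / Rc``."""
    if not rc > 0:
        raise ValueError(f"uninhibited rate must be > 0, got {rc}")
    return 100.0 * ri / rc


def fit_ic50(d: DoseResponse) -> Ic50Fit:
    """Nonlinear least squares of ``RA = 100 / (1 + (I/IC50)^h)``.

    Requires data on both sides of half activity (at least one point below
    40% and one above 60% relative activity); otherwise the half-maximal
    point is extrapolated, not measured, and the fit refuses.
    """
    i = d.inhibitor_uM
    ra = d.relative_activity_pct
    if np.unique(i).size < 4:
        raise ValueError("need at least 4 distinct inhibitor levels")
    if np.all(ra > 60.0) or np.all(ra < 40.0):
        raise ValueError("IC50 not bracketed: data lie on one side of half activity")

    def model(conc, ic50, hill):
        return 100.0 / (1.0 + (conc / ic50) ** hill)

    # start at the concentration whose RA is closest to 50%
    ic50_0 = float(i[np.argmin(np.abs(ra - 50.0))])
    if ic50_0 <= 0:
        ic50_0 = float(np.median(i[i > 0]))
    popt, pcov = optimize.curve_fit(
        model, i, ra, p0=[ic50_0, 1.0], bounds=([1e-12, 1e-3], [np.inf, 100.0]),
        maxfev=10000,
    )
    ic50, hill = popt
    se = np.sqrt(np.diag(pcov))
    resid = ra - model(i, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ra - ra.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Ic50Fit(
        ic50=float(ic50),
        hill=float(hill),
        se_ic50=float(se[0]),
        se_hill=float(se[1]),
        r2=r2,
    )


def ic50_from_mixed_kinetics(p: KineticParams, s: float) -> float:
    """Inhibitor level halving the velocity at fixed substrate ``s``.

    Closed-form consequence of the mixed-inhibition rate law::

        IC50 = (Km + S) / (Km/Ki + S/Kis)
    """
    if math.isinf(p.ki) and math.isinf(p.kis):
        raise ValueError("no inhibition: both constants infinite")
    if not s > 0:
        raise ValueError("substrate concentration must be > 0")
    return (p.km + s) / (p.km / p.ki + s / p.kis)


def reversibility_test(
    table: RateTable,
    origin_tol: float = 0.05,
    use_ci: bool = True,
) -> ReversibilityVerdict:
    """Test whether velocity-vs-enzyme lines pass through the origin with
    slopes that fall as inhibitor rises.

    Per inhibitor level, velocity is regressed on enzyme amount. A line
    passes the origin test when ``|intercept| <= origin_tol * max(v)`` or —
    when a standard error is estimable and ``use_ci`` — its 95% CI covers
    zero. The verdict is "reversible" iff every line passes and the slopes
    strictly decrease with inhibitor concentration.
    """
    frame = table.to_frame()
    i_levels = np.sort(frame["inhibitor_uM"].unique())
    if i_levels.size < 2:
        raise ValueError("need at least 2 inhibitor levels")
    vmax_obs = float(frame["velocity"].abs().max())
    lines: list[LevelLine] = []
    for i_val in i_levels:
        grp = frame[frame["inhibitor_uM"] == i_val]
        e = grp["enzyme_scale"].to_numpy()
        v = grp["velocity"].to_numpy()
        if np.unique(e).size < 2:
            raise ValueError(
                f"inhibitor level {i_val} has a single enzyme level; "
                "cannot fit a line"
            )
        fit = ols_line(e, v)
        ok = abs(fit.intercept) <= origin_tol * vmax_obs
        if not ok and use_ci and fit.n > 2 and fit.intercept_se > 0:
            half = stats.t.ppf(0.975, fit.n - 2) * fit.intercept_se
            ok = (fit.intercept - half) <= 0.0 <= (fit.intercept + half)
        lines.append(
            LevelLine(
                inhibitor_uM=float(i_val),
                slope=fit.slope,
                intercept=fit.intercept,
                intercept_se=fit.intercept_se,
                r2=fit.r2,
                origin_ok=bool(ok),
            )
        )
    slopes = np.array([line.slope for line in lines])
    slopes_decreasing = bool(np.all(np.diff(slopes) < 0))
    reversible = slopes_decreasing and all(line.origin_ok for line in lines)
    return ReversibilityVerdict(
        levels=tuple(lines),
        slopes_decreasing=slopes_decreasing,
        verdict="reversible" if reversible else "inconsistent",
    )
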