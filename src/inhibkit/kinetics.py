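"""Double-reciprocal (Lineweaver-Burk) analysis of mixed inhibition.

Primary fits: one straight line of 1/v on 1/[S] per inhibitor level.
Secondary fits: the primary slopes and y-intercepts regressed on [I] give

    slope([I])       = Km/Vmax + Km/(Vmax*Ki) * [I]
    y-intercept([I]) = 1/Vmax  + 1/(Vmax*Kis) * [I]

so Ki = a/b and Kis = c/d from the two (intercept, slope) pairs, with
Vmax = 1/c and Km = a/c. Classification into competitive / uncompetitive /
noncompetitive / mixed is driven by which constants are finite and how far
apart they are. A direct nonlinear fit of the untransformed rate law is
provided as a cross-check, not the default route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize

from ._regress import ols_line
from .params import INF, KineticParams
from .simulate import mixed_inhibition_rate
from .tables import RateTable

__all__ = [
    "lineweaver_burk_transform",
    "fit_primary_lines",
    "fit_secondary",
    "classify_inhibition",
    "fit_rate_law_direct",
    "PrimaryLine",
    "KineticFit",
]

InhibitionType = Literal["competitive", "uncompetitive", "noncompetitive", "mixed"]


@dataclass(frozen=True)
class PrimaryLine:
    """One Lineweaver-Burk line: 1/v vs 1/[S] at a fixed inhibitor level."""

    inhibitor_uM: float
    slope: float  # apparent Km/Vmax
    y_intercept: float  # apparent 1/Vmax
    slope_se: float
    intercept_se: float
    r2: float


@dataclass(frozen=True)
class KineticFit:
    km: float
    vmax: float
    ki: float  # μmol/L; INF when the slope shows no inhibitor effect
    kis: float  # μmol/L; INF when the intercept shows no inhibitor effect
    ki_se: float
    kis_se: float
    primary_lines: tuple[PrimaryLine, ...]
    secondary_r2_slope: float
    secondary_r2_intercept: float
    inhibition_type: InhibitionType
    binding_preference: str | None  # "free enzyme" | "complex" | None
    intersection_quadrant: int | None = None


def lineweaver_burk_transform(table: RateTable) -> pd.DataFrame:
    """Reciprocal-transform a rate table for double-reciprocal fitting.

    Returns a frame with columns ``inhibitor_uM, inv_s, inv_v`` plus the
    original row index for provenance.
    """
    frame = table.to_frame().reset_index(names="row")
    bad = frame.index[frame["velocity"] <= 0]
    if bad.size:
        row = frame.loc[bad[0]]
        raise ValueError(
            "velocity must be > 0 for the reciprocal transform; offending row "
            f"{int(row['row'])}: S={row['substrate_uM']}, I={row['inhibitor_uM']}, "
            f"v={row['velocity']}"
        )
    out = pd.DataFrame(
        {
            "row": frame["row"],
            "inhibitor_uM": frame["inhibitor_uM"],
            "inv_s": 1.0 / frame["substrate_uM"],
            "inv_v": 1.0 / frame["velocity"],
        }
    )
    return out


def fit_primary_lines(transformed: pd.DataFrame) -> list[PrimaryLine]:
    """Unweighted OLS of 1/v on 1/[S] within each inhibitor level."""
    lines: list[PrimaryLine] = []
    for i_val in np.sort(transformed["inhibitor_uM"].unique()):
        grp = transformed[transformed["inhibitor_uM"] == i_val]
        if grp["inv_s"].nunique() < 3:
            raise ValueError(
                f"inhibitor level {i_val}: need >= 3 substrate levels, "
                f"got {grp['inv_s'].nunique()}"
            )
        fit = ols_line(grp["inv_s"].to_numpy(), grp["inv_v"].to_numpy())
        lines.append(
            PrimaryLine(
                inhibitor_uM=float(i_val),
                slope=fit.slope,
                y_intercept=fit.intercept,
                slope_se=fit.slope_se,
                intercept_se=fit.intercept_se,
                r2=fit.r2,
            )
        )
    return lines


def _intersection_quadrant(lines: list[PrimaryLine]) -> int | None:
    """Quadrant of the intersection of the I=0 and largest-I primary lines."""
    lo, hi = lines[0], lines[-1]
    if math.isclose(lo.slope, hi.slope):
        return None
    x = (hi.y_intercept - lo.y_intercept) / (lo.slope - hi.slope)
    y = lo.slope * x + lo.y_intercept
    if x >= 0:
        return 1 if y >= 0 else 4
    return 2 if y >= 0 else 3


def fit_secondary(
    lines: list[PrimaryLine], rel_tol: float = 0.10
) -> KineticFit:
    """Secondary plots of primary slope and y-intercept against [I].

    Requires >= 3 inhibitor levels including 0. A non-positive secondary
    slope means the corresponding binding mode is undetectable and the
    constant is set to the infinite sentinel.
    """
    if len(lines) < 3:
        raise ValueError("need >= 3 inhibitor levels for the secondary plots")
    lines = sorted(lines, key=lambda ln: ln.inhibitor_uM)
    if lines[0].inhibitor_uM != 0:
        raise ValueError("secondary plots need the uninhibited (I=0) level")
    i_vals = np.array([ln.inhibitor_uM for ln in lines])
    slope_fit = ols_line(i_vals, np.array([ln.slope for ln in lines]))
    int_fit = ols_line(i_vals, np.array([ln.y_intercept for ln in lines]))
    a, b = slope_fit.intercept, slope_fit.slope  # Km/Vmax, Km/(Vmax*Ki)
    c, d = int_fit.intercept, int_fit.slope  # 1/Vmax, 1/(Vmax*Kis)
    if a <= 0 or c <= 0:
        raise ValueError("non-positive secondary intercepts: data not well-posed")
    vmax = 1.0 / c
    km = a / c
    i_max = float(i_vals.max())
    # secondary slopes indistinguishable from zero across the whole grid
    # (numerical fuzz on degenerate data) count as "no detectable effect"
    if b * i_max < 1e-12 * a:
        b = 0.0
    if d * i_max < 1e-12 * c:
        d = 0.0
    if b > 0:
        ki = a / b
        # delta method on the ratio of two OLS coefficients (correlation ignored)
        ki_se = ki * math.hypot(
            slope_fit.intercept_se / a, slope_fit.slope_se / b
        )
    else:
        ki, ki_se = INF, float("nan")
    if d > 0:
        kis = c / d
        kis_se = kis * math.hypot(int_fit.intercept_se / c, int_fit.slope_se / d)
    else:
        kis, kis_se = INF, float("nan")
    inhibition_type = _classify(ki, kis, rel_tol)
    preference = None
    if math.isfinite(ki) and math.isfinite(kis) and ki != kis:
        preference = "free enzyme" if ki < kis else "complex"
    return KineticFit(
        km=km,
        vmax=vmax,
        ki=ki,
        kis=kis,
        ki_se=ki_se,
        kis_se=kis_se,
        primary_lines=tuple(lines),
        secondary_r2_slope=slope_fit.r2,
        secondary_r2_intercept=int_fit.r2,
        inhibition_type=inhibition_type,
        binding_preference=preference,
        intersection_quadrant=_intersection_quadrant(lines),
    )


def _classify(ki: float, kis: float, rel_tol: float) -> InhibitionType:
    if math.isinf(ki) and math.isinf(kis):
        raise ValueError("no inhibition detected: both constants infinite")
    if math.isinf(kis):
        return "competitive"
    if math.isinf(ki):
        return "uncompetitive"
    if abs(ki - kis) / min(ki, kis) <= rel_tol:
        return "noncompetitive"
    return "mixed"


def classify_inhibition(fit: KineticFit, rel_tol: float = 0.10) -> InhibitionType:
    """Classify an existing fit; tie-breaking between noncompetitive and
    mixed uses a relative tolerance on |Ki - Kis| (default 10%)."""
    return _classify(fit.ki, fit.kis, rel_tol)


def fit_rate_law_direct(
    table: RateTable, p0: KineticParams | None = None
) -> KineticParams:
    """Nonlinear least squares of the untransformed rate law.

    Cross-check for the reciprocal-transform route; fits
    (Vmax, Km, Ki, Kis) directly on (S, I, v) rows.
    """
    s = table.substrate_uM
    i = table.inhibitor_uM
    v = table.velocity
    if p0 is None:
        vmax0 = float(v.max()) * 1.5
        km0 = float(np.median(s))
        p0 = KineticParams(vmax=vmax0, km=km0, ki=km0, kis=km0)

    def model(x, vmax, km, ki, kis):
        ss, ii = x
        return vmax * ss / (km * (1.0 + ii / ki) + ss * (1.0 + ii / kis))

    popt, _ = optimize.curve_fit(
        model,
        (s, i),
        v,
        p0=[p0.vmax, p0.km, p0.ki, p0.kis],
        bounds=(1e-12, np.inf),
        maxfev=20000,
    )
    return KineticParams(vmax=popt[0], km=popt[1], ki=popt[2], kis=popt[3])
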