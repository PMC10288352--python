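"""Van't Hoff binding thermodynamics.

Fits log10(Ka) against 1/T, converts slope and intercept to ΔH and ΔS with
the conventional 2.303 decadic factor, evaluates ΔG = ΔH − TΔS per input
temperature, and classifies the dominant driving forces from the signs of
ΔH and ΔS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._regress import ols_line
from ._units import GAS_CONSTANT, LN10

__all__ = [
    "vant_hoff_fit",
    "gibbs_free_energy",
    "classify_forces",
    "binding_thermo",
    "ka_from_thermo",
    "VantHoffFit",
    "BindingThermo",
]

ForceRules = Literal["paper", "ross"]


@dataclass(frozen=True)
class VantHoffFit:
    dh: float  # kJ/mol
    ds: float  # J/(mol*K)
    dh_se: float
    ds_se: float
    r: float


@dataclass(frozen=True)
class BindingThermo:
    temperatures_K: tuple[float, ...]
    ka: tuple[float, ...]  # L/mol, matched to temperatures
    dh: float  # kJ/mol
    ds: float  # J/(mol*K)
    dh_se: float
    ds_se: float
    dg: tuple[float, ...]  # kJ/mol per temperature
    r_vh: float
    force_verdict: str
    spontaneous: bool


def vant_hoff_fit(pairs: Sequence[tuple[float, float]]) -> VantHoffFit:
    """OLS of log10(Ka) on 1/T.

    ΔH = −2.303·R·slope (reported in kJ/mol), ΔS = 2.303·R·intercept
    (J/(mol·K)). Two points give an exact interpolating line with r
    reported as 1 and undefined SEs as NaN.
    """
    t = np.array([p[0] for p in pairs], dtype=float)
    ka = np.array([p[1] for p in pairs], dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 (T, Ka) pairs")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate temperatures")
    if np.any(t <= 0) or np.any(ka <= 0):
        raise ValueError("temperatures and binding constants must be > 0")
    fit = ols_line(1.0 / t, np.log10(ka))
    dh = -LN10 * GAS_CONSTANT * fit.slope / 1000.0  # kJ/mol
    ds = LN10 * GAS_CONSTANT * fit.intercept  # J/(mol*K)
    if t.size == 2:
        dh_se = ds_se = float("nan")
    else:
        dh_se = LN10 * GAS_CONSTANT * fit.slope_se / 1000.0
        ds_se = LN10 * GAS_CONSTANT * fit.intercept_se
    return VantHoffFit(dh=dh, ds=ds, dh_se=dh_se, ds_se=ds_se, r=fit.r)


def ka_from_thermo(dh: float, ds: float, t: float) -> float:
    """Forward model inverse of :func:`vant_hoff_fit`: Ka(T) from ΔH, ΔS.

    Uses the same 2.303 decadic convention so fit/generate round-trips are
    exact. ΔH in kJ/mol, ΔS in J/(mol·K).
    """
    if not t > 0:
        raise ValueError("temperature must be > 0")
    log10_ka = -dh * 1000.0 / (LN10 * GAS_CONSTANT * t) + ds / (LN10 * GAS_CONSTANT)
    return 10.0**log10_ka


def gibbs_free_energy(dh: float, ds: float, t: float) -> float:
    """ΔG = ΔH − TΔS, with ΔH in kJ/mol and ΔS in J/(mol·K); result kJ/mol."""
    if not t > 0:
        raise ValueError("temperature must be > 0")
    return dh - t * ds / 1000.0


def classify_forces(
    dh: float,
    ds: float,
    rules: ForceRules = "paper",
    zero_band_kj: float = 1.0,
) -> str:
    """Dominant-driving-force call from the signs of ΔH and ΔS.

    The default rule table maps (ΔH<0, ΔS>0) to hydrogen bonding plus
    hydrophobic interaction; the Ross-Subramanian convention
    (``rules="ross"``) maps the same sign pattern to electrostatic forces.
    |ΔH| below ``zero_band_kj`` counts as ΔH ≈ 0.
    """
    if not (math.isfinite(dh) and math.isfinite(ds)):
        raise ValueError("dh and ds must be finite")
    if abs(dh) < zero_band_kj and ds > 0:
        return "electrostatic"
    if dh < 0 and ds > 0:
        if rules == "ross":
            return "electrostatic"
        return "hydrogen bonds + hydrophobic"
    if dh < 0 and ds < 0:
        return "hydrogen bonds + van der Waals"
    if dh > 0 and ds > 0:
        return "hydrophobic"
    return "indeterminate"


def binding_thermo(
    pairs: Sequence[tuple[float, float]],
    rules: ForceRules = "paper",
) -> BindingThermo:
    """Full thermodynamic characterization from (T, Ka) pairs.

    ΔG is evaluated per input temperature from the single fitted (ΔH, ΔS)
    pair — not from the per-temperature Ka — so the emitted values satisfy
    ΔG = ΔH − TΔS identically.
    """
    fit = vant_hoff_fit(pairs)
    temps = tuple(float(p[0]) for p in pairs)
    kas = tuple(float(p[1]) for p in pairs)
    dg = tuple(gibbs_free_energy(fit.dh, fit.ds, t) for t in temps)
    return BindingThermo(
        temperatures_K=temps,
        ka=kas,
        dh=fit.dh,
        ds=fit.ds,
        dh_se=fit.dh_se,
        ds_se=fit.ds_se,
        dg=dg,
        r_vh=fit.r,
        force_verdict=classify_forces(fit.dh, fit.ds, rules=rules),
        spontaneous=bool(all(g < 0 for g in dg)),
    )
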