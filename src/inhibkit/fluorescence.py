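"""Fluorescence quenching analysis.

Inner-filter correction, linear Stern-Volmer fitting with mechanism
classification (static vs dynamic), the double-logarithmic binding fit for
the apparent binding constant and site number, and simple emission-peak
extraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from ._regress import ols_line
from ._units import um_to_m
from .tables import TitrationSeries

__all__ = [
    "inner_filter_correct",
    "corrected_intensities",
    "stern_volmer_fit",
    "quenching_rate_constant",
    "classify_quenching",
    "double_log_fit",
    "analyze_titration",
    "emission_peak",
    "QuenchFit",
    "MechanismVerdict",
    "DIFFUSION_LIMIT",
]

#: Maximum diffusion-controlled collisional quenching rate, L/(mol*s).
DIFFUSION_LIMIT = 2.0e10


@dataclass(frozen=True)
class QuenchFit:
    """Quenching constants for one titration at one temperature."""

    temperature_K: float
    ksv: float  # L/mol
    ksv_se: float
    r_sv: float
    sv_intercept: float
    kq: float  # L/(mol*s); always ksv / tau0
    ka: float  # L/mol
    ka_se: float
    n: float
    n_se: float
    r_dl: float
    tau0: float = 1e-8
    corrected: bool = True


@dataclass(frozen=True)
class MechanismVerdict:
    kq_exceeds_diffusion: tuple[bool, ...]
    ksv_decreasing_with_T: bool | None  # None when only one temperature
    verdict: Literal["static", "dynamic", "ambiguous"]
    reasons: tuple[str, ...]


def inner_filter_correct(
    f_measured: np.ndarray, a_ex: np.ndarray, a_em: np.ndarray
) -> np.ndarray:
    """Undo inner-filter attenuation: ``Fc = Fm * exp((A1 + A2)/2)``.

    A1 and A2 are the quencher absorbances at the excitation and emission
    wavelengths. Exact inverse of the simulator's attenuation.
    """
    f_measured = np.asarray(f_measured, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(f_measured <= 0):
        raise ValueError("measured intensities must be positive")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    return f_measured * np.exp((a_ex + a_em) / 2.0)


def corrected_intensities(series: TitrationSeries) -> np.ndarray:
    """Corrected intensities of a series; computes them if not already present."""
    if series.f_corrected is not None:
        return series.f_corrected
    return inner_filter_correct(series.f_measured, series.a_ex, series.a_em)


def stern_volmer_fit(
    series: TitrationSeries, tau0: float = 1e-8, corrected: bool = True
) -> QuenchFit:
    """OLS of F0/F against [Q] in mol/L; Ksv is the slope.

    The intercept is left free; a deviation of more than 5% from 1 is a
    diagnosable systematic error and raises a warning rather than being
    silently constrained away. The fit is normally run on inner-filter
    corrected intensities (``corrected=True``); the uncorrected variant is
    available to quantify the attenuation bias.

    The returned fit carries placeholder NaNs for the double-log block;
    use :func:`analyze_titration` for the combined result.
    """
    f = corrected_intensities(series) if corrected else series.f_measured
    q_m = um_to_m(series.quencher_uM)
    nz = q_m > 0
    if nz.sum() < 4:
        raise ValueError("need >= 4 nonzero quencher levels")
    f0 = f[~nz]
    if f0.size == 0:
        raise ValueError("no zero-quencher row: F0 undefined")
    f0 = float(f0[0])
    fit = ols_line(q_m[nz], f0 / f[nz])
    if abs(fit.intercept - 1.0) > 0.05:
        warnings.warn(
            f"Stern-Volmer intercept {fit.intercept:.4f} deviates from 1 by "
            ">5%: check correction or linearity",
            stacklevel=2,
        )
    if fit.slope <= 0:
        warnings.warn("non-positive Stern-Volmer slope: no quenching detected",
                      stacklevel=2)
    return QuenchFit(
        temperature_K=series.temperature_K,
        ksv=fit.slope,
        ksv_se=fit.slope_se,
        r_sv=fit.r,
        sv_intercept=fit.intercept,
        kq=quenching_rate_constant(fit.slope, tau0),
        ka=float("nan"),
        ka_se=float("nan"),
        n=float("nan"),
        n_se=float("nan"),
        r_dl=float("nan"),
        tau0=tau0,
        corrected=corrected,
    )


def quenching_rate_constant(ksv: float, tau0: float = 1e-8) -> float:
    """Bimolecular quenching rate constant ``Kq = Ksv / tau0``."""
    if not tau0 > 0:
        raise ValueError("tau0 must be > 0")
    return ksv / tau0


def double_log_fit(
    series: TitrationSeries, corrected: bool = True
) -> tuple[float, float, float, float, float]:
    """Double-log binding fit: log10((F0-F)/F) on log10([Q] in mol/L).

    Returns ``(ka, n, ka_se, n_se, r)`` where Ka = 10^intercept (L/mol)
    and n is the slope (binding sites). Rows with F >= F0 carry no
    quenching signal and are dropped with a warning.
    """
    f = corrected_intensities(series) if corrected else series.f_measured
    q_m = um_to_m(series.quencher_uM)
    nz = q_m > 0
    f0_rows = f[~nz]
    if f0_rows.size == 0:
        raise ValueError("no zero-quencher row: F0 undefined")
    f0 = float(f0_rows[0])
    f_nz = f[nz]
    q_nz = q_m[nz]
    usable = f_nz < f0
    if not usable.any():
        raise ValueError("no quenching: all intensities >= F0")
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} titration row(s) with F >= F0",
            stacklevel=2,
        )
    if usable.sum() < 4:
        raise ValueError("fewer than 4 usable titration points")
    x = np.log10(q_nz[usable])
    y = np.log10((f0 - f_nz[usable]) / f_nz[usable])
    fit = ols_line(x, y)
    ka = 10.0**fit.intercept
    # log10 intercept SE -> multiplicative SE on Ka, linearized
    ka_se = ka * math.log(10.0) * fit.intercept_se
    return ka, fit.slope, ka_se, fit.slope_se, fit.r


def analyze_titration(
    series: TitrationSeries, tau0: float = 1e-8, corrected: bool = True
) -> QuenchFit:
    """Run both the Stern-Volmer and double-log fits on one titration."""
    sv = stern_volmer_fit(series, tau0=tau0, corrected=corrected)
    ka, n, ka_se, n_se, r_dl = double_log_fit(series, corrected=corrected)
    return QuenchFit(
        temperature_K=sv.temperature_K,
        ksv=sv.ksv,
        ksv_se=sv.ksv_se,
        r_sv=sv.r_sv,
        sv_intercept=sv.sv_intercept,
        kq=sv.kq,
        ka=ka,
        ka_se=ka_se,
        n=n,
        n_se=n_se,
        r_dl=r_dl,
        tau0=tau0,
        corrected=corrected,
    )


def classify_quenching(
    fits: Sequence[QuenchFit], diffusion_limit: float = DIFFUSION_LIMIT
) -> MechanismVerdict:
    """Static-vs-dynamic call from the Kq magnitude and the Ksv(T) trend.

    Static quenching requires every Kq to exceed the diffusion-controlled
    collisional limit AND Ksv to fall with temperature (complex formation
    weakens on heating). Dynamic requires the converse on both counts.
    Conflicting evidence yields "ambiguous" with the reasons listed.
    """
    if not fits:
        raise ValueError("need at least one quench fit")
    fits = sorted(fits, key=lambda f: f.temperature_K)
    exceeds = tuple(f.kq > diffusion_limit for f in fits)
    reasons: list[str] = []
    if len(fits) >= 2:
        ksv = [f.ksv for f in fits]
        decreasing: bool | None = all(b < a for a, b in zip(ksv, ksv[1:]))
        increasing = all(b > a for a, b in zip(ksv, ksv[1:]))
    else:
        decreasing = None
        increasing = False
        reasons.append("single temperature: Ksv trend unknown")
    if all(exceeds):
        reasons.append(
            f"all Kq exceed the diffusion limit {diffusion_limit:.2g} L/(mol*s)"
        )
    elif not any(exceeds):
        reasons.append("all Kq at or below the diffusion limit")
    else:
        reasons.append("Kq straddles the diffusion limit across temperatures")
    if decreasing:
        reasons.append("Ksv decreases with temperature")
    elif increasing:
        reasons.append("Ksv increases with temperature")
    elif decreasing is not None:
        reasons.append("Ksv shows no monotone temperature trend")

    if all(exceeds) and decreasing:
        verdict = "static"
    elif not any(exceeds) and increasing:
        verdict = "dynamic"
    else:
        verdict = "ambiguous"
    return MechanismVerdict(
        kq_exceeds_diffusion=exceeds,
        ksv_decreasing_with_T=decreasing,
        verdict=verdict,
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class PeakResult:
    peaks_nm: tuple[float, ...]
    peak_intensities: tuple[float, ...]

    @property
    def primary_nm(self) -> float | None:
        if not self.peaks_nm:
            return None
        return self.peaks_nm[
            int(np.argmax(np.asarray(self.peak_intensities)))
        ]


def emission_peak(
    wavelengths: np.ndarray,
    intensity: np.ndarray,
    prominence_frac: float = 0.05,
) -> PeakResult:
    """Locate emission maxima with 3-point parabolic refinement.

    All local maxima with prominence above ``prominence_frac`` of the
    intensity range are reported; a flat spectrum yields an empty result.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if wavelengths.size < 5:
        raise ValueError("need >= 5 spectrum points")
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    span = float(intensity.max() - intensity.min())
    if span == 0:
        return PeakResult(peaks_nm=(), peak_intensities=())
    idx, _ = find_peaks(intensity, prominence=prominence_frac * span,
                        plateau_size=1)
    peaks: list[float] = []
    heights: list[float] = []
    for j in idx:
        lam = wavelengths[j]
        h = intensity[j]
        if 0 < j < wavelengths.size - 1:
            y0, y1, y2 = intensity[j - 1], intensity[j], intensity[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # genuine curvature; refine sub-sample
                delta = 0.5 * (y0 - y2) / denom
                step = 0.5 * (wavelengths[j + 1] - wavelengths[j - 1])
                lam = wavelengths[j] + delta * step
                h = y1 - 0.25 * (y0 - y2) * delta
        peaks.append(float(lam))
        heights.append(float(h))
    return PeakResult(peaks_nm=tuple(peaks), peak_intensities=tuple(heights))
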