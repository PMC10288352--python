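"""Seeded forward simulator for every input table the analysis stages consume.

The simulator produces, from explicit parameter objects:

- mixed-inhibition initial velocities on a substrate x inhibitor grid,
- velocity-vs-enzyme series (the reversibility experiment),
- linear early-phase absorbance progress curves,
- log-logistic dose-response tables,
- cumulative-dilution fluorescence titrations with inner-filter attenuation,
- a simple two-Gaussian emission spectrum for peak-extraction tests.

All randomness flows through a :class:`~inhibkit.params.NoiseModel`; with
``rel_sd = 0`` every output satisfies its generating law to machine
precision, which is what the round-trip recovery tests rely on.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np

from ._units import um_to_m
from .params import NOISELESS, KineticParams, NoiseModel, QuenchParams, TitrationScheme
from .tables import DoseResponse, ProgressCurve, RateTable, TitrationSeries

__all__ = [
    "mixed_inhibition_rate",
    "simulate_progress_curve",
    "simulate_rate_grid",
    "simulate_enzyme_series",
    "simulate_dose_response",
    "make_titration_concentrations",
    "simulate_titration",
    "simulate_emission_spectrum",
    "DEFAULT_SUBSTRATE_GRID",
    "DEFAULT_INHIBITOR_GRID",
    "DEFAULT_TEMPERATURES",
]

#: Default concentration grids (μmol/L) and temperatures (K).
DEFAULT_SUBSTRATE_GRID = (6.25, 12.5, 25.0, 50.0)
DEFAULT_INHIBITOR_GRID = (0.0, 5.21, 10.42, 20.83, 41.67)
DEFAULT_TEMPERATURES = (298.0, 304.0, 310.0)


def mixed_inhibition_rate(p: KineticParams, s: float, i: float) -> float:
    """Mixed-inhibition velocity at substrate ``s`` and inhibitor ``i`` (μmol/L).

    Direct form of the double-reciprocal rate law::

        v = Vmax * S / (Km * (1 + I/Ki) + S * (1 + I/Kis))

    With ``i = 0`` this is plain Michaelis-Menten; infinite Ki or Kis
    silently drop the corresponding term.
    """
    if not s > 0:
        raise ValueError(f"substrate concentration must be > 0, got {s}")
    if i < 0:
        raise ValueError(f"inhibitor concentration must be >= 0, got {i}")
    denom = p.km * (1.0 + i / p.ki) + s * (1.0 + i / p.kis)
    return p.vmax * s / denom


def simulate_progress_curve(
    p: KineticParams,
    s: float,
    i: float,
    e_scale: float,
    times: Sequence[float],
    noise: NoiseModel = NOISELESS,
    k: float = 1.0,
    od_bg: float = 0.05,
    condition_id: str | None = None,
) -> ProgressCurve:
    """Linear early-phase absorbance trace: ``od(t) = od_bg + k*e_scale*v*t``.

    ``k`` converts velocity units to ΔOD per second (no extinction
    coefficient is modelled). Noise is applied multiplicatively to the OD
    readings themselves.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0) or not np.all(np.diff(times) > 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if not e_scale > 0:
        raise ValueError("e_scale must be > 0")
    v = mixed_inhibition_rate(p, s, i)
    od = od_bg + k * e_scale * v * times
    od = noise.apply(od)
    if condition_id is None:
        condition_id = f"S{s:g}_I{i:g}_E{e_scale:g}"
    return ProgressCurve(
        condition_id=condition_id,
        t=times,
        od=od,
        substrate_uM=s,
        inhibitor_uM=i,
        enzyme_scale=e_scale,
    )


def simulate_rate_grid(
    p: KineticParams,
    s_levels: Sequence[float] = DEFAULT_SUBSTRATE_GRID,
    i_levels: Sequence[float] = DEFAULT_INHIBITOR_GRID,
    noise: NoiseModel = NOISELESS,
) -> RateTable:
    """Initial-velocity table over the full substrate x inhibitor grid.

    One row per (S, I) pair, enzyme scale 1. Noiseless velocities satisfy
    the rate law exactly.
    """
    s_levels = [float(s) for s in s_levels]
    i_levels = [float(i) for i in i_levels]
    pairs = [(s, i) for i in i_levels for s in s_levels]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (substrate, inhibitor) pairs in grid")
    s_col = np.array([s for s, _ in pairs])
    i_col = np.array([i for _, i in pairs])
    v = np.array([mixed_inhibition_rate(p, s, i) for s, i in pairs])
    v = noise.apply(v)
    return RateTable(substrate_uM=s_col, inhibitor_uM=i_col, velocity=v)


def simulate_enzyme_series(
    p: KineticParams,
    s: float,
    i_levels: Sequence[float],
    e_levels: Sequence[float],
    noise: NoiseModel = NOISELESS,
) -> RateTable:
    """Velocity vs enzyme amount at fixed substrate, one line per inhibitor level.

    Noiseless velocities are ``E * v(S, I)``: every line passes through the
    origin, with slope decreasing in inhibitor concentration.
    """
    e_levels = [float(e) for e in e_levels]
    if len(set(e_levels)) < 2:
        raise ValueError("need at least 2 distinct enzyme levels")
    if any(e <= 0 for e in e_levels):
        raise ValueError("enzyme levels must be positive")
    rows = [(s, i, e) for i in i_levels for e in e_levels]
    s_col = np.array([r[0] for r in rows])
    i_col = np.array([r[1] for r in rows])
    e_col = np.array([r[2] for r in rows])
    v = np.array([e * mixed_inhibition_rate(p, s, i) for s, i, e in rows])
    v = noise.apply(v)
    return RateTable(
        substrate_uM=s_col, inhibitor_uM=i_col, enzyme_scale=e_col, velocity=v
    )


def simulate_dose_response(
    ic50: float,
    hill: float,
    i_levels: Sequence[float],
    noise: NoiseModel = NOISELESS,
    label: str = "",
) -> DoseResponse:
    """Relative activity from the two-parameter log-logistic model
    ``RA = 100 / (1 + (I/IC50)^h)``."""
    if not ic50 > 0 or not hill > 0:
        raise ValueError("ic50 and hill must be > 0")
    i_levels = np.asarray(i_levels, dtype=float)
    if np.any(i_levels < 0):
        raise ValueError("inhibitor levels must be >= 0")
    ra = 100.0 / (1.0 + (i_levels / ic50) ** hill)
    ra = noise.apply(ra)
    return DoseResponse(inhibitor_uM=i_levels, relative_activity_pct=ra, label=label)


def make_titration_concentrations(scheme: TitrationScheme) -> np.ndarray:
    """Cuvette quencher concentrations (μmol/L) for each addition, 0 included."""
    return scheme.concentrations()


def simulate_titration(
    q: QuenchParams,
    scheme: TitrationScheme,
    temperature_K: float,
    mode: Literal["stern_volmer", "double_log"] = "stern_volmer",
    noise: NoiseModel = NOISELESS,
) -> TitrationSeries:
    """One fluorescence titration at ``temperature_K``.

    The true corrected intensity follows the requested generation law
    (with [Q] converted to mol/L):

    - ``stern_volmer``: ``F0 / Fc = 1 + Ksv * [Q]``
    - ``double_log``:   ``(F0 - Fc) / Fc = Ka * [Q]^n``

    The emitted measured intensity is inner-filter attenuated,
    ``Fm = Fc * exp(-(A1 + A2)/2)`` with ``A1 = eps_ex*[Q]`` and
    ``A2 = eps_em*[Q]``; noise multiplies Fm. The two laws are
    deliberately distinct forward models (they disagree unless n = 1), so
    each recovery test must use its matching mode.
    """
    conc_um = scheme.concentrations()
    conc_m = um_to_m(conc_um)
    if mode == "stern_volmer":
        fc = q.f0 / (1.0 + q.ksv * conc_m)
    elif mode == "double_log":
        fc = q.f0 / (1.0 + q.ka * conc_m**q.n)
    else:
        raise ValueError(f"unknown titration mode {mode!r}")
    a_ex = q.eps_ex * conc_um
    a_em = q.eps_em * conc_um
    fm = fc * np.exp(-(a_ex + a_em) / 2.0)
    fm = noise.apply(fm)
    return TitrationSeries(
        temperature_K=temperature_K,
        quencher_uM=conc_um,
        f_measured=fm,
        a_ex=a_ex,
        a_em=a_em,
    )


def simulate_emission_spectrum(
    wavelengths: Sequence[float] | None = None,
    centers: Sequence[float] = (336.0, 404.0),
    amplitudes: Sequence[float] = (1000.0, 600.0),
    widths: Sequence[float] = (15.0, 18.0),
    noise: NoiseModel = NOISELESS,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-Gaussian-peak emission spectrum on a 290-500 nm grid.

    Exists only to exercise peak-location extraction; no photophysics.
    """
    if wavelengths is None:
        wavelengths = np.arange(290.0, 500.5, 1.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensity = np.zeros_like(wavelengths)
    for c, a, w in zip(centers, amplitudes, widths):
        intensity += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
    intensity = noise.apply(intensity)
    return wavelengths, intensity
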