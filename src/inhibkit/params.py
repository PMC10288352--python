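"""Parameter types shared by the simulator and the analysis stages.

Infinite inhibition constants are legal and meaningful: ``Ki = math.inf``
encodes an inhibitor that never binds the free enzyme (pure uncompetitive),
``Kis = math.inf`` one that never binds the enzyme-substrate complex (pure
competitive). ``I / inf`` evaluates to 0.0 in IEEE arithmetic, so the rate
law needs no special casing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Typed sentinel for "this binding mode does not occur".
INF = math.inf


def _require_positive(name: str, value: float, allow_inf: bool = False) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    if not allow_inf and math.isinf(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class KineticParams:
    """Mixed-inhibition rate-law parameters.

    Parameters
    ----------
    vmax : float
        Maximal velocity, in arbitrary velocity units (e.g. ΔOD/min).
    km : float
        Michaelis constant, μmol/L.
    ki : float
        Inhibition constant for the free enzyme, μmol/L. ``INF`` disables
        the competitive component.
    kis : float
        Inhibition constant for the enzyme-substrate complex, μmol/L.
        ``INF`` disables the uncompetitive component.
    """

    vmax: float
    km: float
    ki: float
    kis: float

    def __post_init__(self) -> None:
        _require_positive("vmax", self.vmax)
        _require_positive("km", self.km)
        _require_positive("ki", self.ki, allow_inf=True)
        _require_positive("kis", self.kis, allow_inf=True)


@dataclass(frozen=True)
class QuenchParams:
    """Forward-model parameters for a fluorescence quenching titration.

    ``eps_ex`` and ``eps_em`` are the quencher's decadic attenuations per
    unit concentration at the excitation and emission wavelengths, in
    (μmol/L)^-1, so the absorbances of a titration point are
    ``a_ex = eps_ex * [Q]`` and ``a_em = eps_em * [Q]``.
    """

    f0: float
    ksv: float  # L/mol
    ka: float  # L/mol
    n: float  # binding sites, dimensionless
    eps_ex: float = 0.0
    eps_em: float = 0.0
    tau0: float = 1e-8  # fluorophore lifetime, s

    def __post_init__(self) -> None:
        _require_positive("f0", self.f0)
        _require_positive("ksv", self.ksv)
        _require_positive("ka", self.ka)
        _require_positive("n", self.n)
        _require_positive("tau0", self.tau0)
        if self.eps_ex < 0 or self.eps_em < 0:
            raise ValueError("eps_ex and eps_em must be non-negative")


@dataclass(frozen=True)
class TitrationScheme:
    """Cumulative-aliquot titration of a fixed cuvette volume.

    ``va`` mL of ``c_stock`` μmol/L quencher stock is added ``n_additions``
    times to an initial volume ``v0`` mL, so after n additions the cuvette
    concentration is ``c_stock * n * va / (v0 + n * va)``.
    """

    v0: float = 2.0  # mL
    va: float = 0.1  # mL
    c_stock: float = 100.0  # μmol/L
    n_additions: int = 8

    def __post_init__(self) -> None:
        _require_positive("v0", self.v0)
        _require_positive("va", self.va)
        _require_positive("c_stock", self.c_stock)
        if self.n_additions < 0:
            raise ValueError("n_additions must be >= 0")

    def concentrations(self) -> np.ndarray:
        """Quencher concentration (μmol/L) after 0..n_additions additions.

        Length ``n_additions + 1``, starting at 0, strictly increasing.
        """
        n = np.arange(self.n_additions + 1, dtype=float)
        return self.c_stock * n * self.va / (self.v0 + n * self.va)

    def volumes(self) -> np.ndarray:
        """Cuvette volume (mL) after each addition; used by the optional
        dilution correction."""
        n = np.arange(self.n_additions + 1, dtype=float)
        return self.v0 + n * self.va


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian instrument noise.

    A reading x becomes ``x * (1 + rel_sd * z)`` with ``z ~ N(0, 1)``.
    ``rel_sd = 0`` reproduces the forward model exactly; identical seed and
    parameters give bit-identical output.
    """

    rel_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.rel_sd == 0:
            return values.copy()
        if rng is None:
            rng = self.rng()
        return values * (1.0 + self.rel_sd * rng.standard_normal(values.shape))


NOISELESS = NoiseModel(rel_sd=0.0, seed=0)
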