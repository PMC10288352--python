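"""Tabular data containers exchanged between pipeline stages.

Each container mirrors one of the CSV interchange formats:

- ``ProgressCurve``  <-> rows of ``progress.csv`` for one condition
- ``RateTable``      <-> ``rates.csv``
- ``DoseResponse``   <-> ``dose_response.csv``
- ``TitrationSeries``<-> rows of ``titration.csv`` for one temperature
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class ProgressCurve:
    """One UV kinetic trace: absorbance vs time under a single condition."""

    condition_id: str
    t: np.ndarray  # seconds, strictly increasing
    od: np.ndarray  # absorbance at the detection wavelength
    substrate_uM: float = float("nan")
    inhibitor_uM: float = float("nan")
    enzyme_scale: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.t.size != self.od.size:
            raise ValueError("t and od must have equal length")
        if self.t.size < 3:
            raise ValueError("a progress curve needs at least 3 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.od))):
            raise ValueError("non-finite values in progress curve")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition_id": self.condition_id, "t_s": self.t, "od290": self.od}
        )


@dataclass
class RateTable:
    """Initial velocities keyed by substrate, inhibitor and enzyme level."""

    substrate_uM: np.ndarray
    inhibitor_uM: np.ndarray
    velocity: np.ndarray
    enzyme_scale: np.ndarray | None = None
    velocity_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.inhibitor_uM = np.asarray(self.inhibitor_uM, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.substrate_uM.size
        if self.inhibitor_uM.size != n or self.velocity.size != n:
            raise ValueError("column lengths differ")
        if self.enzyme_scale is None:
            self.enzyme_scale = np.ones(n)
        else:
            self.enzyme_scale = np.asarray(self.enzyme_scale, dtype=float)
            if self.enzyme_scale.size != n:
                raise ValueError("column lengths differ")
        if self.velocity_se is not None:
            self.velocity_se = np.asarray(self.velocity_se, dtype=float)

    def __len__(self) -> int:
        return int(self.substrate_uM.size)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "substrate_uM": self.substrate_uM,
                "inhibitor_uM": self.inhibitor_uM,
                "enzyme_scale": self.enzyme_scale,
                "velocity": self.velocity,
            }
        )
        if self.velocity_se is not None:
            frame["velocity_se"] = self.velocity_se
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RateTable":
        return cls(
            substrate_uM=frame["substrate_uM"].to_numpy(),
            inhibitor_uM=frame["inhibitor_uM"].to_numpy(),
            velocity=frame["velocity"].to_numpy(),
            enzyme_scale=(
                frame["enzyme_scale"].to_numpy() if "enzyme_scale" in frame else None
            ),
            velocity_se=(
                frame["velocity_se"].to_numpy() if "velocity_se" in frame else None
            ),
        )


@dataclass
class DoseResponse:
    """Relative activity (%) versus inhibitor concentration."""

    inhibitor_uM: np.ndarray
    relative_activity_pct: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.inhibitor_uM = np.asarray(self.inhibitor_uM, dtype=float)
        self.relative_activity_pct = np.asarray(self.relative_activity_pct, dtype=float)
        if self.inhibitor_uM.size != self.relative_activity_pct.size:
            raise ValueError("column lengths differ")
        ra = self.relative_activity_pct
        # 110 leaves headroom for instrument-noise overshoot above 100%
        if np.any(ra < 0) or np.any(ra > 110):
            raise ValueError("relative activity must lie in [0, 110] percent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inhibitor_uM": self.inhibitor_uM,
                "relative_activity_pct": self.relative_activity_pct,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "DoseResponse":
        return cls(
            inhibitor_uM=frame["inhibitor_uM"].to_numpy(),
            relative_activity_pct=frame["relative_activity_pct"].to_numpy(),
            label=label,
        )


@dataclass
class TitrationSeries:
    """One fluorescence titration at a single temperature.

    Row 0 must be the quencher-free point; its corrected intensity defines
    F0 for the quenching fits. ``a_ex``/``a_em`` are the quencher
    absorbances at the excitation and emission wavelengths used by the
    inner-filter correction.
    """

    temperature_K: float
    quencher_uM: np.ndarray
    f_measured: np.ndarray
    a_ex: np.ndarray
    a_em: np.ndarray
    f_corrected: np.ndarray | None = None
    ex_nm: float = 280.0
    em_nm: float = 404.0

    def __post_init__(self) -> None:
        self.quencher_uM = np.asarray(self.quencher_uM, dtype=float)
        self.f_measured = np.asarray(self.f_measured, dtype=float)
        self.a_ex = np.asarray(self.a_ex, dtype=float)
        self.a_em = np.asarray(self.a_em, dtype=float)
        n = self.quencher_uM.size
        for name in ("f_measured", "a_ex", "a_em"):
            if getattr(self, name).size != n:
                raise ValueError("column lengths differ")
        if np.any(np.diff(self.quencher_uM) < 0):
            raise ValueError("quencher concentration must be non-decreasing")
        if self.quencher_uM[0] != 0:
            raise ValueError("row 0 must be the quencher-free point (defines F0)")
        if np.any(self.f_measured <= 0):
            raise ValueError("intensities must be positive")
        if self.f_corrected is not None:
            self.f_corrected = np.asarray(self.f_corrected, dtype=float)

    def __len__(self) -> int:
        return int(self.quencher_uM.size)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "temperature_K": self.temperature_K,
                "addition_index": np.arange(len(self)),
                "quencher_uM": self.quencher_uM,
                "f_measured": self.f_measured,
                "a_ex": self.a_ex,
                "a_em": self.a_em,
            }
        )
        if self.f_corrected is not None:
            frame["f_corrected"] = self.f_corrected
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TitrationSeries":
        temps = frame["temperature_K"].unique()
        if temps.size != 1:
            raise ValueError(
                "a TitrationSeries holds one temperature; got " + repr(temps)
            )
        frame = frame.sort_values("addition_index")
        return cls(
            temperature_K=float(temps[0]),
            quencher_uM=frame["quencher_uM"].to_numpy(),
            f_measured=frame["f_measured"].to_numpy(),
            a_ex=frame["a_ex"].to_numpy(),
            a_em=frame["a_em"].to_numpy(),
            f_corrected=(
                frame["f_corrected"].to_numpy() if "f_corrected" in frame else None
            ),
        )
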