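"""CSV and JSON interchange.

All CSV files are UTF-8 with a header row and '.' decimal separator:

- ``rates.csv``:         substrate_uM, inhibitor_uM, enzyme_scale, velocity
- ``progress.csv``:      condition_id, t_s, od290
- ``dose_response.csv``: inhibitor_uM, relative_activity_pct
- ``titration.csv``:     temperature_K, addition_index, quencher_uM,
                         f_measured, a_ex, a_em
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .tables import DoseResponse, ProgressCurve, RateTable, TitrationSeries

__all__ = [
    "write_rates",
    "read_rates",
    "write_progress",
    "read_progress",
    "write_dose_response",
    "read_dose_response",
    "write_titrations",
    "read_titrations",
    "write_json",
    "read_json",
    "jsonable",
]


def write_rates(table: RateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_rates(path: str | Path) -> RateTable:
    return RateTable.from_frame(pd.read_csv(path))


def write_progress(curves: list[ProgressCurve], path: str | Path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False
    )


def read_progress(path: str | Path) -> list[ProgressCurve]:
    frame = pd.read_csv(path)
    curves = []
    for cid, grp in frame.groupby("condition_id", sort=False):
        curves.append(
            ProgressCurve(
                condition_id=str(cid),
                t=grp["t_s"].to_numpy(),
                od=grp["od290"].to_numpy(),
            )
        )
    return curves


def write_dose_response(d: DoseResponse, path: str | Path) -> None:
    d.to_frame().to_csv(path, index=False)


def read_dose_response(path: str | Path) -> DoseResponse:
    return DoseResponse.from_frame(pd.read_csv(path))


def write_titrations(series: list[TitrationSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False
    )


def read_titrations(path: str | Path) -> list[TitrationSeries]:
    frame = pd.read_csv(path)
    return [
        TitrationSeries.from_frame(grp)
        for _, grp in frame.groupby("temperature_K", sort=True)
    ]


def jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy, inf) to JSON types.

    Infinities become the strings "inf"/"-inf" so the output is strict
    JSON; NaN becomes null.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return None
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(jsonable(obj), indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text(encoding="utf-8"))
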