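"""CSV readers/writers for frames, anthropometrics, features and results.

Frame dialect: one row per frame with ``subject_id``, ``round_id``,
``activity`` and 200 pressure columns ``p_{r}_{c}`` in row-major order
(r in 0..19, c in 0..9).  This is the package's own documented dialect;
loaders for other dialects can be plugged in by converting to
:class:`~smartsleeve.types.RawFrame` lists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GRID_COLS, GRID_ROWS, EvalResult, RawFrame

logger = logging.getLogger(__name__)

PRESSURE_COLUMNS = [
    f"p_{r}_{c}" for r in range(GRID_ROWS) for c in range(GRID_COLS)
]
LABEL_COLUMNS = ["subject_id", "round_id", "activity"]


def frames_to_table(frames: list[RawFrame]) -> pd.DataFrame:
    """Flatten frames into the tabular dialect (one row per frame)."""
    rows = []
    for f in frames:
        row = {
            "subject_id": f.subject_id,
            "round_id": f.round_id,
            "activity": f.activity,
        }
        row.update(zip(PRESSURE_COLUMNS, f.values.ravel()))
        rows.append(row)
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + PRESSURE_COLUMNS)


def write_frames(path: str | Path, frames: list[RawFrame]) -> None:
    frames_to_table(frames).to_csv(path, index=False)


def read_frames(path: str | Path) -> list[RawFrame]:
    """Read frames from CSV; malformed content raises with detail.

    An empty file (header only) returns an empty list with a warning.
    """
    table = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS + PRESSURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    if table.empty:
        logger.warning("%s contains no frames", path)
        return []
    pressures = table[PRESSURE_COLUMNS]
    bad = pressures.map(lambda v: not np.isreal(v) or pd.isna(v)).any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()
        raise ValueError(f"{path}: non-numeric pressure cells at lines {lines[:10]}")
    values = pressures.to_numpy(dtype=float)
    if (values < 0).any():
        lines = (np.nonzero((values < 0).any(axis=1))[0] + 2).tolist()
        raise ValueError(f"{path}: negative pressures at lines {lines[:10]}")
    return [
        RawFrame(
            values=values[i].reshape(GRID_ROWS, GRID_COLS),
            subject_id=int(table["subject_id"].iloc[i]),
            round_id=int(table["round_id"].iloc[i]),
            activity=str(table["activity"].iloc[i]),
        )
        for i in range(len(table))
    ]


def write_anthropometrics(path: str | Path, anthro: pd.DataFrame) -> None:
    anthro.to_csv(path, index=False)


def read_anthropometrics(path: str | Path) -> pd.DataFrame:
    anthro = pd.read_csv(path)
    required = {"subject_id", "forearm_length_cm", "biceps_circumference_cm"}
    missing = required - set(anthro.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return anthro


def write_features(path: str | Path, features: pd.DataFrame) -> None:
    """Write a feature table (stable header order) as CSV."""
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results(path: str | Path, results: list[EvalResult]) -> None:
    """Serialize evaluation results as JSON (confusion matrices included)."""
    payload = []
    for r in results:
        d = asdict(r)
        if r.confusion is not None:
            d["confusion"] = np.asarray(r.confusion).tolist()
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2))
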