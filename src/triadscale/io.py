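"""Plain-text file formats for designs, blocks, responses, and models.

All tabular artifacts are CSV with explicit headers; models and run
metadata are JSON.  Readers validate rather than coerce: a malformed or
internally inconsistent row aborts with its row number (counting the
header as line 1) instead of being silently dropped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Block, Triad, TriadDesign
from .models import RESPONSE_COLUMNS, ScalingModel, responses_to_frame

__all__ = [
    "read_design",
    "write_design",
    "read_blocks",
    "write_blocks",
    "read_responses",
    "write_responses",
    "load_model",
    "save_model",
]

logger = logging.getLogger("triadscale")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def write_design(design: TriadDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path) -> TriadDesign:
    frame = pd.read_csv(path)
    _require_columns(frame, ["standard", "d1", "d2"], path)
    triads = tuple(
        Triad(float(r.standard), float(r.d1), float(r.d2))
        for r in frame.itertuples(index=False)
    )
    return TriadDesign(triads=triads, provenance={"source": str(path)})


def write_blocks(blocks: list[Block], path) -> None:
    rows = []
    for block in blocks:
        for triad, side in zip(block.triads, block.side_dark):
            rows.append(
                {
                    "standard": triad.standard,
                    "d1": triad.d1,
                    "d2": triad.d2,
                    "block": block.index,
                    "side_dark": side,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_blocks(path) -> list[Block]:
    frame = pd.read_csv(path)
    _require_columns(frame, ["standard", "d1", "d2", "block", "side_dark"], path)
    blocks = []
    for index, group in frame.groupby("block", sort=True):
        blocks.append(
            Block(
                index=int(index),
                triads=tuple(
                    Triad(float(r.standard), float(r.d1), float(r.d2))
                    for r in group.itertuples(index=False)
                ),
                side_dark=tuple(str(s) for s in group["side_dark"]),
            )
        )
    return blocks


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_bool(value, row: int, column: str, path):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise ValueError(f"{path}: row {row}: non-boolean value {value!r} in column {column!r}")
    return _BOOL_MAP[key]


def write_responses(responses, path, meta: dict | None = None) -> None:
    """Write a response table; optional metadata goes to a JSON sidecar.

    The sidecar (``<path>.meta.json``) records seeds and generating
    parameters so a simulated dataset can be regenerated exactly.
    """
    frame = responses_to_frame(responses)
    frame.to_csv(path, index=False)
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_responses(path) -> pd.DataFrame:
    """Read and validate a response table.

    The ``correct`` flag is recomputed from ``chose_dark`` and the offsets
    and cross-checked against the stored column; any disagreement, missing
    column, or non-numeric field raises with the offending row number.
    A header-only file yields an empty table with a logged warning.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, RESPONSE_COLUMNS, path)
    if len(frame) == 0:
        logger.warning("%s: response file contains a header but no rows", path)
        return frame
    for col in ("standard", "d1", "d2"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: row {row}: non-numeric value in column {col!r}")
        frame[col] = numeric.astype(float)
    for col in ("chose_dark", "correct"):
        frame[col] = [
            _parse_bool(v, i + 2, col, path) for i, v in enumerate(frame[col])
        ]
    expected = frame["chose_dark"] == (frame["d1"] > frame["d2"])
    mismatch = frame["correct"] != expected
    if mismatch.any():
        row = int(mismatch.idxmax()) + 2
        raise ValueError(
            f"{path}: row {row}: stored correct flag contradicts chose_dark and d1/d2"
        )
    frame["participant"] = frame["participant"].astype(str)
    return frame[RESPONSE_COLUMNS]


def save_model(model: ScalingModel, path) -> None:
    """Serialize a model to JSON (round-trip stable to float precision)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> ScalingModel:
    return ScalingModel.from_dict(json.loads(Path(path).read_text()))
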