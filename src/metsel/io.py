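"""CSV readers and writers for plot-level trial data.

Two dialects: long (``accession,year,block,column,trait,value``) and wide
(one column per trait after the four design factors).  CSV is the sole
interchange format; a JSON "truth" sidecar can record generating parameters
next to simulated datasets.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LONG_COLUMNS, TrialData, TrialDataError

__all__ = ["read_trial", "write_trial", "write_truth"]


def read_trial(path: str | Path, dialect: str = "long") -> TrialData:
    """Read a plot-level CSV in either dialect into a :class:`TrialData`.

    Errors (missing columns, duplicate plot keys, non-numeric values) carry
    the offending key or row so malformed files are diagnosable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    try:
        if dialect == "long":
            return TrialData(df)
        if dialect == "wide":
            return TrialData.from_wide(df)
    except TrialDataError as err:
        raise TrialDataError(f"{path}: {err}") from err
    raise ValueError(f"unknown dialect {dialect!r} (use 'long' or 'wide')")


def write_trial(data: TrialData, path: str | Path, dialect: str = "long") -> Path:
    """Write plot-level data as CSV in the requested dialect."""
    path = Path(path)
    if dialect == "long":
        data.long[LONG_COLUMNS].to_csv(path, index=False)
    elif dialect == "wide":
        data.to_wide().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_truth(params: dict, path: str | Path) -> Path:
    """Record generating parameters of a simulated dataset as JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True))
    return path
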