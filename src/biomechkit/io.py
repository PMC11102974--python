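"""Readers and writers for tabular time-series files.

Two dialects are supported:

* plain delimited text with a one-line header of channel labels and a
  ``time`` column in seconds (CSV/TSV, pandas-readable);
* OpenSim-style MOT/STO files: a free-form header terminated by
  ``endheader``, then a tab-delimited table whose first column is time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_signal import SampledSignal
from .errors import InvalidParameterError

__all__ = ["read_timeseries", "write_timeseries", "read_mot", "frame_to_signals"]


def _infer_rate(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise InvalidParameterError("time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise InvalidParameterError("time column is not uniformly sampled")
    return 1.0 / float(np.mean(dt))


def frame_to_signals(df: pd.DataFrame, units: dict[str, str] | None = None) -> dict[str, SampledSignal]:
    """Turn a time-indexed DataFrame (column ``time`` in s) into signals."""
    if "time" not in df.columns:
        raise InvalidParameterError("expected a 'time' column in seconds")
    t = df["time"].to_numpy(dtype=float)
    rate = _infer_rate(t)
    units = units or {}
    return {
        col: SampledSignal(df[col].to_numpy(dtype=float), rate_hz=rate,
                           units=units.get(col, ""), label=col, t0_s=float(t[0]))
        for col in df.columns if col != "time"
    }


def read_timeseries(path: str | Path, sep: str = ",") -> dict[str, SampledSignal]:
    """Read a delimited text file (header row + ``time`` column) as signals."""
    df = pd.read_csv(path, sep=sep)
    return frame_to_signals(df)


def write_timeseries(path: str | Path, signals: dict[str, SampledSignal], sep: str = ",") -> None:
    """Write signals sharing one rate and start time to delimited text."""
    rates = {round(s.rate_hz, 9) for s in signals.values()}
    lengths = {s.n for s in signals.values()}
    if len(rates) != 1 or len(lengths) != 1:
        raise InvalidParameterError("all channels must share rate and length")
    first = next(iter(signals.values()))
    df = pd.DataFrame({"time": first.time_s()})
    for name, sig in signals.items():
        df[name] = sig.samples
    df.to_csv(path, sep=sep, index=False)


def read_mot(path: str | Path) -> dict[str, SampledSignal]:
    """Read an OpenSim-style MOT/STO file (header ... ``endheader``, table)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            start = i + 1
            break
    else:
        raise InvalidParameterError(f"{path}: no 'endheader' line found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[start:])), sep=r"\s+")
    df = df.rename(columns={df.columns[0]: "time"})
    return frame_to_signals(df)
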