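"""Uniformly sampled scalar signals and their plain-text interchange format.

A :class:`TimeSeries` is the package's basic container: an ordered vector of
real samples (in microvolts, the natural scale for scalp EEG) together with
its sampling rate.  Signals travel between runs as a one-column CSV
(``value_uV``) whose leading comment line carries the sampling rate
(``# fs_hz=200.0``); a file without the rate is rejected rather than guessed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_series_csv", "write_series_csv"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like of float
        Samples, in microvolts.  At least two samples are required.
    fs : float
        Sampling rate in Hz; must be positive.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"expected a 1-D sample vector, got shape {values.shape}")
        if values.size < 2:
            raise ValueError(f"need at least 2 samples, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("samples must be finite")
        fs = float(self.fs)
        if not np.isfinite(fs) or fs <= 0:
            raise ValueError(f"sampling rate must be positive and finite, got {fs}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fs", fs)

    @property
    def n(self) -> int:
        """Number of samples N."""
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (N / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.n) / self.fs

    def __len__(self) -> int:
        return self.n

    def scaled(self, c: float) -> "TimeSeries":
        """Return a copy with every sample multiplied by ``c``."""
        return TimeSeries(self.values * float(c), self.fs)


def write_series_csv(series: TimeSeries, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a series as one-column CSV with the sampling rate in a comment header."""
    header = f"# fs_hz={series.fs!r}\nvalue_uV\n"
    body = "\n".join(repr(float(v)) for v in series.values)
    text = header + body + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_series_csv(path: str | os.PathLike | io.TextIOBase) -> TimeSeries:
    """Read a series written by :func:`write_series_csv`.

    Raises
    ------
    ValueError
        If the ``# fs_hz=`` header line is absent or malformed, or the CSV
        lacks a ``value_uV`` column.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    fs: float | None = None
    data_lines: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            comment = stripped.lstrip("#").strip()
            if comment.startswith("fs_hz="):
                try:
                    fs = float(comment.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(f"malformed sampling-rate header: {stripped!r}") from exc
        elif stripped:
            data_lines.append(line)
    if fs is None:
        raise ValueError("missing '# fs_hz=<float>' header: sampling rate is required")
    frame = pd.read_csv(io.StringIO("\n".join(data_lines)), float_precision="round_trip")
    if "value_uV" not in frame.columns:
        raise ValueError(f"expected a 'value_uV' column, found {list(frame.columns)}")
    return TimeSeries(frame["value_uV"].to_numpy(dtype=float), fs)
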