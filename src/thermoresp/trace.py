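"""Uniformly sampled single-channel time series.

All recorded and simulated signals in this package — nasal temperature,
chest movement/diameter, lick vibration — are carried as :class:`SampledTrace`
objects: a value array plus a sampling rate, start time, units and label.
Traces round-trip through a small commented-header CSV dialect so that
sessions can be exchanged as plain text.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SampledTrace", "read_trace_csv", "write_trace_csv"]


@dataclass
class SampledTrace:
    """A uniformly sampled signal.

    Sample ``i`` is taken at time ``t0 + i / fs`` seconds.

    Parameters
    ----------
    values : ndarray
        Signal samples; must be finite.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    units : str
        Physical units of the samples (e.g. ``"degC"``).
    label : str
        Channel name (e.g. ``"nasal_temperature"``).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (len(self.values) - 1) / self.fs if len(self.values) else 0.0

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self.values)) / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index to time ``t`` (clipped to the trace)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), len(self.values) - 1)

    def with_values(self, values: np.ndarray) -> "SampledTrace":
        return replace(self, values=np.asarray(values, dtype=float))


_HEADER_RE = re.compile(r"#\s*fs_hz=([^,]+),\s*units=([^,]*),\s*t0=([^,\s]+)")


def write_trace_csv(trace: SampledTrace, path: str | Path) -> None:
    """Write a trace as CSV with a ``# fs_hz=..., units=..., t0=...`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={trace.fs}, units={trace.units}, t0={trace.t0}\n")
        pd.DataFrame({"value": trace.values}).to_csv(fh, index=False)


def read_trace_csv(path: str | Path, label: str = "") -> SampledTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header)
        if m is None:
            raise ValueError(
                f"{path}: expected header '# fs_hz=<float>, units=<str>, t0=<float>', "
                f"got {header!r}"
            )
        fs, units, t0 = float(m.group(1)), m.group(2).strip(), float(m.group(3))
        df = pd.read_csv(io.StringIO(fh.read()))
    if "value" not in df.columns:
        raise ValueError(f"{path}: missing 'value' column")
    return SampledTrace(df["value"].to_numpy(float), fs=fs, t0=t0, units=units,
                        label=label or path.stem)
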