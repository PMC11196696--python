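"""Reading and writing vibration traces, walk metadata, and gait reports.

On-disk conventions for the whole package:

* Trace CSV, narrow form: header ``time,amplitude`` — one sensor per file.
* Trace CSV, wide form: header ``time,<id1>,<id2>,...`` — one amplitude
  column per sensor, shared time base.
* Gait report CSV: flat ``key,value`` pairs with units encoded in the key
  (``step_time_s``, ``cadence_per_min``, ...); round-trips losslessly.

Times are seconds as floats. Internally all math is recording-relative;
absolute epochs, if present in the input, are kept only through ``t0``.
Amplitudes are arbitrary sensor units and are never interpreted physically —
the detection pipeline is amplitude-scale invariant by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeismicTrace",
    "WalkMetadata",
    "read_traces",
    "write_traces",
    "write_gait_report",
    "read_gait_report",
]


@dataclass
class SeismicTrace:
    """One sensor's evenly sampled amplitude series.

    Parameters
    ----------
    sensor_id : str
        Identifier of the seismograph channel.
    t0 : float
        Time of the first sample in seconds (epoch or recording-relative).
    fs : float
        Sampling rate in Hz (nominal 100 for the study hardware).
    samples : ndarray
        Ordered real amplitudes in arbitrary sensor units.
    position : tuple of float, optional
        (x, y) sensor position in metres along/across the walkway.
    """

    sensor_id: str
    t0: float
    fs: float
    samples: np.ndarray
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps ``t0 + k / fs`` (strictly increasing)."""
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) / self.fs


@dataclass
class WalkMetadata:
    """Per-walk experiment metadata.

    ``walkway_length_cm`` is the active measurement length of the reference
    walkway (488 cm for the study hardware); it anchors the spatial
    (approximated) gait parameters.
    """

    walk_id: str = "walk"
    walkway_length_cm: float = 488.0
    first_foot: str = "unknown"  # left | right | unknown
    experiment_label: str = "free"  # free | fast | normal | tug

    def __post_init__(self) -> None:
        if self.walkway_length_cm <= 0:
            raise ValueError("walkway_length_cm must be positive")
        if self.first_foot not in ("left", "right", "unknown"):
            raise ValueError(f"first_foot must be left|right|unknown, got {self.first_foot!r}")


def _infer_fs(time: np.ndarray, path: str) -> float:
    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # +2: offending row counted 1-based including the header line
        raise ValueError(
            f"{path}: timestamps not strictly increasing at data row {bad[0] + 2} "
            f"(t={time[bad[0] + 1]!r} follows t={time[bad[0]]!r})"
        )
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        warnings.warn(
            f"{path}: sample spacing varies by more than 1% from the median "
            f"({med:.6g} s); resampling required before aggregation",
            stacklevel=3,
        )
    return 1.0 / med


def read_traces(path: str, declared_fs: float | None = None) -> list[SeismicTrace]:
    """Read one or more traces from a delimited text file.

    The first column is time in seconds; every further column is one
    sensor's amplitude (column name = sensor id). The sampling rate is
    inferred from the median timestamp spacing; when ``declared_fs`` is
    given it wins over the inferred rate (a warning is issued if the two
    disagree by more than 1%).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus at least one amplitude column")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows to infer a sampling rate")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    fs = _infer_fs(time, path)
    if declared_fs is not None:
        if abs(fs - declared_fs) > 0.01 * declared_fs:
            warnings.warn(
                f"{path}: inferred rate {fs:.4g} Hz disagrees with declared "
                f"{declared_fs:.4g} Hz; using the declared rate",
                stacklevel=2,
            )
        fs = declared_fs
    t0 = float(time[0])
    return [
        SeismicTrace(sensor_id=str(col), t0=t0, fs=fs, samples=df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]


def write_traces(traces: list[SeismicTrace], path: str) -> None:
    """Write aligned traces as a wide CSV (``time,<id>,...``) at full precision."""
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n
    if any(t.n != n or t.fs != traces[0].fs or t.t0 != traces[0].t0 for t in traces):
        raise ValueError("traces must share t0, fs and length to be written wide")
    data = {"time": traces[0].times}
    for tr in traces:
        data[tr.sensor_id] = tr.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_gait_report(params, path: str) -> None:
    """Write a gait-parameter report as flat ``key,value`` CSV.

    ``params`` is any object with a ``to_dict()`` method whose keys carry
    units (as produced by :class:`seismogait.gait_analysis.GaitParameters`),
    or a plain mapping.
    """
    d = params.to_dict() if hasattr(params, "to_dict") else dict(params)
    if not d:
        raise ValueError("empty gait report")
    with open(path, "w") as fh:
        fh.write("key,value\n")
        for k, v in d.items():
            fh.write(f"{k},{v!r}\n")


def read_gait_report(path: str) -> dict[str, float]:
    """Read a ``key,value`` gait report back into a dict of floats."""
    df = pd.read_csv(path)
    out: dict[str, float] = {}
    for k, v in zip(df["key"], df["value"]):
        out[str(k)] = float(v)
    return out
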