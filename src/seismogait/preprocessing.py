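"""Per-sensor normalization, temporal alignment, and rolling-maximum aggregation.

Stage 1 of the step-extraction pipeline: each sensor trace is min-max scaled
to [0, 1] and mean-subtracted, all traces are resampled onto a common time
grid, and the sensors are combined with a rolling maximum. Taking the maximum
across sensors counteracts per-sensor amplitude damping — whichever sensor is
closest to the footfall dominates the composite signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .signal_io import SeismicTrace

__all__ = ["AggregatedSignal", "detrend_normalize", "align", "aggregate_max"]


@dataclass
class AggregatedSignal:
    """Composite signal on the common aligned grid.

    ``samples`` lie in roughly [-1, 1]: the per-sensor min-max normalization
    maps to [0, 1] and the subsequent mean subtraction shifts the range.
    """

    fs: float
    t0: float
    samples: np.ndarray
    source_ids: tuple[str, ...]
    agg_window: float

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def detrend_normalize(trace: SeismicTrace) -> SeismicTrace:
    """Min-max scale a trace to [0, 1], then subtract the scaled mean.

    The output has zero mean and is invariant to positive affine transforms
    of the input (gain and offset differences between sensors vanish). A
    constant trace has no scale to normalize by and maps to all zeros with
    a warning.
    """
    x = trace.samples
    if x.size < 2:
        raise ValueError("detrend_normalize needs at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn(
            f"trace {trace.sensor_id!r} is constant; normalized to zeros", stacklevel=2
        )
        y = np.zeros_like(x)
    else:
        y = (x - lo) / (hi - lo)
        y = y - y.mean()
    return SeismicTrace(
        sensor_id=trace.sensor_id, t0=trace.t0, fs=trace.fs, samples=y, position=trace.position
    )


def align(traces: list[SeismicTrace], fs: float | None = None) -> list[SeismicTrace]:
    """Resample traces onto a common grid over the intersection of time ranges.

    All traces must overlap in time and agree on the sampling rate to within
    1%. Resampling is linear interpolation at the nominal rate ``fs``
    (default: rate of the first trace); for traces already on the grid this
    is the identity.
    """
    if not traces:
        raise ValueError("no traces to align")
    if fs is None:
        fs = traces[0].fs
    for tr in traces:
        if abs(tr.fs - fs) > 0.01 * fs:
            raise ValueError(
                f"trace {tr.sensor_id!r} rate {tr.fs} Hz differs from nominal {fs} Hz by >1%"
            )
    start = max(tr.t0 for tr in traces)
    end = min(tr.t_end for tr in traces)
    if end <= start:
        raise ValueError("traces have no temporal overlap")
    n = int(np.floor((end - start) * fs + 1e-9)) + 1
    grid = start + np.arange(n) / fs
    out = []
    for tr in traces:
        y = np.interp(grid, tr.times, tr.samples)
        out.append(
            SeismicTrace(sensor_id=tr.sensor_id, t0=start, fs=fs, samples=y, position=tr.position)
        )
    return out


def aggregate_max(traces: list[SeismicTrace], window: float = 0.05) -> AggregatedSignal:
    """Combine aligned traces by a rolling maximum.

    At each sample the output is the maximum over all sensors and over all
    samples within ``window / 2`` seconds. ``window = 0`` reduces to the
    pointwise maximum across sensors. The rolling window uses a shrinking
    support at the edges (edge replication of the pointwise max, which for
    a maximum is equivalent to clipping the window in-bounds).
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    if window < 0:
        raise ValueError("window must be >= 0")
    n = traces[0].n
    fs = traces[0].fs
    t0 = traces[0].t0
    if any(tr.n != n or tr.fs != fs or abs(tr.t0 - t0) > 1e-9 for tr in traces):
        raise ValueError("traces must be aligned (same grid) before aggregation")
    pointwise = np.max(np.vstack([tr.samples for tr in traces]), axis=0)
    half = int(np.floor(window * fs / 2 + 1e-9))
    if half > 0:
        pointwise = maximum_filter1d(pointwise, size=2 * half + 1, mode="nearest")
    return AggregatedSignal(
        fs=fs,
        t0=t0,
        samples=pointwise,
        source_ids=tuple(tr.sensor_id for tr in traces),
        agg_window=window,
    )
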