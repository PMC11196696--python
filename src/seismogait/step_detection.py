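"""Smoothing filters and constrained peak detection for footstep extraction.

Stages 3-4 of the pipeline: the CTF output is smoothed with a Hamming
window (boosts peaks while attenuating residual jitter) and a rectangular
moving average (merges closely adjoining double peaks from heel/toe
strikes), both with a 100 ms radius. The smoothed signal is min-max
renormalized and footsteps are the local maxima whose height reaches the
95th percentile of the normalized amplitudes, greedily pruned so that no
two surviving peaks are closer than 50 ms.

Only peak timestamps leave this module; amplitudes never reach the gait
math, which makes the whole pipeline invariant to amplitude scaling of
the input traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import find_peaks

from .morphology import StructuringElement, ctf
from .preprocessing import aggregate_max, align, detrend_normalize
from .signal_io import SeismicTrace

__all__ = [
    "DetectorConfig",
    "FootstepEvents",
    "hamming_smooth",
    "rect_filter",
    "minmax_normalize",
    "detect_peaks",
    "extract_footsteps",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detector constraints (defaults are the study's constants)."""

    min_distance: float = 0.05  # s, refractory distance between peaks
    height_percentile: float = 95.0  # % of min-max normalized amplitudes
    hamming_radius: float = 0.1  # s
    rect_radius: float = 0.1  # s
    renormalize: bool = True  # re-min-max-normalize after filtering

    def __post_init__(self) -> None:
        if self.min_distance <= 0 or self.hamming_radius <= 0 or self.rect_radius <= 0:
            raise ValueError("all radii/distances must be positive")
        if not 0 < self.height_percentile < 100:
            raise ValueError("height_percentile must be in (0, 100)")


@dataclass
class FootstepEvents:
    """Ordered initial-contact timestamps, optionally foot-labelled."""

    times: np.ndarray
    feet: list[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.feet is not None and len(self.feet) != self.times.size:
            raise ValueError("feet labels must match number of events")

    @property
    def n(self) -> int:
        return self.times.size


def _unit_kernel(window: np.ndarray) -> np.ndarray:
    return window / window.sum()


def _smooth(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if kernel.size > x.size:
        raise ValueError(f"kernel length {kernel.size} exceeds signal length {x.size}")
    # symmetric kernels: correlation == convolution; reflect keeps length
    return convolve1d(x, kernel, mode="reflect")


def hamming_smooth(signal, radius: float, fs: float) -> np.ndarray:
    """Convolve with a unit-sum Hamming window of length ``2*round(radius*fs)+1``.

    Reflect-padded so the output length equals the input length; DC gain is
    exactly 1 (constants pass through unchanged).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _smooth(signal, _unit_kernel(np.hamming(2 * int(round(radius * fs)) + 1)))


def rect_filter(signal, radius: float, fs: float) -> np.ndarray:
    """Moving average with a unit-sum rectangular kernel, reflect-padded.

    Two peaks closer than the kernel support merge into one local maximum,
    eliminating double peaks from a single footfall.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _smooth(signal, _unit_kernel(np.ones(2 * int(round(radius * fs)) + 1)))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant signal maps to zeros with a warning."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant signal; normalization degenerate (all zeros)", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def detect_peaks(
    signal, fs: float, t0: float = 0.0, cfg: DetectorConfig | None = None, source: str = ""
) -> FootstepEvents:
    """Thresholded, distance-constrained peak detection on a normalized signal.

    Candidates are local maxima strictly greater than both neighbours
    (plateaus resolve to the plateau midpoint). A candidate survives if its
    height reaches the ``height_percentile``-th percentile of the min-max
    normalized amplitude distribution (taken over all samples), and the
    survivors are greedily pruned highest-first (earlier peak kept on ties)
    so no two are closer than ``min_distance`` seconds.
    """
    cfg = cfg or DetectorConfig()
    xn = minmax_normalize(signal)
    if not np.any(xn):
        return FootstepEvents(times=np.empty(0), source=source)
    idx, _ = find_peaks(xn)  # strict local maxima; plateau midpoint (rounded down)
    thr = np.percentile(xn, cfg.height_percentile)
    idx = idx[xn[idx] >= thr]
    if idx.size == 0:
        return FootstepEvents(times=np.empty(0), source=source)
    # greedy pruning: highest first, earlier index wins ties
    order = np.lexsort((idx, -xn[idx]))
    min_gap = cfg.min_distance * fs - 1e-9
    kept: list[int] = []
    for i in idx[order]:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(int(i))
    kept.sort()
    return FootstepEvents(times=t0 + np.asarray(kept) / fs, source=source)


def extract_footsteps(
    traces: list[SeismicTrace],
    cfg: DetectorConfig | None = None,
    se: StructuringElement | None = None,
    agg_window: float = 0.05,
    source: str = "",
) -> FootstepEvents:
    """Full step-extraction pipeline from raw traces to footstep events.

    Composition: per-trace normalize/detrend -> temporal alignment ->
    rolling-maximum aggregation -> compound top-hat filter -> Hamming
    smoothing -> rectangular filter -> renormalization -> constrained
    peak detection. Deterministic for fixed inputs and configuration.
    """
    if not traces:
        raise ValueError("need at least one trace")
    cfg = cfg or DetectorConfig()
    normed = [detrend_normalize(tr) for tr in traces]
    aligned = align(normed)
    agg = aggregate_max(aligned, window=agg_window)
    if se is None:
        se = StructuringElement(radius=0.2, fs=agg.fs, shape="spherical")
    elif se.fs != agg.fs:
        se = StructuringElement(radius=se.radius, fs=agg.fs, shape=se.shape, height=se.height)
    filtered = ctf(agg.samples, se).samples
    filtered = hamming_smooth(filtered, cfg.hamming_radius, agg.fs)
    filtered = rect_filter(filtered, cfg.rect_radius, agg.fs)
    if cfg.renormalize:
        filtered = minmax_normalize(filtered)
    return detect_peaks(filtered, fs=agg.fs, t0=agg.t0, cfg=cfg, source=source)
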