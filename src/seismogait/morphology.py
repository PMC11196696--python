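"""1-D grayscale morphology and the compound top-hat filter (CTF).

The CTF is the noise-attenuation core of the step-extraction pipeline: the
signal minus the average of its morphological opening and closing. Opening
(erosion then dilation) removes sharp positive spikes; closing (dilation
then erosion) fills sharp dips; their average tracks the slowly varying
baseline, so subtracting it suppresses low-frequency floor vibration while
preserving impulsive footstep transients. Unlike a bandpass filter, this is
robust to footstep energy and noise overlapping in frequency.

The structuring element (SE) is "spherical": a semicircular height profile
whose radius in time (default 200 ms, the duration of a single footstep
during normal walking) sets the scale separating transients from baseline.
A flat SE is provided as an option — detection consumes only peak
timestamps, not heights, and the flat variant is the classical rolling
min/max.

Boundary policy: the min/max are taken over the in-bounds part of the SE
support (a shrinking window). No padding values are fabricated, so the
first and last footfalls of a walk are not distorted by artificial extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructuringElement",
    "MorphResult",
    "erode",
    "dilate",
    "opening",
    "closing",
    "ctf",
]


@dataclass(frozen=True)
class StructuringElement:
    """Discretized symmetric structuring element.

    ``heights`` has odd length ``2 * round(radius * fs) + 1`` with the
    origin at the centre. For the spherical shape
    ``heights[k] = height * sqrt(1 - (k / (radius * fs))**2)``;
    for the flat shape all heights are zero.
    """

    radius: float = 0.2
    fs: float = 100.0
    shape: str = "spherical"  # spherical | flat
    height: float = 0.2
    heights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.fs <= 0:
            raise ValueError("radius and fs must be positive")
        if self.shape not in ("spherical", "flat"):
            raise ValueError(f"shape must be spherical|flat, got {self.shape!r}")
        half = int(round(self.radius * self.fs))
        k = np.arange(-half, half + 1)
        if self.shape == "flat" or half == 0:
            h = np.zeros(k.size)
        else:
            h = self.height * np.sqrt(np.maximum(0.0, 1.0 - (k / (self.radius * self.fs)) ** 2))
        object.__setattr__(self, "heights", h)

    def __len__(self) -> int:
        return self.heights.size

    @property
    def half(self) -> int:
        return self.heights.size // 2


@dataclass
class MorphResult:
    """Output of a morphological operator; same length as its input."""

    samples: np.ndarray
    op_label: str


def _check(x: np.ndarray, se: StructuringElement) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("signal must be a non-empty 1-D array")
    if len(se) > x.size:
        raise ValueError(f"SE length {len(se)} exceeds signal length {x.size}")
    return x


def _windows(x: np.ndarray, L: int, pad: float) -> np.ndarray:
    r = L // 2
    xp = np.concatenate([np.full(r, pad), x, np.full(r, pad)])
    return np.lib.stride_tricks.sliding_window_view(xp, L)


def erode(signal, se: StructuringElement) -> MorphResult:
    """Grayscale erosion: ``out[i] = min_k signal[i+k] - heights[k]``.

    The minimum runs over the in-bounds SE support (+inf padding is never
    selected by a min against finite values).
    """
    x = _check(signal, se)
    w = _windows(x, len(se), np.inf)
    return MorphResult((w - se.heights).min(axis=1), "erosion")


def dilate(signal, se: StructuringElement) -> MorphResult:
    """Grayscale dilation: ``out[i] = max_k signal[i-k] + heights[k]``."""
    x = _check(signal, se)
    w = _windows(x, len(se), -np.inf)
    # w[i][j] = x[i - half + j]; with k = half - j this is x[i-k] + heights[k]
    return MorphResult((w + se.heights[::-1]).max(axis=1), "dilation")


def opening(signal, se: StructuringElement) -> MorphResult:
    """Erosion followed by dilation; removes positive spikes narrower than the SE.

    Anti-extensive (``opening(x) <= x`` pointwise) and idempotent.
    """
    return MorphResult(dilate(erode(signal, se).samples, se).samples, "opening")


def closing(signal, se: StructuringElement) -> MorphResult:
    """Dilation followed by erosion; fills dips narrower than the SE.

    Extensive (``closing(x) >= x`` pointwise) and idempotent.
    """
    return MorphResult(erode(dilate(signal, se).samples, se).samples, "closing")


def ctf(signal, se: StructuringElement) -> MorphResult:
    """Compound top-hat filter: signal minus the opening/closing average."""
    x = _check(signal, se)
    baseline = 0.5 * (opening(x, se).samples + closing(x, se).samples)
    return MorphResult(x - baseline, "ctf")
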