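"""Spatiotemporal gait parameters and TUG timings from footstep events.

All quantities derive purely from the ordered initial-contact timestamps
``t_1 < ... < t_n`` of one ambulation pass and the known active walkway
length. With step intervals ``D_i = t_{i+1} - t_i``:

* step time (s)        = mean(D_i)                 — contralateral interval
* cycle time (s)       = mean(t_{i+2} - t_i)       — ipsilateral interval
* ambulation time (s)  = sum(D_i) = t_n - t_1
* cadence (1/min)      = 60 * n / ambulation time
* velocity (cm/s)      = walkway length / ambulation time
* step length (cm)     = mean(velocity * D_i) = velocity * step time

The temporal parameters are exact; velocity and step length are
approximations that lean on the walkway length because a 100 Hz sampling
rate is too coarse for per-step seismic localization.

The TUG (timed up-and-go) duration is the interval from the first to the
last detected peak: the initial peak of the seismic signal corresponds to
rising from the chair, the last to sitting back down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal_io import WalkMetadata
from .step_detection import FootstepEvents

__all__ = ["GaitParameters", "TugTiming", "assign_feet", "compute_gait_parameters", "compute_tug"]


@dataclass
class GaitParameters:
    """The six per-walk gait parameters (NaN where unavailable)."""

    step_time_s: float
    cycle_time_s: float
    ambulation_time_s: float
    cadence_per_min: float
    velocity_cm_s: float
    step_length_cm: float
    n_steps: int

    def to_dict(self) -> dict[str, float]:
        return {
            "step_time_s": self.step_time_s,
            "cycle_time_s": self.cycle_time_s,
            "ambulation_time_s": self.ambulation_time_s,
            "cadence_per_min": self.cadence_per_min,
            "velocity_cm_s": self.velocity_cm_s,
            "step_length_cm": self.step_length_cm,
            "n_steps": float(self.n_steps),
        }


@dataclass
class TugTiming:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TUG end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def assign_feet(events: FootstepEvents, first_foot: str) -> FootstepEvents:
    """Label events with strictly alternating feet starting from ``first_foot``.

    Footedness is not inferred from the signal; the first foot comes from an
    external observation (camera). ``first_foot='unknown'`` leaves the labels
    unset — they are presentational, and cycle time is computed on
    every-other-event intervals regardless.
    """
    if events.n == 0:
        raise ValueError("no events to label")
    if first_foot == "unknown":
        return replace(events, feet=None)
    if first_foot not in ("left", "right"):
        raise ValueError(f"first_foot must be left|right|unknown, got {first_foot!r}")
    other = "right" if first_foot == "left" else "left"
    feet = [first_foot if k % 2 == 0 else other for k in range(events.n)]
    return replace(events, feet=feet)


def compute_gait_parameters(events: FootstepEvents, meta: WalkMetadata) -> GaitParameters:
    """Compute the six gait parameters for one walk.

    Requires at least 2 events; with exactly 2, cycle time and step length
    are reported as NaN (a single interval supports neither the ipsilateral
    interval nor a meaningful per-step length average).
    """
    t = events.times
    n = t.size
    if n < 2:
        raise ValueError(f"insufficient events: need >= 2, got {n}")
    d = np.diff(t)
    step_time = float(d.mean())
    ambulation = float(t[-1] - t[0])
    cadence = 60.0 * n / ambulation
    velocity = meta.walkway_length_cm / ambulation
    if n >= 3:
        cycle_time = float((t[2:] - t[:-2]).mean())
        step_length = float((velocity * d).mean())  # == velocity * step_time
    else:
        cycle_time = math.nan
        step_length = math.nan
    return GaitParameters(
        step_time_s=step_time,
        cycle_time_s=cycle_time,
        ambulation_time_s=ambulation,
        cadence_per_min=cadence,
        velocity_cm_s=velocity,
        step_length_cm=step_length,
        n_steps=n,
    )


def compute_tug(events: FootstepEvents) -> TugTiming:
    """TUG timing: first detected peak to last detected peak."""
    if events.n < 2:
        raise ValueError(f"insufficient events for TUG timing: need >= 2, got {events.n}")
    return TugTiming(start=float(events.times[0]), end=float(events.times[-1]))
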