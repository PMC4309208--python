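"""Loading protocols: piecewise ramp / hold / sinusoid pressure histories.

A protocol is an ordered list of segments, each with its own fixed time
step.  The applied quantity is the nominal compressive pressure on the
superior surface in MPa; the solver converts it to a platen force.

The standard cyclic test applies a preload (linear ramp 0 -> 0.1 MPa over
60 s, then a 10 min hold at 0.1 MPa) followed by sinusoidal cycles between
0.1 and 0.8 MPa at one or more frequencies.  A frequency sweep runs its
segments consecutively in ascending frequency, carrying the consolidation
state from one segment into the next, as in a sweep test on a material
testing machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Ramp",
    "Hold",
    "Sinusoid",
    "LoadProtocol",
    "preload_protocol",
    "sweep_protocol",
    "cyclic_protocol",
    "SWEEP_FREQUENCIES_HZ",
]

#: in-vitro sweep frequencies (Hz); the experimental rig also ran 10 Hz
SWEEP_FREQUENCIES_HZ = (0.01, 0.063, 0.1, 0.63, 1.0, 6.3)

#: minimum number of time steps resolving one sinusoid period
MIN_STEPS_PER_CYCLE = 10


@dataclass(frozen=True)
class Ramp:
    """Linear pressure ramp from p_start to p_end (MPa) over duration (s)."""

    p_start: float
    p_end: float
    duration: float
    dt: float

    def pressure(self, t_local: np.ndarray) -> np.ndarray:
        frac = np.asarray(t_local) / self.duration
        return self.p_start + (self.p_end - self.p_start) * frac


@dataclass(frozen=True)
class Hold:
    """Constant pressure p (MPa) held for duration (s)."""

    p: float
    duration: float
    dt: float

    def pressure(self, t_local: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(t_local, dtype=float), self.p)


@dataclass(frozen=True)
class Sinusoid:
    """Sinusoidal cycling between p_min and p_max (MPa) at frequency (Hz).

    The pressure starts at p_min (continuous with a preceding hold at the
    same level) and first rises to p_max:
    p(t) = p_min + (p_max - p_min)/2 * (1 - cos(2 pi f t)).
    """

    p_min: float
    p_max: float
    frequency: float
    duration: float
    dt: float

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def n_cycles(self) -> float:
        return self.duration * self.frequency

    def pressure(self, t_local: np.ndarray) -> np.ndarray:
        amp = 0.5 * (self.p_max - self.p_min)
        return self.p_min + amp * (1.0 - np.cos(2.0 * np.pi * self.frequency * np.asarray(t_local)))


Segment = Ramp | Hold | Sinusoid


@dataclass(frozen=True)
class LoadProtocol:
    """An ordered sequence of contiguous load segments."""

    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for seg in self.segments:
            if not seg.duration > 0:
                raise ValueError(f"segment duration must be > 0: {seg}")
            if not seg.dt > 0:
                raise ValueError(f"segment dt must be > 0: {seg}")
            n = seg.duration / seg.dt
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"segment duration {seg.duration} is not a whole number of "
                    f"steps of dt={seg.dt}"
                )
            if isinstance(seg, Sinusoid):
                if seg.p_min < 0 or seg.p_max < seg.p_min:
                    raise ValueError(f"need 0 <= p_min <= p_max: {seg}")
                if seg.dt > seg.period / MIN_STEPS_PER_CYCLE + 1e-12:
                    raise ValueError(
                        f"dt={seg.dt} too coarse for frequency {seg.frequency} Hz: "
                        f"need dt <= period/{MIN_STEPS_PER_CYCLE} = "
                        f"{seg.period / MIN_STEPS_PER_CYCLE:g} s"
                    )
            else:
                p_vals = (
                    (seg.p_start, seg.p_end) if isinstance(seg, Ramp) else (seg.p,)
                )
                if any(p < 0 for p in p_vals):
                    raise ValueError(f"pressures must be >= 0: {seg}")

    @property
    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    @property
    def n_steps(self) -> int:
        return sum(int(round(seg.duration / seg.dt)) for seg in self.segments)

    def extended(self, *segments: Segment) -> "LoadProtocol":
        return LoadProtocol(self.segments + tuple(segments))

    def step_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand to per-step arrays (times, pressures, segment index).

        Times are the step *end* times t_1 .. t_N (t_0 = 0 is the initial
        state, not included).
        """
        times, pressures, seg_idx = [], [], []
        t0 = 0.0
        for i, seg in enumerate(self.segments):
            n = int(round(seg.duration / seg.dt))
            t_local = seg.dt * np.arange(1, n + 1)
            times.append(t0 + t_local)
            pressures.append(seg.pressure(t_local))
            seg_idx.append(np.full(n, i, dtype=int))
            t0 += seg.duration
        return np.concatenate(times), np.concatenate(pressures), np.concatenate(seg_idx)


def preload_protocol(
    p_preload: float = 0.1,
    ramp_duration: float = 60.0,
    hold_duration: float = 600.0,
    dt: float = 5.0,
) -> LoadProtocol:
    """The standard preload: ramp to 0.1 MPa over 60 s, hold 10 min."""
    return LoadProtocol(
        (
            Ramp(0.0, p_preload, ramp_duration, dt),
            Hold(p_preload, hold_duration, dt),
        )
    )


def _sinusoid_dt(frequency: float, steps_per_cycle: int) -> float:
    if steps_per_cycle < MIN_STEPS_PER_CYCLE:
        raise ValueError(
            f"steps_per_cycle must be >= {MIN_STEPS_PER_CYCLE}, got {steps_per_cycle}"
        )
    return 1.0 / (frequency * steps_per_cycle)


def cyclic_protocol(
    frequency: float,
    duration: float,
    p_min: float = 0.1,
    p_max: float = 0.8,
    steps_per_cycle: int = 20,
    include_preload: bool = True,
) -> LoadProtocol:
    """Preload followed by a single-frequency cyclic segment.

    The default time resolution of 20 steps per cycle reproduces the
    standard increments (5, 0.5, 0.05, 0.005 s at 0.01, 0.1, 1, 10 Hz).
    """
    sin = Sinusoid(p_min, p_max, frequency, duration, _sinusoid_dt(frequency, steps_per_cycle))
    if include_preload:
        return preload_protocol(p_preload=p_min).extended(sin)
    return LoadProtocol((sin,))


def sweep_protocol(
    frequencies: Sequence[float] = SWEEP_FREQUENCIES_HZ,
    segment_duration: float = 300.0,
    p_min: float = 0.1,
    p_max: float = 0.8,
    steps_per_cycle: int = 20,
    include_preload: bool = True,
) -> LoadProtocol:
    """Preload followed by consecutive cyclic segments, ascending frequency."""
    freqs = sorted(frequencies)
    segs: list[Segment] = []
    for f in freqs:
        segs.append(
            Sinusoid(p_min, p_max, f, segment_duration, _sinusoid_dt(f, steps_per_cycle))
        )
    if include_preload:
        return preload_protocol(p_preload=p_min).extended(*segs)
    return LoadProtocol(tuple(segs))
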