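"""Step voltage-clamp protocols.

A protocol is an ordered list of ``(level_mV, duration_ms)`` segments.  The
first segment is the holding level used to initialise the simulation at
steady state.  Segments are left-closed/right-open in time: at a step
boundary the *new* level applies, so transients are attributed to the
segment that caused them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Protocol",
    "build_step_protocol",
    "build_iv_protocol",
]


@dataclass(frozen=True)
class Protocol:
    """A piecewise-constant command-voltage protocol."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol must have at least one segment")
        segs = tuple((float(v), float(d)) for v, d in self.segments)
        for _, d in segs:
            if not d > 0:
                raise ValueError(f"segment durations must be > 0, got {d}")
        object.__setattr__(self, "segments", segs)

    @property
    def levels(self) -> np.ndarray:
        return np.array([v for v, _ in self.segments])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.segments])

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, length = number of segments."""
        return np.cumsum(self.durations)

    @property
    def holding(self) -> float:
        """Holding level: the first segment's voltage."""
        return self.segments[0][0]

    def voltage_at(self, t: float) -> float:
        """Command voltage at time ``t`` (ms from protocol start).

        Segments are left-closed/right-open; at a boundary the later
        segment's level applies.  The final instant returns the last level.
        """
        if t < 0 or t > self.total_duration:
            raise ValueError(
                f"t={t} outside protocol duration [0, {self.total_duration}]"
            )
        starts = np.concatenate([[0.0], self.boundaries[:-1]])
        idx = int(np.searchsorted(starts, t, side="right")) - 1
        return self.segments[idx][0]

    def voltage_trace(self, t: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`voltage_at` for an array of times."""
        starts = np.concatenate([[0.0], self.boundaries[:-1]])
        idx = np.searchsorted(starts, np.asarray(t, dtype=float), side="right") - 1
        return self.levels[np.clip(idx, 0, len(self.segments) - 1)]


def build_step_protocol(
    hold: float, hold_ms: float, step: float, step_ms: float, tail_ms: float
) -> Protocol:
    """Three-segment hold → step → hold protocol.

    ``build_step_protocol(-80, 20, 50, 20, 20)`` is the large model-cell
    validation step (hold −80 mV, step to 50 mV for 20 ms, return for 20 ms).
    """
    return Protocol(((hold, hold_ms), (step, step_ms), (hold, tail_ms)))


def build_iv_protocol(
    hold: float,
    hold_ms: float,
    v_start: float,
    v_end: float,
    v_inc: float,
    step_ms: float,
    tail_ms: float | None = None,
) -> list[Protocol]:
    """One protocol per test voltage of an I-V step family.

    Test voltages run from ``v_start`` to ``v_end`` inclusive in increments
    of ``v_inc``.  Each protocol holds at ``hold`` for ``hold_ms`` then steps
    to the test voltage for ``step_ms`` (plus an optional tail back at the
    holding level).
    """
    if not v_inc > 0:
        raise ValueError("v_inc must be > 0")
    if v_end < v_start:
        raise ValueError("v_end must be >= v_start")
    n = int(round((v_end - v_start) / v_inc)) + 1
    voltages = v_start + v_inc * np.arange(n)
    protocols = []
    for v in voltages:
        segs = [(hold, hold_ms), (float(v), step_ms)]
        if tail_ms is not None:
            segs.append((hold, tail_ms))
        protocols.append(Protocol(tuple(segs)))
    return protocols


def voltage_at(protocol: Protocol, t: float) -> float:
    """Module-level alias for :meth:`Protocol.voltage_at`."""
    return protocol.voltage_at(t)
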