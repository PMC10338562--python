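"""Ergometer workload schedules.

The excitation input of the kinetics model is the workload ``P(t)`` in watts
set on the cycle ergometer.  A test protocol is an ordered list of contiguous
segments (baseline sitting, constant warm-up, incremental ramp, constant
recovery).  The incremental phase is represented as a staircase: the power is
raised by ``increment_W`` every ``step_period_s`` seconds ("step incremental
test"); a continuous linear ramp is available behind ``continuous=True`` for
protocols whose hardware ramps smoothly.

Time is measured in seconds from the start of the recording; each segment
occupies the half-open interval ``[start_s, start_s + duration_s)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ProtocolSegment",
    "WorkloadProtocol",
    "retrospective_protocol",
    "validation_protocol",
]

PHASE_KINDS = ("baseline", "warmup", "ramp", "recovery")

#: Default constant workload (W) during warm-up and recovery phases.
STANDARD_LOW_POWER_W = 50.0
#: Default ramp increment: +25 W applied every 60 s.
STANDARD_INCREMENT_W = 25.0
STANDARD_STEP_PERIOD_S = 60.0


class ProtocolError(ValueError):
    """Raised for inconsistent protocol definitions or out-of-range queries."""


@dataclass(frozen=True)
class ProtocolSegment:
    """One contiguous phase of an ergometer protocol.

    Parameters
    ----------
    start_s : float
        Segment start time (s) from recording start.
    duration_s : float or None
        Segment length in seconds; ``None`` marks an open-ended segment
        (used for ramp extension during extrapolation).
    kind : {'baseline', 'warmup', 'ramp', 'recovery'}
    power_start_W : float
        Workload at the segment start.
    increment_W : float
        Power step applied every ``step_period_s`` within a ramp; must be 0
        for constant segments.
    step_period_s : float
        Period of the staircase steps (s).
    continuous : bool
        If True the ramp rises linearly at ``increment_W / step_period_s``
        W/s instead of in discrete steps.
    """

    start_s: float
    duration_s: Optional[float]
    kind: str
    power_start_W: float
    increment_W: float = 0.0
    step_period_s: float = STANDARD_STEP_PERIOD_S
    continuous: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ProtocolError("segment duration must be positive")
        if self.power_start_W < 0:
            raise ProtocolError("power must be non-negative")
        if self.kind != "ramp" and self.increment_W != 0:
            raise ProtocolError("increment_W must be 0 outside ramp segments")
        if self.step_period_s <= 0:
            raise ProtocolError("step_period_s must be positive")

    @property
    def end_s(self) -> Optional[float]:
        if self.duration_s is None:
            return None
        return self.start_s + self.duration_s

    @property
    def open_ended(self) -> bool:
        return self.duration_s is None

    def power_at(self, t: float) -> float:
        """Workload (W) at absolute time ``t`` inside this segment."""
        dt = t - self.start_s
        if dt < 0 or (not self.open_ended and dt >= self.duration_s):
            raise ProtocolError(f"t={t} outside segment [{self.start_s}, {self.end_s})")
        if self.increment_W == 0:
            return self.power_start_W
        if self.continuous:
            return self.power_start_W + self.increment_W / self.step_period_s * dt
        return self.power_start_W + self.increment_W * math.floor(dt / self.step_period_s)


@dataclass(frozen=True)
class WorkloadProtocol:
    """A full ergometer workload schedule ``P(t)``.

    Segments must be contiguous and start at t = 0.  Evaluation is defined
    for every ``t`` in ``[0, end)``; if the last segment is open-ended the
    protocol extends to infinity.
    """

    segments: tuple[ProtocolSegment, ...]
    name: str = "protocol"
    #: Recovery power retained as metadata when a ramp is extended.
    recovery_power_W: float = STANDARD_LOW_POWER_W

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ProtocolError("protocol needs at least one segment")
        if segs[0].start_s != 0:
            raise ProtocolError("first segment must start at t=0")
        for a, b in zip(segs, segs[1:]):
            if a.open_ended:
                raise ProtocolError("only the last segment may be open-ended")
            if not math.isclose(a.end_s, b.start_s):
                raise ProtocolError("segments must be contiguous")

    @property
    def end_s(self) -> Optional[float]:
        """Protocol end time, ``None`` if open-ended."""
        return self.segments[-1].end_s

    def segment_at(self, t: float) -> ProtocolSegment:
        if t < 0:
            raise ProtocolError("t must be >= 0")
        for seg in self.segments:
            if seg.open_ended or t < seg.end_s:
                if t >= seg.start_s:
                    return seg
        raise ProtocolError(
            f"t={t} beyond protocol end ({self.end_s} s); extend_ramp() first"
        )

    def power_at(self, t: float) -> float:
        """Workload in W at time ``t`` (piecewise constant, right-continuous)."""
        return self.segment_at(t).power_at(t)

    def phase_at(self, t: float) -> str:
        return self.segment_at(t).kind

    def ramp_segment(self) -> ProtocolSegment:
        ramps = [s for s in self.segments if s.kind == "ramp"]
        if not ramps:
            raise ProtocolError("protocol has no ramp segment")
        return ramps[-1]

    def extend_ramp(self) -> "WorkloadProtocol":
        """Continue the ramp indefinitely with identical step increments.

        Used for extrapolation beyond the recorded (truncated) test: any
        recovery segment after the ramp is dropped from the extended branch,
        its constant power kept as ``recovery_power_W`` metadata.
        """
        ramp = self.ramp_segment()
        idx = self.segments.index(ramp)
        dropped = self.segments[idx + 1 :]
        recovery_power = self.recovery_power_W
        for seg in dropped:
            if seg.kind == "recovery":
                recovery_power = seg.power_start_W
        open_ramp = replace(ramp, duration_s=None)
        return WorkloadProtocol(
            segments=self.segments[:idx] + (open_ramp,),
            name=f"{self.name}+extended",
            recovery_power_W=recovery_power,
        )

    def truncate_ramp(self, t_cut: float, recovery_duration_s: float,
                      recovery_power_W: Optional[float] = None) -> "WorkloadProtocol":
        """End the ramp at ``t_cut`` and append a constant recovery segment."""
        ramp = self.ramp_segment()
        if t_cut <= ramp.start_s:
            raise ProtocolError("t_cut must lie inside the ramp")
        if not ramp.open_ended and t_cut > ramp.end_s:
            raise ProtocolError("t_cut beyond ramp end")
        idx = self.segments.index(ramp)
        cut_ramp = replace(ramp, duration_s=t_cut - ramp.start_s)
        power = self.recovery_power_W if recovery_power_W is None else recovery_power_W
        recovery = ProtocolSegment(
            start_s=t_cut, duration_s=recovery_duration_s, kind="recovery",
            power_start_W=power,
        )
        return WorkloadProtocol(
            segments=self.segments[:idx] + (cut_ramp, recovery),
            name=f"{self.name}@cut{t_cut:.0f}s",
            recovery_power_W=power,
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "recovery_power_W": self.recovery_power_W,
            "segments": [
                {
                    "start_s": s.start_s,
                    "duration_s": s.duration_s,
                    "kind": s.kind,
                    "power_start_W": s.power_start_W,
                    "increment_W": s.increment_W,
                    "step_period_s": s.step_period_s,
                    "continuous": s.continuous,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorkloadProtocol":
        segs = tuple(ProtocolSegment(**sd) for sd in d["segments"])
        return cls(segments=segs, name=d.get("name", "protocol"),
                   recovery_power_W=d.get("recovery_power_W", STANDARD_LOW_POWER_W))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "WorkloadProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _standard(name: str, baseline_s: float, baseline_power: float,
              warmup_s: float, ramp_s: Optional[float], recovery_s: float,
              continuous: bool) -> WorkloadProtocol:
    for label, v in (("baseline", baseline_s), ("warmup", warmup_s),
                     ("recovery", recovery_s)):
        if v <= 0:
            raise ProtocolError(f"{label} duration must be positive")
    if ramp_s is not None and ramp_s <= 0:
        raise ProtocolError("ramp duration must be positive")
    t = 0.0
    segs = [ProtocolSegment(t, baseline_s, "baseline", baseline_power)]
    t += baseline_s
    segs.append(ProtocolSegment(t, warmup_s, "warmup", STANDARD_LOW_POWER_W))
    t += warmup_s
    segs.append(ProtocolSegment(
        t, ramp_s, "ramp", STANDARD_LOW_POWER_W + STANDARD_INCREMENT_W,
        increment_W=STANDARD_INCREMENT_W, step_period_s=STANDARD_STEP_PERIOD_S,
        continuous=continuous,
    ))
    if ramp_s is not None:
        t += ramp_s
        segs.append(ProtocolSegment(t, recovery_s, "recovery", STANDARD_LOW_POWER_W))
    return WorkloadProtocol(tuple(segs), name=name)


def retrospective_protocol(baseline_s: float = 360.0, warmup_s: float = 180.0,
                           ramp_s: Optional[float] = None,
                           recovery_s: float = 180.0,
                           continuous: bool = False) -> WorkloadProtocol:
    """Maximal-test protocol of the reference cohort.

    Up to 6 min seated adaptation without cycling (0 W), 3 min warm-up at
    50 W, incremental phase at +25 W/min, and at least 3 min cool-down at
    50 W.  With ``ramp_s=None`` the ramp is open-ended (no recovery appended),
    which is the natural input for simulation up to a subject-dependent
    exhaustion time.
    """
    return _standard("retrospective", baseline_s, 0.0, warmup_s, ramp_s,
                     recovery_s, continuous)


def validation_protocol(baseline_s: float = 180.0, warmup_s: float = 300.0,
                        ramp_s: Optional[float] = None,
                        recovery_s: float = 300.0,
                        continuous: bool = False) -> WorkloadProtocol:
    """Validation-test protocol: 3 min familiarization, 5 min warm-up and
    5 min cool-down at 50 W, ramp at +25 W/min.

    The familiarization phase is light unloaded cycling; it is modelled at
    0 W like the retrospective baseline.
    """
    return _standard("validation", baseline_s, 0.0, warmup_s, ramp_s,
                     recovery_s, continuous)


BUILDERS = {
    "retrospective": retrospective_protocol,
    "validation": validation_protocol,
}
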