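"""Magnetic-tweezers bead-trace processing.

A tethered, torsionally constrained DNA is supercoiled by magnet rotation;
R-loop formation under negative turns (and dissociation under positive
turns) absorbs/releases ~2 turns of twist, producing an upward step in bead
extension.  This module smooths raw 60 Hz traces, labels each sample with
its supercoiling phase from the magnet-turn schedule, detects the extension
steps, and extracts formation/dissociation dwell times.

The dwell clock starts when the magnet transit ends (turn setpoint
reached); phases with no detected step yield a right-censored dwell equal
to the phase hold duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ProtocolError

__all__ = [
    "BeadTrace",
    "Phase",
    "RotationProtocol",
    "DwellEvent",
    "smooth_trace",
    "segment_protocol",
    "detect_rloop_events",
]


@dataclass
class BeadTrace:
    """Uniformly sampled extension record of one bead.

    extension in micrometres; magnet_turns signed relative to the
    rotational zero reference; force (pN) constant per phase; torque
    (pN nm) is optional metadata.
    """

    trace_id: str
    time: np.ndarray
    extension: np.ndarray
    magnet_turns: np.ndarray | None = None
    sample_rate: float = 60.0
    force_pn: float | None = None
    torque_pn_nm: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.magnet_turns is not None:
            self.magnet_turns = np.asarray(self.magnet_turns, dtype=float)
            if self.magnet_turns.size != self.time.size:
                raise ValueError("magnet_turns length mismatch")
        if self.extension.size != self.time.size:
            raise ValueError("time and extension must have equal length")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 0.01 * np.mean(dt):
                raise ValueError("sampling must be uniform within 1%")
        if np.any(self.extension <= 0):
            raise ValueError("extension must be > 0")


@dataclass
class Phase:
    """One constant-turn hold, including the magnet transit that leads
    into it from the previous setpoint."""

    start_time: float
    end_time: float
    target_turns: float
    rotation_rate: float = 10.0
    sense: str = field(default="")

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("phase end must exceed start")
        if self.rotation_rate <= 0:
            raise ValueError("rotation_rate must be > 0")
        if not self.sense:
            self.sense = "negative" if self.target_turns < 0 else "positive"
        if self.sense not in ("negative", "positive"):
            raise ValueError(f"invalid sense {self.sense!r}")


@dataclass
class RotationProtocol:
    """Ordered, contiguous magnet-turn schedule.

    Default cycling rate is 10 turns/s; ``initial_turns`` is the setpoint
    before the first phase (usually 0 at Rot_0).
    """

    phases: list
    initial_turns: float = 0.0

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if abs(prev.end_time - nxt.start_time) > 1e-9:
                raise ProtocolError("phases must be contiguous and non-overlapping")

    def transit_duration(self, i: int) -> float:
        """Seconds the magnets spend rotating at the start of phase i."""
        prev = self.initial_turns if i == 0 else self.phases[i - 1].target_turns
        ph = self.phases[i]
        return abs(ph.target_turns - prev) / ph.rotation_rate

    def span(self) -> tuple:
        return self.phases[0].start_time, self.phases[-1].end_time


@dataclass
class DwellEvent:
    """One R-loop formation or dissociation waiting time.

    ``complete`` is False for partial R-loops (step height between 25% and
    75% of the expected full step); ``censored`` marks phases where no step
    occurred before the phase ended (dwell = hold duration).
    """

    trace_id: str
    kind: str  # formation | dissociation
    dwell: float
    step_height: float
    step_turns: float = float("nan")
    phase_index: int = -1
    phase_torque: float | None = None
    complete: bool = True
    censored: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("formation", "dissociation"):
            raise ValueError(f"invalid event kind {self.kind!r}")
        if self.dwell < 0:
            raise ValueError("dwell must be >= 0")


def smooth_trace(trace: BeadTrace, cutoff: float = 2.0) -> BeadTrace:
    """Zero-phase low-pass filter of the extension (2nd-order Butterworth,
    forward-backward), matching the 2 Hz display smoothing convention."""
    nyquist = trace.sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    b, a = butter(2, cutoff / nyquist)
    smoothed = filtfilt(b, a, trace.extension)
    return replace(trace, extension=smoothed)


def segment_protocol(trace: BeadTrace, protocol: RotationProtocol) -> pd.DataFrame:
    """Label every sample with its phase index and transit/hold segment.

    Samples inside the magnet-transit window at the start of each phase
    (duration |delta turns| / rate) are flagged ``transit`` and excluded
    from dwell timing downstream.
    """
    t0, t1 = protocol.span()
    if trace.time[0] < t0 - 1e-9 or trace.time[-1] > t1 + 1e-9:
        raise ProtocolError(
            f"protocol [{t0}, {t1}] s does not cover trace span "
            f"[{trace.time[0]}, {trace.time[-1]}] s"
        )
    phase_idx = np.full(trace.time.size, -1, dtype=int)
    segment = np.empty(trace.time.size, dtype=object)
    sense = np.empty(trace.time.size, dtype=object)
    for i, ph in enumerate(protocol.phases):
        mask = (trace.time >= ph.start_time - 1e-9) & (trace.time < ph.end_time - 1e-9)
        if i == len(protocol.phases) - 1:
            mask |= np.isclose(trace.time, ph.end_time)
        transit_end = ph.start_time + protocol.transit_duration(i)
        phase_idx[mask] = i
        sense[mask] = ph.sense
        segment[mask] = np.where(trace.time[mask] < transit_end, "transit", "hold")
    if np.any(phase_idx < 0):
        raise ProtocolError("some samples fall outside every protocol phase")
    return pd.DataFrame(
        {
            "time_s": trace.time,
            "phase_index": phase_idx,
            "segment": segment,
            "sense": sense,
        }
    )


_EVENT_FLOOR = 0.25  # of expected step: below this a phase is censored
_PARTIAL_CEIL = 0.75  # of expected step: below this an event is partial


def _hold_levels(x: np.ndarray, fs: float) -> tuple:
    """Baseline (early median) and final level (late median) of a hold."""
    n_base = max(3, int(round(0.15 * fs)))
    n_tail = max(3, int(round(0.5 * fs)))
    return float(np.median(x[:n_base])), float(np.median(x[-n_tail:]))


def detect_rloop_events(
    trace: BeadTrace,
    protocol: RotationProtocol,
    expected_step: float,
    threshold_fraction: float = 0.5,
    min_persist: float = 0.5,
    um_per_turn: float | None = None,
    smoothed: bool = False,
) -> list:
    """Detect R-loop steps and extract dwell times, one pass per hold phase.

    The step height of a hold is the late-median minus early-median level;
    holds with step < 0.25 x ``expected_step`` yield a right-censored dwell.
    Otherwise the dwell runs from the end of the magnet transit to the first
    crossing of baseline + ``threshold_fraction`` x step height that
    persists for ``min_persist`` seconds.  Steps between 25% and 75% of the
    expected step are flagged as partial R-loops (``complete=False``).
    Negative-turn holds produce formation events, positive-turn holds
    dissociation events.

    ``um_per_turn`` (extension change per magnet turn, from a no-enzyme
    rotation curve) converts step heights to turn equivalents.
    """
    if expected_step <= 0:
        raise ValueError("expected_step must be > 0")
    work = trace if smoothed else smooth_trace(trace)
    labels = segment_protocol(work, protocol)
    fs = work.sample_rate
    persist_n = max(1, int(round(min_persist * fs)))
    events: list = []
    for i, ph in enumerate(protocol.phases):
        hold = (labels["phase_index"].to_numpy() == i) & (
            labels["segment"].to_numpy() == "hold"
        )
        if not np.any(hold):
            continue
        x = work.extension[hold]
        t = work.time[hold]
        hold_duration = t[-1] - t[0]
        baseline, final = _hold_levels(x, fs)
        step = final - baseline
        kind = "formation" if ph.sense == "negative" else "dissociation"
        step_turns = step / um_per_turn if um_per_turn else float("nan")
        if step < _EVENT_FLOOR * expected_step:
            events.append(
                DwellEvent(
                    trace_id=trace.trace_id,
                    kind=kind,
                    dwell=float(hold_duration),
                    step_height=float(step),
                    step_turns=step_turns,
                    phase_index=i,
                    phase_torque=trace.torque_pn_nm,
                    complete=False,
                    censored=True,
                )
            )
            continue
        thresh = baseline + threshold_fraction * step
        above = x >= thresh
        crossing = None
        idx = np.flatnonzero(above)
        for j in idx:
            window = above[j : j + persist_n]
            if window.size and np.mean(window) >= 0.8:
                crossing = j
                break
        if crossing is None:
            crossing = idx[0] if idx.size else None
        if crossing is None:
            events.append(
                DwellEvent(
                    trace_id=trace.trace_id,
                    kind=kind,
                    dwell=float(hold_duration),
                    step_height=float(step),
                    step_turns=step_turns,
                    phase_index=i,
                    phase_torque=trace.torque_pn_nm,
                    complete=False,
                    censored=True,
                )
            )
            continue
        dwell = float(t[crossing] - t[0])
        events.append(
            DwellEvent(
                trace_id=trace.trace_id,
                kind=kind,
                dwell=dwell,
                step_height=float(step),
                step_turns=step_turns,
                phase_index=i,
                phase_torque=trace.torque_pn_nm,
                complete=bool(step >= _PARTIAL_CEIL * expected_step),
                censored=False,
            )
        )
    for ev in events:
        # hard contract: formation only under negative turns and vice versa
        ph = protocol.phases[ev.phase_index]
        assert (ev.kind == "formation") == (ph.sense == "negative")
    return events


_EVENT_COLUMNS = [
    "trace_id", "kind", "dwell_s", "step_um", "step_turns",
    "complete", "censored", "phase_index",
]


def events_to_frame(events: list) -> pd.DataFrame:
    """Flatten DwellEvents to the events-table schema used on disk."""
    if not events:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    return pd.DataFrame(
        [
            {
                "trace_id": e.trace_id,
                "kind": e.kind,
                "dwell_s": e.dwell,
                "step_um": e.step_height,
                "step_turns": e.step_turns,
                "complete": e.complete,
                "censored": e.censored,
                "phase_index": e.phase_index,
            }
            for e in events
        ]
    )
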