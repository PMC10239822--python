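"""Injected-current protocols: steps, bidirectional ramps, zap chirps,
test-pulse memory protocols, and composition.

A protocol maps time t (ms) to injected current (pA); positive current
depolarizes.  Every protocol carries an explicit, sorted list of breakpoints
(times where its definition changes) so the integrator can restart there and
step onsets/offsets are not smeared.  Stimulus windows are half-open
[onset, offset): the sample at exactly the offset carries 0 pA, which makes
charge accounting unambiguous.  Evaluation outside the protocol window
returns 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "ZapParameters",
    "zero_current",
    "step_current",
    "ramp_current",
    "zap_frequency",
    "zap_current",
    "memory_protocol",
]


class ProtocolError(ValueError):
    """Raised for ill-formed protocol definitions (overlaps, bad windows)."""


@dataclass(frozen=True)
class _Segment:
    """Half-open time window [t0, t1) with its own current function."""

    t0: float
    t1: float
    fn: Callable[[float], float]


class StimulusProtocol:
    """Piecewise injected-current protocol.

    Built from non-overlapping half-open segments; zero current between and
    outside them.  Callable with a scalar time in ms; :meth:`sample`
    evaluates a whole time grid.
    """

    def __init__(self, segments: Sequence[_Segment], description: str = ""):
        segments = sorted(segments, key=lambda s: s.t0)
        for a, b in zip(segments, segments[1:]):
            if b.t0 < a.t1:
                raise ProtocolError(
                    f"overlapping stimulus segments at t={b.t0:g} ms"
                )
        for s in segments:
            if not (s.t1 > s.t0):
                raise ProtocolError("segment duration must be positive")
        self._segments = tuple(segments)
        self.description = description

    @property
    def breakpoints(self) -> list[float]:
        """Sorted times where the current definition changes."""
        pts = sorted({t for s in self._segments for t in (s.t0, s.t1)})
        return pts

    @property
    def end(self) -> float:
        """Time after which the protocol is identically zero (ms)."""
        return self._segments[-1].t1 if self._segments else 0.0

    def __call__(self, t: float) -> float:
        for s in self._segments:
            if s.t0 <= t < s.t1:
                return s.fn(t)
        return 0.0

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.array([self(float(ti)) for ti in t])

    def __add__(self, other: "StimulusProtocol") -> "StimulusProtocol":
        return StimulusProtocol(
            list(self._segments) + list(other._segments),
            description=f"{self.description}+{other.description}",
        )

    def to_csv(self, path, dt: float = 1.0, t_max: float | None = None) -> None:
        """Write a two-column (t_ms, I_pA) audit table."""
        t_max = self.end if t_max is None else t_max
        t = np.arange(0.0, t_max + dt / 2, dt)
        np.savetxt(
            path,
            np.column_stack([t, self.sample(t)]),
            delimiter=",",
            header="t_ms,Iinj_pA",
            comments="",
        )


def zero_current() -> StimulusProtocol:
    """The empty protocol (0 pA everywhere)."""
    return StimulusProtocol([], description="zero")


def step_current(amplitude: float, onset: float, duration: float) -> StimulusProtocol:
    """Rectangular step: `amplitude` pA on [onset, onset+duration) ms."""
    if duration <= 0:
        raise ProtocolError("step duration must be positive")
    return StimulusProtocol(
        [_Segment(onset, onset + duration, lambda t, a=amplitude: a)],
        description=f"step {amplitude:g} pA, {duration:g} ms at {onset:g} ms",
    )


def ramp_current(
    peak: float, up_duration: float, down_duration: float, onset: float = 0.0
) -> StimulusProtocol:
    """Bidirectional triangular ramp 0 -> peak -> 0 (continuous everywhere)."""
    if up_duration <= 0 or down_duration <= 0:
        raise ProtocolError("ramp durations must be positive")
    t_peak = onset + up_duration
    t_end = t_peak + down_duration

    def up(t: float) -> float:
        return peak * (t - onset) / up_duration

    def down(t: float) -> float:
        return peak * (t_end - t) / down_duration

    return StimulusProtocol(
        [_Segment(onset, t_peak, up), _Segment(t_peak, t_end, down)],
        description=f"ramp 0-{peak:g}-0 pA over {up_duration + down_duration:g} ms",
    )


@dataclass(frozen=True)
class ZapParameters:
    """Exponential-chirp ('zap') parameters.

    The acceleration half sweeps an instantaneous frequency f0*exp(lambda*t)
    from f0 to fmax over tau_half seconds; the deceleration half is the exact
    time mirror of the acceleration current waveform.  lambda is derived:
    ln(fmax/f0)/tau_half.
    """

    Izapmax: float = 30.5
    f0: float = 0.1
    fmax: float = 5.0
    tau_half: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.f0 < self.fmax):
            raise ProtocolError("need 0 < f0 < fmax")
        if self.tau_half <= 0:
            raise ProtocolError("tau_half must be positive")

    @property
    def lam(self) -> float:
        """Exponential rising factor, 1/s."""
        return math.log(self.fmax / self.f0) / self.tau_half


def zap_frequency(t: float, zap: ZapParameters = ZapParameters()) -> float:
    """Sweep frequency f_zap (Hz) at time t (s) into the acceleration half.

    f_zap(t) = f0 (exp(lambda t) - 1)/(lambda t), the average of the
    instantaneous exponential chirp frequency f0 exp(lambda t) over [0, t],
    so that 2 pi f_zap t is the chirp's accumulated phase.  The removable
    singularity at t=0 is filled with f0.
    """
    if not (0.0 <= t <= zap.tau_half):
        raise ProtocolError(f"t={t:g} s outside the acceleration half")
    x = zap.lam * t
    if x < 1e-9:
        return zap.f0
    return zap.f0 * math.expm1(x) / x


def _zap_accel_current(t_s: float, zap: ZapParameters) -> float:
    # accumulated chirp phase: 2*pi*f0*(exp(lam t)-1)/lam
    phase = 2.0 * math.pi * zap.f0 * math.expm1(zap.lam * t_s) / zap.lam
    return zap.Izapmax * (0.5 + 0.5 * math.cos(phase + math.pi))


def zap_current(
    t: float, zap: ZapParameters = ZapParameters(), onset: float = 0.0
) -> float:
    """Zap current (pA) at time t (ms); total duration 2*tau_half seconds.

    Acceleration half: Izapmax*(0.5 + 0.5*cos(2 pi f_zap t + pi)), starting
    at 0 pA (cosine phase offset pi).  Deceleration half: time mirror,
    I(t) = I(2*tau_half - t), so the full waveform is symmetric about its
    midpoint to machine precision.
    """
    t_s = (t - onset) / 1000.0
    total = 2.0 * zap.tau_half
    if not (0.0 <= t_s <= total):
        return 0.0
    if t_s <= zap.tau_half:
        return _zap_accel_current(t_s, zap)
    return _zap_accel_current(total - t_s, zap)


def zap_protocol(zap: ZapParameters = ZapParameters(), onset: float = 0.0) -> StimulusProtocol:
    """Full 2*tau_half zap as a protocol (breakpoints at ends and midpoint)."""
    half_ms = zap.tau_half * 1000.0
    return StimulusProtocol(
        [
            _Segment(onset, onset + half_ms, lambda t: zap_current(t, zap, onset)),
            _Segment(
                onset + half_ms,
                onset + 2 * half_ms + 1e-9,
                lambda t: zap_current(t, zap, onset),
            ),
        ],
        description=(
            f"zap {zap.Izapmax:g} pA, {zap.f0:g}-{zap.fmax:g} Hz over "
            f"{2 * zap.tau_half:g} s"
        ),
    )


@dataclass(frozen=True)
class MemoryProtocolTimes:
    """Onsets/offsets (ms) of the pieces of a test-pulse memory protocol."""

    pre_onset: float
    pre_end: float
    main_onset: float
    main_end: float
    post_onset: float
    post_end: float


def memory_protocol(
    delay: float,
    test_amp: float = 22.0,
    test_dur: float = 200.0,
    main_amp: float = 50.0,
    main_dur: float = 5000.0,
    pre_gap: float = 5000.0,
    include_pre: bool = True,
    include_main: bool = True,
) -> tuple[StimulusProtocol, MemoryProtocolTimes]:
    """Excitability-memory protocol: test pulse, main stimulus, test pulse.

    A short test pulse (default 22 pA, 200 ms) probes baseline excitability;
    after a quiet gap (default 5 s) the main stimulus (default 50 pA, 5 s)
    drives spiking; `delay` seconds after the main stimulus ends, the same
    test pulse probes excitability during the afterhyperpolarization.
    `include_pre`/`include_main` allow isolated-pulse control runs on the
    same absolute timeline.
    """
    if delay <= 0:
        raise ProtocolError("post-stimulus delay must be positive")
    pre_onset = 0.0
    main_onset = pre_onset + test_dur + pre_gap
    main_end = main_onset + main_dur
    post_onset = main_end + delay * 1000.0
    times = MemoryProtocolTimes(
        pre_onset, pre_onset + test_dur, main_onset, main_end,
        post_onset, post_onset + test_dur,
    )
    proto = step_current(test_amp, post_onset, test_dur)
    if include_main:
        proto = proto + step_current(main_amp, main_onset, main_dur)
    if include_pre:
        proto = proto + step_current(test_amp, pre_onset, test_dur)
    proto.description = (
        f"memory protocol: {test_amp:g} pA/{test_dur:g} ms test pulses around "
        f"{main_amp:g} pA/{main_dur:g} ms main stimulus, delay {delay:g} s"
    )
    return proto, times
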