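"""Spike detection and excitability descriptors.

Implements the descriptors used throughout the experiments: instantaneous
firing rates (IFR) from interspike intervals, the grouped-average late
adaptation slope s_adapt, afterhyperpolarization amplitude and half
duration, step-response classification, burst segmentation, and
time-to-first-spike.  Synthetic spike trains and voltage traces with known
ground truth are provided for testing the descriptors without running the
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SpikeTrain",
    "IFRSeries",
    "StepResponseMetrics",
    "BurstMetrics",
    "ResponseClass",
    "detect_spikes",
    "ifr_series",
    "adaptation_slope",
    "ahp_metrics",
    "classify_step_response",
    "burst_segmentation",
    "time_to_first_spike",
    "step_response_metrics",
    "make_constant_rate_train",
    "make_linear_ifr_train",
    "make_burst_train",
    "make_ahp_trace",
    "make_spiking_trace",
]

DEFAULT_THRESHOLD = -20.0  # mV; spikes overshoot ~0 mV, subthreshold stays < -40
DEFAULT_REFRACTORY = 2.0  # ms


class ResponseClass(str, Enum):
    SUBTHRESHOLD = "subthreshold"
    SUSTAINED = "sustained"
    PREMATURE_TERMINATION = "premature_termination"
    DEPOLARIZATION_BLOCK = "depolarization_block"


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) plus the detection settings."""

    spike_times: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    refractory: float = DEFAULT_REFRACTORY

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if len(st) > 1 and np.any(np.diff(st) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.spike_times + dt, self.threshold, self.refractory)

    def in_window(self, t0: float, t1: float) -> "SpikeTrain":
        st = self.spike_times
        return SpikeTrain(st[(st >= t0) & (st <= t1)], self.threshold, self.refractory)


@dataclass(frozen=True)
class IFRSeries:
    """Instantaneous firing rate per interspike interval.

    IFR_k = 1000/ISI_k in Hz, time-stamped at the later spike of the pair
    (causal convention: the rate becomes known when the second spike fires).
    """

    t: np.ndarray  # ms, time of the later spike of each ISI
    ifr: np.ndarray  # Hz

    def __len__(self) -> int:
        return len(self.ifr)


def ifr_series(train: SpikeTrain) -> IFRSeries:
    """IFR series of a spike train; empty for trains with < 2 spikes."""
    st = train.spike_times
    if len(st) < 2:
        return IFRSeries(np.empty(0), np.empty(0))
    isi = np.diff(st)
    return IFRSeries(t=st[1:], ifr=1000.0 / isi)


def detect_spikes(
    trace,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> SpikeTrain:
    """Upward threshold crossings of V, linearly interpolated in time.

    Crossings closer together than the refractory period are merged (the
    first one wins).  `trace` is any object with `t` (ms) and `V` (mV)
    arrays; an empty train is a valid result.
    """
    t = np.asarray(trace.t, dtype=float)
    V = np.asarray(trace.V, dtype=float)
    if len(t) == 0:
        raise ValueError("empty trace")
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if len(idx) == 0:
        return SpikeTrain(np.empty(0), threshold, refractory)
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    kept = [times[0]]
    for ti in times[1:]:
        if ti - kept[-1] >= refractory:
            kept.append(ti)
    return SpikeTrain(np.array(kept), threshold, refractory)


def adaptation_slope(ifr: IFRSeries) -> float | None:
    """Late-time IFR slope s_adapt (Hz/s) by the grouped-average procedure.

    Take the last 19 IFR values, drop the very last (it may come from an
    ISI truncated by the stimulus ending mid-spike), split the remaining 18
    into two consecutive groups of 9, and divide the difference of the group
    means by the time between the middle (5th) entries of the groups.
    Returns None (undefined) with fewer than 19 IFR values.
    """
    if len(ifr) < 19:
        return None
    t = ifr.t[-19:-1]
    r = ifr.ifr[-19:-1]
    early_mean, late_mean = r[:9].mean(), r[9:].mean()
    t_mid_early, t_mid_late = t[4], t[13]
    return float((late_mean - early_mean) / ((t_mid_late - t_mid_early) / 1000.0))


def ahp_metrics(
    trace,
    injection_end: float,
    baseline_V: float,
    min_amplitude: float = -0.05,
) -> tuple[float | None, float | None]:
    """Afterhyperpolarization amplitude (mV) and half duration (s).

    AHPamp = lowest post-offset voltage minus the pre-injection baseline;
    T_half = time from stimulus offset until the voltage has first recovered
    to baseline + AHPamp/2 after the trough.  Returns (None, None) when the
    post-offset minimum does not undershoot the baseline by more than
    |min_amplitude| ("no AHP"); T_half alone is None when the trace ends
    before half recovery.
    """
    t = np.asarray(trace.t, dtype=float)
    V = np.asarray(trace.V, dtype=float)
    post = t >= injection_end
    if not np.any(post):
        raise ValueError("trace does not extend past the injection end")
    t_post, V_post = t[post], V[post]
    i_min = int(np.argmin(V_post))
    amp = float(V_post[i_min] - baseline_V)
    if amp >= min_amplitude:
        return None, None
    half_level = baseline_V + amp / 2.0
    after = V_post[i_min:]
    above = np.nonzero(after >= half_level)[0]
    if len(above) == 0:
        return amp, None  # unrecovered within the trace
    j = above[0] + i_min
    if j == 0:
        t_half = float(t_post[0] - injection_end)
    else:
        # linear interpolation of the recovery crossing
        f = (half_level - V_post[j - 1]) / (V_post[j] - V_post[j - 1])
        t_cross = t_post[j - 1] + f * (t_post[j] - t_post[j - 1])
        t_half = float(t_cross - injection_end)
    return amp, t_half / 1000.0


def classify_step_response(
    train: SpikeTrain,
    trace,
    injection_onset: float,
    injection_end: float,
    block_level: float = -30.0,
    block_min_duration: float = 200.0,
    termination_margin: float = 250.0,
) -> ResponseClass:
    """Classify the response to a step injection.

    subthreshold: no spikes in the injection window.  depolarization_block:
    V stays above `block_level` without spiking for more than
    `block_min_duration` ms contiguously during the injection.
    premature_termination: the gap from the last spike to the injection end
    exceeds max(`termination_margin` ms, 3x the last ISI) — spiking stopped
    well before the stimulus did.  Otherwise sustained.
    """
    spikes = train.in_window(injection_onset, injection_end).spike_times
    if len(spikes) == 0:
        t = np.asarray(trace.t)
        V = np.asarray(trace.V)
        win = (t >= injection_onset) & (t <= injection_end)
        if np.any(win) and _longest_high_run(t[win], V[win], block_level) > block_min_duration:
            return ResponseClass.DEPOLARIZATION_BLOCK
        return ResponseClass.SUBTHRESHOLD
    # spikeless depolarized stretches between/after spikes
    t = np.asarray(trace.t)
    V = np.asarray(trace.V)
    edges = np.concatenate([[injection_onset], spikes, [injection_end]])
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= block_min_duration:
            continue
        win = (t >= a + 5.0) & (t <= b)  # skip the spike itself
        if np.any(win) and _longest_high_run(t[win], V[win], block_level) > block_min_duration:
            return ResponseClass.DEPOLARIZATION_BLOCK
    last_gap = injection_end - spikes[-1]
    last_isi = spikes[-1] - spikes[-2] if len(spikes) >= 2 else math.inf
    if last_gap > max(termination_margin, 3.0 * last_isi):
        return ResponseClass.PREMATURE_TERMINATION
    return ResponseClass.SUSTAINED


def _longest_high_run(t: np.ndarray, V: np.ndarray, level: float) -> float:
    """Longest contiguous time (ms) with V above `level`."""
    high = V > level
    longest = run_start = 0.0
    in_run = False
    for i in range(len(t)):
        if high[i] and not in_run:
            in_run, run_start = True, t[i]
        elif not high[i] and in_run:
            in_run = False
            longest = max(longest, t[i] - run_start)
    if in_run:
        longest = max(longest, t[-1] - run_start)
    return longest


@dataclass(frozen=True)
class StepResponseMetrics:
    """Descriptors of one step-current response."""

    IFR_ini: float | None  # Hz, inverse of the first ISI
    IFR_fin: float | None  # Hz, inverse of the last ISI
    s_adapt: float | None  # Hz/s, None when < 20 spikes
    AHPamp: float | None  # mV (negative), None when no AHP
    T_half: float | None  # s, None when no AHP or unrecovered
    n_spikes: int
    classification: ResponseClass


def step_response_metrics(
    trace,
    injection_onset: float,
    injection_end: float,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> StepResponseMetrics:
    """All step-response descriptors of a simulated trace in one pass.

    The baseline voltage for the AHP is the sample immediately before the
    injection onset.
    """
    train = detect_spikes(trace, threshold, refractory)
    spikes = train.in_window(injection_onset, injection_end)
    ifr = ifr_series(spikes)
    t = np.asarray(trace.t)
    pre = np.nonzero(t < injection_onset)[0]
    baseline = float(np.asarray(trace.V)[pre[-1]]) if len(pre) else float(trace.V[0])
    amp, t_half = ahp_metrics(trace, injection_end, baseline)
    cls = classify_step_response(spikes, trace, injection_onset, injection_end)
    return StepResponseMetrics(
        IFR_ini=float(ifr.ifr[0]) if len(ifr) else None,
        IFR_fin=float(ifr.ifr[-1]) if len(ifr) else None,
        s_adapt=adaptation_slope(ifr),
        AHPamp=amp,
        T_half=t_half,
        n_spikes=len(spikes),
        classification=cls,
    )


@dataclass(frozen=True)
class BurstMetrics:
    """Summary of a rhythmic bursting record (all times in s)."""

    period: float
    burst_duration: float
    duty_cycle: float
    n_cycles_used: int


def burst_segmentation(
    train: SpikeTrain,
    gap_factor: float = 5.0,
    transient_fraction: float = 0.2,
    record_end: float | None = None,
    min_cycles: int = 3,
) -> BurstMetrics | None:
    """Segment a spike train into bursts and summarize the rhythm.

    Burst boundaries are interspike intervals exceeding `gap_factor` times
    the median ISI (gap detection runs on the full train so onsets keep
    their provenance); bursts starting in the first `transient_fraction` of
    the record are then discarded.  period = mean interval between
    remaining burst onsets; burst_duration = mean span from first to last
    spike within a burst, over bursts whose termination is confirmed by a
    following gap (the record's last burst counts only if enough silence
    follows it); duty cycle = duration/period.  Returns None ("not
    bursting") for tonic trains or fewer than `min_cycles` burst onsets.
    """
    st = train.spike_times
    if len(st) < 4:
        return None
    t_end = record_end if record_end is not None else st[-1]
    isi = np.diff(st)
    gap_thresh = gap_factor * np.median(isi)
    gap_idx = np.nonzero(isi > gap_thresh)[0]
    if len(gap_idx) == 0:
        return None  # tonic
    onsets = np.concatenate([[st[0]], st[gap_idx + 1]])
    ends = np.concatenate([st[gap_idx], [st[-1]]])
    t_cut = st[0] + transient_fraction * (t_end - st[0])
    keep = onsets >= t_cut
    onsets, ends = onsets[keep], ends[keep]
    if len(onsets) < min_cycles:
        return None
    durations = ends - onsets
    if t_end - ends[-1] < gap_thresh:
        durations = durations[:-1]  # last burst may be cut off by record end
    periods = np.diff(onsets)
    if len(durations) == 0:
        return None
    period = float(periods.mean()) / 1000.0
    duration = float(durations.mean()) / 1000.0
    return BurstMetrics(
        period=period,
        burst_duration=duration,
        duty_cycle=duration / period,
        n_cycles_used=len(periods),
    )


def time_to_first_spike(train: SpikeTrain, pulse_onset: float) -> float | None:
    """Latency (ms) from pulse onset to the first subsequent spike, or None."""
    after = train.spike_times[train.spike_times >= pulse_onset]
    if len(after) == 0:
        return None
    return float(after[0] - pulse_onset)


# ---------------------------------------------------------------------------
# Synthetic fixtures with known ground truth
# ---------------------------------------------------------------------------

def make_constant_rate_train(rate_hz: float, n_spikes: int, t0: float = 0.0) -> SpikeTrain:
    """Regular train at a constant rate (Hz)."""
    if rate_hz <= 0 or n_spikes < 1:
        raise ValueError("need positive rate and at least one spike")
    isi = 1000.0 / rate_hz
    return SpikeTrain(t0 + isi * np.arange(n_spikes))


def make_linear_ifr_train(
    ifr0_hz: float, slope_hz_per_s: float, n_spikes: int, t0: float = 0.0
) -> SpikeTrain:
    """Train whose IFR profile follows IFR(t) = ifr0 + slope * t.

    Built by stepping through ISIs whose inverse tracks the target profile
    at the time of the later spike of each interval (the IFR timestamp
    convention), so the measured IFR series lies on the requested line.
    """
    if n_spikes < 2:
        raise ValueError("need at least two spikes")
    times = [0.0]
    for _ in range(n_spikes - 1):
        t_prev = times[-1]
        # solve isi = 1000 / (ifr0 + slope*(t_prev+isi)/1000) for isi
        a = slope_hz_per_s / 1000.0
        b = ifr0_hz + a * t_prev
        if a == 0:
            isi = 1000.0 / b
        else:
            isi = (-b + math.sqrt(b * b + 4.0 * a * 1000.0)) / (2.0 * a)
        if isi <= 0 or not math.isfinite(isi):
            raise ValueError("IFR profile reaches zero within the train")
        times.append(t_prev + isi)
    return SpikeTrain(t0 + np.array(times))


def make_burst_train(
    n_bursts: int,
    spikes_per_burst: int,
    intra_isi: float,
    period: float,
    t0: float = 0.0,
) -> SpikeTrain:
    """Periodic bursts: `spikes_per_burst` spikes at `intra_isi` ms spacing,
    burst onsets `period` ms apart."""
    if spikes_per_burst < 2 or n_bursts < 1:
        raise ValueError("need at least two spikes per burst")
    if (spikes_per_burst - 1) * intra_isi >= period:
        raise ValueError("burst longer than period")
    times = [
        t0 + b * period + s * intra_isi
        for b in range(n_bursts)
        for s in range(spikes_per_burst)
    ]
    return SpikeTrain(np.array(times))


@dataclass
class _ArrayTrace:
    t: np.ndarray
    V: np.ndarray


def make_ahp_trace(
    baseline: float,
    trough: float,
    injection_end: float,
    trough_delay: float = 500.0,
    tau_decay: float = 3000.0,
    duration: float = 40_000.0,
    dt: float = 1.0,
) -> _ArrayTrace:
    """Voltage trace at `baseline` with a post-offset exponential AHP.

    The voltage dips linearly to `trough` over `trough_delay` ms after the
    injection end, then relaxes back exponentially with time constant
    `tau_decay` ms; ground-truth AHPamp = trough - baseline and
    T_half = trough_delay + tau_decay*ln(2).
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    V = np.full_like(t, baseline)
    amp = trough - baseline
    fall = (t > injection_end) & (t <= injection_end + trough_delay)
    V[fall] = baseline + amp * (t[fall] - injection_end) / trough_delay
    rec = t > injection_end + trough_delay
    V[rec] = baseline + amp * np.exp(-(t[rec] - injection_end - trough_delay) / tau_decay)
    return _ArrayTrace(t=t, V=V)


def make_spiking_trace(
    train: SpikeTrain,
    baseline: float = -60.0,
    peak: float = 5.0,
    spike_width: float = 1.0,
    duration: float | None = None,
    dt: float = 0.05,
) -> _ArrayTrace:
    """Voltage trace with triangular spikes at the times of `train`.

    Each spike rises from baseline to `peak` and back over `spike_width` ms,
    centred so the upward -20 mV crossing falls at the nominal spike time to
    within the rise-time discretization.
    """
    end = duration if duration is not None else float(train.spike_times[-1] + 50.0)
    t = np.arange(0.0, end + dt / 2, dt)
    V = np.full_like(t, baseline)
    half = spike_width / 2.0
    for ts in train.spike_times:
        win = np.abs(t - ts - half) < half
        V[win] = np.maximum(
            V[win], peak - (peak - baseline) * np.abs(t[win] - ts - half) / half
        )
    return _ArrayTrace(t=t, V=V)
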