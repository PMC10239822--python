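"""Scripted in-silico experiments: FI curves, ramps, zaps, test-pulse memory,
pump-parameter sweeps and bursting surveys.

Each driver runs a set of deterministic simulations and returns an
:class:`ExperimentResult` holding a tidy long-format table (one row per
variant/condition/metric) plus enough provenance to rerun it.  Rows whose
quantity is undefined (no spikes, no AHP, not bursting...) carry a status
instead of a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core_model import NeuronState, PumpParameters, resting_gating
from .dynamics_engine import (
    ModelSpec,
    RestResult,
    SimulationTrace,
    SolverOptions,
    find_rest,
    integrate,
)
from .electrophys_metrics import (
    ResponseClass,
    StepResponseMetrics,
    burst_segmentation,
    detect_spikes,
    ifr_series,
    step_response_metrics,
    time_to_first_spike,
)
from .stimulus import (
    ZapParameters,
    memory_protocol,
    ramp_current,
    step_current,
    zap_protocol,
    zero_current,
)

__all__ = [
    "ExperimentResult",
    "run_step_response",
    "run_fi_curve",
    "find_sustained_threshold",
    "run_ramp_suite",
    "run_zap",
    "run_memory_protocol",
    "run_pump_sweep",
    "run_burst_survey",
]

#: Baseline window before any stimulus, ms.
PRE_STIMULUS = 1000.0
#: Default post-stimulus tail for AHP recovery, ms (AHPs last tens of seconds).
AHP_TAIL = 60_000.0


@dataclass
class ExperimentResult:
    """Tidy long-format experiment output.

    `table` columns: variant, the condition columns of the experiment,
    metric, value, status ("ok" or a reason the value is undefined).
    """

    name: str
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("software_version", _pkg_version)
        self.provenance.setdefault("deterministic", True)

    def values(self, metric: str, **conditions) -> pd.Series:
        sel = self.table[self.table.metric == metric]
        for k, v in conditions.items():
            sel = sel[sel[k] == v]
        return sel.value

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rows(variant, conditions: dict, metrics: dict) -> list[dict]:
    out = []
    for metric, value in metrics.items():
        status = "ok"
        if value is None:
            status, value = "undefined", np.nan
        elif isinstance(value, ResponseClass):
            value = value.value
        out.append({"variant": variant, **conditions, "metric": metric, "value": value, "status": status})
    return out


def _rest_state(model: ModelSpec) -> RestResult:
    return find_rest(model)


def run_step_response(
    model: ModelSpec,
    amplitude: float,
    duration: float = 5000.0,
    tail: float = AHP_TAIL,
    rest: NeuronState | None = None,
    options: SolverOptions | None = None,
) -> tuple["StepResponseMetrics", SimulationTrace]:
    """One step-current run from rest, with metrics.

    The step starts after a 1 s baseline; the trace continues `tail` ms past
    the offset so the slow AHP can be measured.
    """
    if rest is None:
        rr = _rest_state(model)
        if not rr.converged:
            raise RuntimeError(f"no stable rest for this model: {rr.message}")
        rest = rr.state
    opts = options or SolverOptions(output_dt=0.1)
    onset, offset = PRE_STIMULUS, PRE_STIMULUS + duration
    trace = integrate(rest, step_current(amplitude, onset, duration), offset + tail, model, opts)
    metrics = step_response_metrics(trace, onset, offset)
    return metrics, trace


def run_fi_curve(
    variant: str,
    currents: Iterable[float],
    duration: float = 5000.0,
    tail: float = AHP_TAIL,
    model: ModelSpec | None = None,
    options: SolverOptions | None = None,
) -> ExperimentResult:
    """Step-response metrics across injection currents (FI curve).

    Subthreshold and depolarization-block rows keep their classification so
    callers can flag or drop them (the figures omit them).  Solver failures
    are recorded per-row, not raised.
    """
    model = model or ModelSpec.variant(variant)
    rr = _rest_state(model)
    rows: list[dict] = []
    for amp in currents:
        cond = {"current_pA": float(amp)}
        if not rr.converged:
            rows += _rows(variant, cond, {"classification": None})
            continue
        try:
            m, _ = run_step_response(model, float(amp), duration, tail, rr.state, options)
        except Exception as exc:  # pragma: no cover - solver failures are rare
            rows.append({"variant": variant, **cond, "metric": "error",
                         "value": np.nan, "status": str(exc)})
            continue
        rows += _rows(variant, cond, {
            "IFR_ini_Hz": m.IFR_ini,
            "IFR_fin_Hz": m.IFR_fin,
            "s_adapt_Hz_per_s": m.s_adapt,
            "AHPamp_mV": m.AHPamp,
            "T_half_s": m.T_half,
            "n_spikes": m.n_spikes,
            "classification": m.classification,
        })
    return ExperimentResult(
        "fi_curve", pd.DataFrame(rows),
        {"variant": variant, "duration_ms": duration, "tail_ms": tail},
    )


def find_sustained_threshold(
    variant: str,
    lo: int = 20,
    hi: int = 50,
    duration: float = 5000.0,
    model: ModelSpec | None = None,
    scan_all: bool = False,
) -> int:
    """Smallest integer current (pA) sustaining spiking for the whole step.

    Below the threshold spiking ceases prematurely (growing pump current
    overwhelms the drive).  By default exploits the monotonicity of the
    premature/sustained boundary with a bisection over integers and verifies
    both sides; `scan_all` forces the exhaustive 1 pA scan.
    """
    model = model or ModelSpec.variant(variant)
    rr = _rest_state(model)
    if not rr.converged:
        raise RuntimeError("no stable rest")

    def sustained(amp: int) -> bool:
        m, _ = run_step_response(model, float(amp), duration, tail=1000.0, rest=rr.state)
        return m.classification == ResponseClass.SUSTAINED

    if scan_all:
        for amp in range(lo, hi + 1):
            if sustained(amp):
                return amp
        raise RuntimeError(f"no sustained current in [{lo}, {hi}] pA")
    if sustained(lo):
        return lo
    if not sustained(hi):
        raise RuntimeError(f"no sustained current in [{lo}, {hi}] pA")
    a, b = lo, hi  # a premature, b sustained
    while b - a > 1:
        mid = (a + b) // 2
        if sustained(mid):
            b = mid
        else:
            a = mid
    return b


def run_ramp_suite(
    variant: str,
    peak: float = 70.0,
    total_durations_s: Sequence[float] = (2.0, 10.0, 40.0),
    model: ModelSpec | None = None,
    options: SolverOptions | None = None,
) -> ExperimentResult:
    """Bidirectional ramps 0 -> peak -> 0 at several speeds.

    For each ramp, the IFR of every spike is paired with the momentary
    injected current; the hysteresis metric is the mean (up-phase IFR minus
    down-phase IFR) across overlapping 2 pA current bins.  ISIs spanning a
    silent gap (over 5x the median ISI, e.g. across the depolarization-block
    window near the ramp peak) are not instantaneous rates and are excluded
    from the pairing.
    """
    model = model or ModelSpec.variant(variant)
    rr = _rest_state(model)
    if not rr.converged:
        raise RuntimeError("no stable rest")
    opts = options or SolverOptions(output_dt=0.1)
    rows: list[dict] = []
    for total in total_durations_s:
        half = total * 500.0  # ms
        proto = ramp_current(peak, half, half, onset=PRE_STIMULUS)
        trace = integrate(rr.state, proto, PRE_STIMULUS + 2 * half + 500.0, model, opts)
        train = detect_spikes(trace)
        ifr = ifr_series(train)
        t_peak = PRE_STIMULUS + half
        if len(ifr) >= 3:
            isi = 1000.0 / ifr.ifr
            neighbor = np.maximum(
                np.concatenate([[isi[1]], isi[:-1]]),
                np.concatenate([isi[1:], [isi[-2]]]),
            )
            # an isolated long ISI is a silent gap, not a momentary rate;
            # uniformly slow spiking (long ISIs with long neighbours) stays
            keep = ~((isi > 5.0 * np.median(isi)) & (isi > 3.0 * neighbor))
            ifr = type(ifr)(t=ifr.t[keep], ifr=ifr.ifr[keep])
        current_at = np.array([proto(float(t)) for t in ifr.t])
        up = ifr.t <= t_peak
        hyst = _binned_hysteresis(current_at[up], ifr.ifr[up], current_at[~up], ifr.ifr[~up])
        rows += _rows(variant, {"ramp_total_s": total}, {
            "n_spikes": len(train),
            "hysteresis_Hz": hyst,
            "max_IFR_Hz": float(ifr.ifr.max()) if len(ifr) else None,
        })
    return ExperimentResult(
        "ramp_suite", pd.DataFrame(rows),
        {"variant": variant, "peak_pA": peak},
    )


def _binned_hysteresis(i_up, f_up, i_down, f_down, bin_width: float = 2.0) -> float | None:
    """Mean IFR(up) - IFR(down) over current bins populated in both phases."""
    if len(i_up) == 0 or len(i_down) == 0:
        return None
    edges = np.arange(0.0, max(i_up.max(), i_down.max()) + bin_width, bin_width)
    diffs = []
    for a, b in zip(edges[:-1], edges[1:]):
        mu = (i_up >= a) & (i_up < b)
        md = (i_down >= a) & (i_down < b)
        if mu.any() and md.any():
            diffs.append(f_up[mu].mean() - f_down[md].mean())
    return float(np.mean(diffs)) if diffs else None


def run_zap(
    variant: str,
    amplitude: float,
    zap: ZapParameters | None = None,
    model: ModelSpec | None = None,
    options: SolverOptions | None = None,
) -> ExperimentResult:
    """Response to the symmetric exponential-chirp (zap) current.

    Reports the first- and last-cycle voltage peaks, spikes per zap cycle,
    and a mirror-symmetry score (mean |spike-count difference| between each
    cycle and its time-mirrored partner; 0 for a perfectly history-free
    response).
    """
    model = model or ModelSpec.variant(variant)
    base_zap = zap or ZapParameters()
    zap = ZapParameters(amplitude, base_zap.f0, base_zap.fmax, base_zap.tau_half)
    rr = _rest_state(model)
    if not rr.converged:
        raise RuntimeError("no stable rest")
    opts = options or SolverOptions(output_dt=0.2)
    proto = zap_protocol(zap, onset=PRE_STIMULUS)
    total = 2000.0 * zap.tau_half
    trace = integrate(rr.state, proto, PRE_STIMULUS + total + 1000.0, model, opts)
    train = detect_spikes(trace)

    edges = _zap_cycle_edges(zap, onset=PRE_STIMULUS)
    counts, vpeaks = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        counts.append(len(train.in_window(a, b)))
        w = trace.window(a, b)
        vpeaks.append(float(w.V.max()))
    counts_arr = np.array(counts)
    sym = float(np.mean(np.abs(counts_arr - counts_arr[::-1]))) if len(counts) else None
    rows = _rows(variant, {"amplitude_pA": amplitude}, {
        "n_spikes": len(train),
        "first_cycle_Vpeak_mV": vpeaks[0] if vpeaks else None,
        "last_cycle_Vpeak_mV": vpeaks[-1] if vpeaks else None,
        "first_cycle_spikes": counts[0] if counts else None,
        "last_cycle_spikes": counts[-1] if counts else None,
        "symmetry_score": sym,
    })
    df = pd.DataFrame(rows)
    return ExperimentResult(
        "zap", df,
        {"variant": variant, "zap": vars(zap) | {"lam_per_s": zap.lam},
         "cycle_spike_counts": counts},
    )


def _zap_cycle_edges(zap: ZapParameters, onset: float) -> np.ndarray:
    """Cycle boundaries (ms): current minima, where the chirp phase hits 2*pi*k.

    Acceleration-half boundaries from inverting the accumulated phase;
    deceleration half mirrored.
    """
    lam, f0 = zap.lam, zap.f0
    half_ms = zap.tau_half * 1000.0
    ks = []
    k = 1
    while True:
        x = 1.0 + k * lam / f0
        t = np.log(x) / lam  # s
        if t >= zap.tau_half:
            break
        ks.append(t * 1000.0)
        k += 1
    accel = np.array(ks)
    edges = np.concatenate([[0.0], accel, [half_ms], 2 * half_ms - accel[::-1], [2 * half_ms]])
    return onset + np.unique(edges)


def run_memory_protocol(
    delays_s: Sequence[float],
    model: ModelSpec | None = None,
    test_amp: float = 22.0,
    test_dur: float = 200.0,
    main_amp: float = 50.0,
    main_dur: float = 5000.0,
    options: SolverOptions | None = None,
    include_isolated_control: bool = False,
) -> ExperimentResult:
    """Test-pulse excitability probing during the AHP.

    Each delay is an independent simulation from the same rest state (the
    responses are overlaid, never chained).  Reports the spike count and
    time-to-first-spike of the pre-stimulus (baseline) and post-stimulus
    test pulses; optionally an isolated late test pulse with the main
    stimulus omitted, which should match baseline exactly.
    """
    model = model or ModelSpec.variant("DynDyn")
    rr = _rest_state(model)
    if not rr.converged:
        raise RuntimeError("no stable rest")
    opts = options or SolverOptions(output_dt=0.1)
    rows: list[dict] = []
    variant = model.switches.name
    baseline_done = False
    for delay in delays_s:
        proto, times = memory_protocol(delay, test_amp, test_dur, main_amp, main_dur)
        trace = integrate(rr.state, proto, times.post_end + 300.0, model, opts)
        train = detect_spikes(trace)
        pre = train.in_window(times.pre_onset, times.pre_end + 50.0)
        post = train.in_window(times.post_onset, times.post_end + 50.0)
        if not baseline_done:
            rows += _rows(variant, {"delay_s": "baseline"}, {
                "test_spikes": len(pre),
                "T1_ms": time_to_first_spike(pre, times.pre_onset),
            })
            baseline_done = True
        rows += _rows(variant, {"delay_s": float(delay)}, {
            "test_spikes": len(post),
            "T1_ms": time_to_first_spike(post, times.post_onset),
        })
        if include_isolated_control:
            proto_c, times_c = memory_protocol(
                delay, test_amp, test_dur, main_amp, main_dur, include_main=False
            )
            trace_c = integrate(rr.state, proto_c, times_c.post_end + 300.0, model, opts)
            train_c = detect_spikes(trace_c)
            iso = train_c.in_window(times_c.post_onset, times_c.post_end + 50.0)
            rows += _rows(variant, {"delay_s": f"isolated_{delay:g}"}, {
                "test_spikes": len(iso),
                "T1_ms": time_to_first_spike(iso, times_c.post_onset),
            })
    return ExperimentResult(
        "memory_protocol", pd.DataFrame(rows),
        {"variant": variant, "test_pA": test_amp, "main_pA": main_amp},
    )


def run_pump_sweep(
    parameter: str,
    values: Sequence[float],
    amplitude: float = 50.0,
    duration: float = 5000.0,
    tail: float = AHP_TAIL,
    base: ModelSpec | None = None,
) -> ExperimentResult:
    """Step response while sweeping one pump parameter (others at default).

    Every sweep point re-derives its own rest state first — the resting
    [Na+] and V shift with the pump activation curve.  Points without a
    stable rest are flagged, not dropped.
    """
    if parameter not in ("Ipumpmax", "NaH", "NaS"):
        raise ValueError("parameter must be one of Ipumpmax, NaH, NaS")
    base = base or ModelSpec.variant("DynDyn")
    rows: list[dict] = []
    variant = base.switches.name
    for v in values:
        pump = replace(base.pump, **{parameter: float(v)})
        model = replace(base, pump=pump)
        cond = {"parameter": parameter, "param_value": float(v)}
        rr = _rest_state(model)
        if not rr.converged:
            rows.append({"variant": variant, **cond, "metric": "rest",
                         "value": np.nan, "status": "no stable rest"})
            continue
        m, _ = run_step_response(model, amplitude, duration, tail, rr.state)
        rows += _rows(variant, cond, {
            "V_rest_mV": rr.state.V,
            "Na_rest_mM": rr.state.Na_in,
            "IFR_ini_Hz": m.IFR_ini,
            "IFR_fin_Hz": m.IFR_fin,
            "s_adapt_Hz_per_s": m.s_adapt,
            "AHPamp_mV": m.AHPamp,
            "T_half_s": m.T_half,
            "classification": m.classification,
        })
    return ExperimentResult(
        "pump_sweep", pd.DataFrame(rows),
        {"parameter": parameter, "amplitude_pA": amplitude},
    )


def run_burst_survey(
    param_sets: Sequence[tuple[float, float, float, float]],
    duration_s: float = 50.0,
    base: ModelSpec | None = None,
    options: SolverOptions | None = None,
) -> ExperimentResult:
    """Long constant injections across pump-parameter sets (activity survey).

    Each set is (Ipumpmax, NaH, NaS, Iinj).  Runs start from the model's own
    rest when one exists, else from the standard cold start (V=-60 mV,
    gating at steady state, [Na+]=Na_rest).  Classification: silent, tonic,
    bursting (with burst metrics) or premature_then_silent.
    """
    base = base or ModelSpec.variant("DynDyn")
    opts = options or SolverOptions(output_dt=0.2)
    rows: list[dict] = []
    variant = base.switches.name
    dur_ms = duration_s * 1000.0
    for (ipm, nah, nas, iinj) in param_sets:
        model = replace(base, pump=PumpParameters(ipm, nah, nas))
        cond = {"Ipumpmax": ipm, "NaH": nah, "NaS": nas, "Iinj_pA": iinj}
        rr = _rest_state(model)
        if rr.converged:
            init = rr.state
        else:
            init = NeuronState(-60.0, resting_gating(-60.0), base.env.Na_rest)
        proto = step_current(iinj, 0.0, dur_ms) if iinj != 0 else zero_current()
        trace = integrate(init, proto, dur_ms, model, opts)
        train = detect_spikes(trace)
        bm = burst_segmentation(train, record_end=dur_ms)
        if len(train) == 0:
            cls = "silent"
        elif bm is not None:
            cls = "bursting"
        elif train.spike_times[-1] < 0.5 * dur_ms:
            cls = "premature_then_silent"
        else:
            cls = "tonic"
        rows += _rows(variant, cond, {
            "classification": cls,
            "n_spikes": len(train),
            "burst_period_s": bm.period if bm else None,
            "burst_duration_s": bm.burst_duration if bm else None,
            "duty_cycle": bm.duty_cycle if bm else None,
        })
    return ExperimentResult(
        "burst_survey", pd.DataFrame(rows), {"duration_s": duration_s}
    )
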