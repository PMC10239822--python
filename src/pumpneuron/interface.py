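"""Configuration schema, trace/metrics file I/O.

A run is fully described by a declarative YAML mapping mirroring the model's
type structure (variant, membrane, pump, environment, solver, stimulus).
Unknown keys are rejected and all physical values are validated before any
simulation starts, so a config file fully determines every output byte
except timestamps.  Traces are written as CSV with unit-bearing column
names and ``#``-prefixed metadata headers; metric summaries as flat JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .core_model import (
    MembraneParameters,
    PumpParameters,
    SodiumEnvironment,
    VariantSwitches,
)
from .dynamics_engine import ModelSpec, SimulationTrace, SolverOptions
from .stimulus import (
    StimulusProtocol,
    ZapParameters,
    memory_protocol,
    ramp_current,
    step_current,
    zap_protocol,
    zero_current,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "parse_config",
    "write_trace",
    "read_trace",
    "write_metrics",
    "validate_metrics",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ("t_ms", "V_mV", "Na_mM", "ENa_mV", "Ipump_pA", "Iinj_pA")


class ConfigError(ValueError):
    """Configuration rejected; message names the offending field."""


@dataclass(frozen=True)
class RunConfig:
    """Validated single-run configuration."""

    model: ModelSpec
    stimulus: StimulusProtocol
    duration_ms: float
    solver: SolverOptions = SolverOptions()
    stimulus_spec: dict = field(default_factory=dict)


def _build(cls, mapping: dict, section: str):
    """Instantiate a parameter dataclass from a mapping, strictly."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{section}: expected a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


_STIMULUS_KEYS = {
    "step": {"amplitude_pA", "onset_ms", "duration_ms"},
    "ramp": {"peak_pA", "up_ms", "down_ms", "onset_ms"},
    "zap": {"Izapmax_pA", "f0_Hz", "fmax_Hz", "tau_half_s", "onset_ms"},
    "test_pulse_memory": {
        "delay_s", "test_amp_pA", "test_dur_ms", "main_amp_pA", "main_dur_ms"
    },
    "none": set(),
}


def _build_stimulus(spec: dict) -> StimulusProtocol:
    if not spec:
        return zero_current()
    if "type" not in spec:
        raise ConfigError("stimulus: missing 'type'")
    kind = spec["type"]
    if kind not in _STIMULUS_KEYS:
        raise ConfigError(
            f"stimulus: unknown type {kind!r}; expected {sorted(_STIMULUS_KEYS)}"
        )
    extra = set(spec) - _STIMULUS_KEYS[kind] - {"type"}
    if extra:
        raise ConfigError(f"stimulus({kind}): unknown keys {sorted(extra)}")
    try:
        if kind == "none":
            return zero_current()
        if kind == "step":
            return step_current(
                spec["amplitude_pA"], spec.get("onset_ms", 1000.0), spec["duration_ms"]
            )
        if kind == "ramp":
            return ramp_current(
                spec["peak_pA"], spec["up_ms"], spec["down_ms"], spec.get("onset_ms", 1000.0)
            )
        if kind == "zap":
            zp = ZapParameters(
                Izapmax=spec.get("Izapmax_pA", 30.5),
                f0=spec.get("f0_Hz", 0.1),
                fmax=spec.get("fmax_Hz", 5.0),
                tau_half=spec.get("tau_half_s", 20.0),
            )
            return zap_protocol(zp, onset=spec.get("onset_ms", 1000.0))
        proto, _times = memory_protocol(
            spec["delay_s"],
            spec.get("test_amp_pA", 22.0),
            spec.get("test_dur_ms", 200.0),
            spec.get("main_amp_pA", 50.0),
            spec.get("main_dur_ms", 5000.0),
        )
        return proto
    except KeyError as exc:
        raise ConfigError(f"stimulus({kind}): missing key {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"stimulus({kind}): {exc}") from exc


_TOP_KEYS = {
    "variant", "switches", "membrane", "pump", "environment", "solver",
    "stimulus", "duration_ms",
}


def parse_config(mapping: dict) -> RunConfig:
    """Validate a config mapping and build a :class:`RunConfig`."""
    if not isinstance(mapping, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(mapping) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"top level: unknown keys {sorted(unknown)}")
    if "variant" in mapping and "switches" in mapping:
        raise ConfigError("give either 'variant' or 'switches', not both")
    if "switches" in mapping:
        switches = _build(VariantSwitches, mapping["switches"], "switches")
    else:
        name = mapping.get("variant", "DynDyn")
        try:
            switches = VariantSwitches.from_name(name)
        except ValueError as exc:
            raise ConfigError(f"variant: {exc}") from exc
    model = ModelSpec(
        params=_build(MembraneParameters, mapping.get("membrane", {}), "membrane"),
        pump=_build(PumpParameters, mapping.get("pump", {}), "pump"),
        env=_build(SodiumEnvironment, mapping.get("environment", {}), "environment"),
        switches=switches,
    )
    solver = _build(SolverOptions, mapping.get("solver", {}), "solver")
    stim_spec = mapping.get("stimulus", {}) or {}
    stimulus = _build_stimulus(stim_spec)
    duration = mapping.get("duration_ms")
    if duration is None:
        duration = stimulus.end + 1000.0 if stimulus.end > 0 else 1000.0
    if not (duration > 0):
        raise ConfigError("duration_ms: must be positive")
    return RunConfig(model, stimulus, float(duration), solver, dict(stim_spec))


def load_config(path) -> RunConfig:
    """Read and validate a YAML config file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    return parse_config(mapping or {})


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def write_trace(trace: SimulationTrace, path) -> None:
    """Write a trace as CSV (15 significant digits) with metadata headers."""
    if len(trace.t) == 0:
        raise ValueError("refusing to write an empty trace")
    meta = {
        "software_version": __version__,
        "variant": trace.model.switches.name,
        "membrane": dataclasses.asdict(trace.model.params),
        "pump": dataclasses.asdict(trace.model.pump),
        "environment": dataclasses.asdict(trace.model.env),
        "solver": dataclasses.asdict(trace.options),
        **trace.metadata,
    }
    cols = np.column_stack([
        trace.t, trace.V, trace.Na_in, trace.ENa, trace.Ipump, trace.Iinj
    ])
    with open(path, "w") as fh:
        fh.write(f"# pumpneuron-trace {json.dumps(meta)}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        np.savetxt(fh, cols, fmt="%.15g", delimiter=",")


@dataclass
class TraceRecord:
    """A trace read back from disk (sampled series only, no raw gating)."""

    t: np.ndarray
    V: np.ndarray
    Na_in: np.ndarray
    ENa: np.ndarray
    Ipump: np.ndarray
    Iinj: np.ndarray
    metadata: dict = field(default_factory=dict)


def read_trace(path) -> TraceRecord:
    """Read a trace CSV written by :func:`write_trace`."""
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            payload = line.lstrip("# ").strip()
            if payload.startswith("pumpneuron-trace"):
                meta = json.loads(payload[len("pumpneuron-trace"):])
        elif line.strip():
            body_start = i
            break
    header = lines[body_start].strip().split(",")
    if tuple(header) != TRACE_COLUMNS:
        raise ValueError(
            f"{path}: line {body_start + 1}: expected columns "
            f"{','.join(TRACE_COLUMNS)}, found {','.join(header)}"
        )
    try:
        data = np.loadtxt(lines[body_start + 1:], delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed numeric body: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path}: trace has no samples")
    return TraceRecord(*(data[:, i] for i in range(6)), metadata=meta)


# ---------------------------------------------------------------------------
# Metrics JSON
# ---------------------------------------------------------------------------

#: Minimal schema for metric summary files: field name -> (types, nullable).
METRICS_SCHEMA: dict[str, tuple[tuple[type, ...], bool]] = {
    "IFR_ini_Hz": ((int, float), True),
    "IFR_fin_Hz": ((int, float), True),
    "s_adapt_Hz_per_s": ((int, float), True),
    "AHPamp_mV": ((int, float), True),
    "T_half_s": ((int, float), True),
    "n_spikes": ((int,), False),
    "classification": ((str,), False),
}


def write_metrics(metrics, path) -> dict:
    """Write a step-response metrics object as flat JSON; returns the dict."""
    record = {
        "IFR_ini_Hz": metrics.IFR_ini,
        "IFR_fin_Hz": metrics.IFR_fin,
        "s_adapt_Hz_per_s": metrics.s_adapt,
        "AHPamp_mV": metrics.AHPamp,
        "T_half_s": metrics.T_half,
        "n_spikes": metrics.n_spikes,
        "classification": metrics.classification.value,
        "software_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
    return record


def validate_metrics(record: dict) -> None:
    """Check a metrics record against :data:`METRICS_SCHEMA` (raises on error)."""
    for name, (types, nullable) in METRICS_SCHEMA.items():
        if name not in record:
            raise ValueError(f"metrics record missing field {name!r}")
        v = record[name]
        if v is None:
            if not nullable:
                raise ValueError(f"metrics field {name!r} may not be null")
        elif not isinstance(v, types) or isinstance(v, bool):
            raise ValueError(f"metrics field {name!r} has wrong type {type(v).__name__}")
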