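"""Numerical integration of the model, rest-state determination, traces.

The reference integrator is the adaptive, stiffness-switching LSODA method
(through :func:`scipy.integrate.odeint`) with tight tolerances; spikes are
~1 ms events riding on tens-of-seconds sodium dynamics, so an adaptive
stiffness-capable solver is the right tool.  A fixed-step classical
Runge-Kutta (RK4) integrator is kept alongside purely as a cross-validation
oracle.  Stimulus breakpoints (step onsets/offsets) partition the
integration so discontinuities are never smeared across a solver step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq, root

from . import core_model as cm
from .core_model import (
    MembraneParameters,
    NeuronState,
    PumpParameters,
    SodiumEnvironment,
    VariantSwitches,
)
from .stimulus import StimulusProtocol, zero_current

__all__ = [
    "SolverOptions",
    "SimulationTrace",
    "RestResult",
    "ModelSpec",
    "find_rest",
    "integrate",
    "rk4_integrate",
]


@dataclass(frozen=True)
class SolverOptions:
    """Integration settings.

    abs_tol / rel_tol follow the published tolerances verbatim (note the
    absolute tolerance is the larger of the two).  output_dt is the trace
    sampling interval only; the adaptive solver steps independently of it.
    """

    abs_tol: float = 1.49012e-8
    rel_tol: float = 1e-10
    max_step: float = 0.0  # 0 = no cap
    output_dt: float = 0.05

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0 or self.output_dt <= 0:
            raise ValueError("solver tolerances and output_dt must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Bundle of all model parameters plus the variant switches."""

    params: MembraneParameters = MembraneParameters()
    pump: PumpParameters = PumpParameters()
    env: SodiumEnvironment = SodiumEnvironment()
    switches: VariantSwitches = VariantSwitches()

    @classmethod
    def variant(cls, name: str, **overrides: Any) -> "ModelSpec":
        """ModelSpec for a named variant (ConCon/DynCon/DynDyn)."""
        return cls(switches=VariantSwitches.from_name(name), **overrides)

    def rhs_args(self) -> tuple:
        return (self.params, self.pump, self.env, self.switches)


@dataclass
class SimulationTrace:
    """Uniformly sampled record of a simulation.

    All series share the time grid `t` (ms): membrane potential V (mV),
    intracellular sodium Na_in (mM), effective sodium reversal ENa (mV),
    pump current Ipump (pA) and injected current Iinj (pA).  `y` keeps the
    full raw state matrix (V, 7 gating variables, Na) for diagnostics.
    """

    t: np.ndarray
    y: np.ndarray
    Iinj: np.ndarray
    model: ModelSpec
    options: SolverOptions
    metadata: dict = field(default_factory=dict)

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def Na_in(self) -> np.ndarray:
        return self.y[:, 8]

    @property
    def ENa(self) -> np.ndarray:
        if self.model.switches.ena_dynamic:
            env = self.model.env
            return env.RT_over_F * np.log(env.Na_out / self.Na_in)
        return np.full_like(self.t, self.model.env.ENa_rest)

    @property
    def Ipump(self) -> np.ndarray:
        p = self.model.pump
        return p.Ipumpmax / (1.0 + np.exp((p.NaH - self.Na_in) / p.NaS))

    def final_state(self) -> NeuronState:
        return cm.vector_to_state(self.y[-1])

    def window(self, t0: float, t1: float) -> "SimulationTrace":
        """Sub-trace with t0 <= t <= t1 (same absolute time stamps)."""
        mask = (self.t >= t0) & (self.t <= t1)
        return SimulationTrace(
            self.t[mask], self.y[mask], self.Iinj[mask],
            self.model, self.options, dict(self.metadata),
        )


class SolverFailure(RuntimeError):
    """Adaptive integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_good_time: float):
        super().__init__(f"{message} (last good time {last_good_time:g} ms)")
        self.last_good_time = last_good_time


def integrate(
    initial: NeuronState,
    stimulus: StimulusProtocol,
    duration: float,
    model: ModelSpec = ModelSpec(),
    options: SolverOptions = SolverOptions(),
) -> SimulationTrace:
    """Integrate the model for `duration` ms under a stimulus protocol.

    The trace is sampled on the uniform grid k*output_dt; the solver is
    restarted at every stimulus breakpoint.  Sampling does not influence the
    solution (the adaptive solver's dense output interpolates onto the grid).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = options.output_dt
    breaks = [b for b in stimulus.breakpoints if 0.0 < b < duration]
    edges = [0.0] + breaks + [duration]
    t_global = np.arange(0, math.floor(round(duration / dt, 9)) + 1) * dt

    y0 = cm.state_to_vector(initial)
    args = model.rhs_args()
    ts: list[np.ndarray] = [t_global[:1]]
    ys: list[np.ndarray] = [y0[None, :].copy()]
    kwargs = {}
    if options.max_step > 0:
        kwargs["hmax"] = options.max_step
    for t0, t1 in zip(edges, edges[1:]):
        inner = t_global[(t_global > t0 + 1e-9) & (t_global <= t1 + 1e-9)]
        grid = np.concatenate([[t0], inner])
        on_grid = np.ones(len(grid), dtype=bool)
        on_grid[0] = False  # segment start was emitted by the previous segment
        if len(grid) == 1 or grid[-1] < t1 - 1e-9:
            grid = np.concatenate([grid, [t1]])
            on_grid = np.concatenate([on_grid, [False]])
        # ramps/zaps vary inside a segment, so the stimulus callable is
        # evaluated in the RHS at solver time, not frozen per segment
        sol, info = odeint(
            cm.rhs,
            y0,
            grid,
            args=(stimulus, *args),
            rtol=options.rel_tol,
            atol=options.abs_tol,
            tfirst=True,
            full_output=True,
            mxstep=10_000_000,
            **kwargs,
        )
        if info["message"] != "Integration successful.":
            raise SolverFailure(info["message"], float(info["tcur"][-1]))
        y0 = sol[-1]
        ts.append(grid[on_grid])
        ys.append(sol[on_grid])
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    if not model.switches.na_dynamic:
        y[:, 8] = initial.Na_in  # frozen concentration is exactly constant
    Iinj = stimulus.sample(t)
    return SimulationTrace(
        t, y, Iinj, model, options,
        metadata={"stimulus": stimulus.description, "duration_ms": duration},
    )


def rk4_integrate(
    initial: NeuronState,
    stimulus: StimulusProtocol,
    duration: float,
    dt: float,
    model: ModelSpec = ModelSpec(),
    record_every: int = 1,
) -> SimulationTrace:
    """Fixed-step classical Runge-Kutta integration (cross-validation oracle).

    Deliberately simple and slow; used in tests to confirm the adaptive
    reference solution, never for production runs.
    """
    n = int(round(duration / dt))
    y = cm.state_to_vector(initial)
    args = model.rhs_args()
    ts = [0.0]
    ys = [y.copy()]
    for k in range(n):
        t = k * dt
        k1 = cm.rhs(t, y, stimulus, *args)
        k2 = cm.rhs(t + dt / 2, y + dt / 2 * k1, stimulus, *args)
        k3 = cm.rhs(t + dt / 2, y + dt / 2 * k2, stimulus, *args)
        k4 = cm.rhs(t + dt, y + dt * k3, stimulus, *args)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (k + 1) % record_every == 0:
            ts.append((k + 1) * dt)
            ys.append(y.copy())
    t_arr = np.array(ts)
    y_arr = np.array(ys)
    opts = SolverOptions(output_dt=dt * record_every)
    return SimulationTrace(
        t_arr, y_arr, stimulus.sample(t_arr), model, opts,
        metadata={"integrator": "rk4", "dt_ms": dt},
    )


@dataclass(frozen=True)
class RestResult:
    """Outcome of rest-state determination.

    `converged` is False for parameter regimes that are legitimately
    oscillatory (endogenous bursters) — callers must check it rather than
    rely on `state` alone.  `residual` is the max absolute component of the
    state derivative at `state`.
    """

    state: NeuronState | None
    converged: bool
    residual: float
    message: str = ""


def _rest_equations(model: ModelSpec):
    """Reduced fixed-point system with gating eliminated at x_inf(V)."""
    params, pump, env, switches = model.rhs_args()

    def currents_at(V: float, Na: float) -> cm.CurrentBreakdown:
        state = NeuronState(V=V, gating=cm.resting_gating(V), Na_in=Na)
        return cm.membrane_currents(state, params, pump, env, switches)

    return currents_at


def find_rest(
    model: ModelSpec = ModelSpec(),
    options: SolverOptions = SolverOptions(),
    relax_duration: float = 200_000.0,
    initial_V: float = -60.0,
    residual_tol: float = 1e-7,
) -> RestResult:
    """Locate the silent resting state by relaxation plus root polishing.

    Relaxes the model for `relax_duration` ms with no stimulus (robust in
    the face of multistability), checks that the trajectory has actually
    settled, then polishes the endpoint with a root solve of the reduced
    fixed-point system.  Oscillatory regimes are reported as non-converged
    ("no stable rest"), not as an exception.
    """
    params, pump, env, switches = model.rhs_args()
    Na0 = env.Na_rest
    init = NeuronState(V=initial_V, gating=cm.resting_gating(initial_V), Na_in=Na0)
    relax_opts = SolverOptions(
        abs_tol=options.abs_tol, rel_tol=options.rel_tol, output_dt=10.0
    )
    trace = integrate(init, zero_current(), relax_duration, model, relax_opts)
    tail = trace.V[int(0.75 * len(trace.V)):]
    v_span = float(np.ptp(tail))
    if v_span > 0.01:
        return RestResult(
            None, False, math.inf,
            f"no stable rest: V still varies by {v_span:.3g} mV at the end "
            f"of a {relax_duration/1000:.0f} s relaxation (oscillatory regime)",
        )
    end = trace.final_state()

    currents_at = _rest_equations(model)
    if switches.na_dynamic:
        def eqs(x):
            c = currents_at(x[0], x[1])
            return [c.total, c.sodium_flux_sum]

        sol = root(eqs, [end.V, end.Na_in], tol=1e-13)
        V_star, Na_star = sol.x
    else:
        def balance(V):
            return currents_at(V, Na0).total

        V_star = brentq(balance, end.V - 2.0, end.V + 2.0, xtol=1e-13)
        Na_star = Na0
    polished = NeuronState(
        V=float(V_star), gating=cm.resting_gating(float(V_star)), Na_in=float(Na_star)
    )
    deriv = cm.state_derivative(0.0, polished, 0.0, params, pump, env, switches)
    residual = float(np.max(np.abs(deriv)))
    if residual > residual_tol:
        return RestResult(
            None, False, residual,
            f"relaxation settled but derivative residual {residual:.3g} "
            f"exceeds {residual_tol:g}",
        )
    # guard against polishing onto a different (unstable) fixed point
    if abs(polished.V - end.V) > 0.5:
        return RestResult(
            None, False, residual,
            "root polish moved far from the relaxed state; no stable rest",
        )
    return RestResult(polished, True, residual, "converged")
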