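"""Membrane model: currents, gating kinetics, Na/K pump and sodium handling.

The model is a single-compartment, conductance-based neuron loosely based on
*Drosophila* larval motoneurons.  It carries a transient sodium current
(NaT), a persistent sodium current (NaP), fast and slow delayed-rectifier
potassium currents (Kf, Ks), sodium and potassium leak currents, and an
electrogenic Na/K-ATPase pump whose outward current depends sigmoidally on
the intracellular sodium concentration.  Intracellular sodium in a thin
sub-membrane shell may evolve with the sodium fluxes (channel influx vs. 3:2
pump extrusion), and the sodium reversal potential may follow the Nernst
equation of the momentary concentration.

Unit system, fixed throughout the package: mV, ms, nS, pA, pF, mM, pL.
In these units nS*mV = pA and pA/pF = mV/ms hold identically, so the
voltage equation needs no conversion factor; the sodium balance needs the
single constant 1/(F*Vol) converting pA to mM/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "MembraneParameters",
    "PumpParameters",
    "SodiumEnvironment",
    "VariantSwitches",
    "GatingState",
    "NeuronState",
    "CurrentBreakdown",
    "GATING_NAMES",
    "gating_kinetics",
    "pump_current",
    "nernst_sodium",
    "membrane_currents",
    "state_derivative",
    "state_to_vector",
    "vector_to_state",
    "resting_gating",
]

#: Faraday constant, C/mol.
FARADAY = 96485.332
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314462618

#: Order of the gating variables everywhere in the package.
GATING_NAMES = ("mNaT", "hNaT", "mNaP", "mKf", "hKf1", "hKf2", "nKs")


class ModelInputError(ValueError):
    """Raised for physically invalid inputs (non-finite V, [Na+] <= 0, ...)."""


@dataclass(frozen=True)
class MembraneParameters:
    """Passive and maximal-conductance parameters of the membrane.

    Capacitance in pF, conductances in nS, potassium reversal in mV.
    """

    C: float = 4.0
    gNaT: float = 100.0
    gNaP: float = 0.80
    gNaleak: float = 1.2
    gKf: float = 15.1
    gKs: float = 50.0
    gKleak: float = 3.75
    EK: float = -80.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ModelInputError("membrane capacitance must be positive")
        for name in ("gNaT", "gNaP", "gNaleak", "gKf", "gKs", "gKleak"):
            if getattr(self, name) < 0:
                raise ModelInputError(f"conductance {name} must be non-negative")


@dataclass(frozen=True)
class PumpParameters:
    """Na/K pump activation curve: maximal current (pA), half-activation
    sodium concentration NaH (mM) and slope factor NaS (mM)."""

    Ipumpmax: float = 75.0
    NaH: float = 40.0
    NaS: float = 10.0

    def __post_init__(self) -> None:
        if self.Ipumpmax <= 0 or self.NaH <= 0 or self.NaS <= 0:
            raise ModelInputError("pump parameters must be positive")


@dataclass(frozen=True)
class SodiumEnvironment:
    """Ionic environment of the sodium subsystem.

    Na_out: extracellular sodium (mM, held constant).
    Vol: volume of the sub-membrane shell whose concentration the sodium
        currents influence (pL).
    T: absolute temperature (K); 25 degrees C.
    Na_rest: reference resting intracellular sodium (mM), the value at which
        the constant-concentration variants are frozen.
    ENa_rest: sodium reversal at Na_rest (mV), the value at which the
        constant-reversal variants are frozen.
    """

    Na_out: float = 135.0
    Vol: float = 0.549
    T: float = 298.15
    Na_rest: float = 40.08
    ENa_rest: float = 31.2

    def __post_init__(self) -> None:
        if self.Na_out <= 0 or self.Vol <= 0 or self.T <= 0 or self.Na_rest <= 0:
            raise ModelInputError("environment parameters must be positive")

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage R*T/F in mV."""
        return GAS_CONSTANT * self.T / FARADAY * 1000.0

    @property
    def na_flux_factor(self) -> float:
        """Conversion from pA to mM/ms for the shell: 1/(F*Vol).

        pA/(C/mol * pL) works out to mM/ms with no further factor:
        1e-15 C/ms / (96485 C/mol) / 0.549e-12 L = 1.888e-5 mol/(L ms)
        ... in mM/ms after the 1e3 mM/M cancellation.
        """
        return 1.0 / (FARADAY * self.Vol)


@dataclass(frozen=True)
class VariantSwitches:
    """Concentration/reversal switches selecting the model variant.

    na_dynamic: intracellular [Na+] evolves with the sodium fluxes; when
        False it is frozen at Na_rest.
    ena_dynamic: E_Na follows the Nernst equation of the momentary [Na+];
        when False it is frozen at ENa_rest.

    A dynamic reversal without a dynamic concentration is meaningless and
    rejected.  Named presets: ConCon (False, False), DynCon (True, False),
    DynDyn (True, True).
    """

    na_dynamic: bool = True
    ena_dynamic: bool = True

    def __post_init__(self) -> None:
        if self.ena_dynamic and not self.na_dynamic:
            raise ModelInputError(
                "ena_dynamic=True requires na_dynamic=True: E_Na cannot vary "
                "while [Na+] is frozen"
            )

    @classmethod
    def from_name(cls, name: str) -> "VariantSwitches":
        try:
            return cls(*_VARIANTS[name])
        except KeyError:
            raise ModelInputError(
                f"unknown variant {name!r}; expected one of {sorted(_VARIANTS)}"
            ) from None

    @property
    def name(self) -> str:
        return {v: k for k, v in _VARIANTS.items()}[(self.na_dynamic, self.ena_dynamic)]


_VARIANTS = {
    "ConCon": (False, False),
    "DynCon": (True, False),
    "DynDyn": (True, True),
}


@dataclass(frozen=True)
class GatingState:
    """Dimensionless activation/inactivation variables, each in [0, 1]."""

    mNaT: float
    hNaT: float
    mNaP: float
    mKf: float
    hKf1: float
    hKf2: float
    nKs: float

    def __post_init__(self) -> None:
        for name in GATING_NAMES:
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ModelInputError(f"gating variable {name}={x} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GATING_NAMES])


@dataclass(frozen=True)
class NeuronState:
    """Full dynamical state: V (mV), gating, intracellular sodium (mM)."""

    V: float
    gating: GatingState
    Na_in: float

    def __post_init__(self) -> None:
        if self.Na_in <= 0:
            raise ModelInputError("intracellular sodium must be positive")
        if not math.isfinite(self.V):
            raise ModelInputError("membrane potential must be finite")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Instantaneous currents in pA; outward positive.

    At rest the sodium currents are negative (inward) and the pump current
    positive (net outward, 3 Na+ out per 2 K+ in).  ENa_effective is the
    sodium reversal actually used (frozen or Nernst, per the switches).
    """

    INaT: float
    INaP: float
    INaleak: float
    IKf: float
    IKs: float
    IKleak: float
    Ipump: float
    ENa_effective: float

    @property
    def total(self) -> float:
        """Sum of all membrane currents (pA), the term opposing I_inj."""
        return (
            self.INaT + self.INaP + self.INaleak
            + self.IKf + self.IKs + self.IKleak + self.Ipump
        )

    @property
    def sodium_flux_sum(self) -> float:
        """Numerator of the sodium balance: INaT + INaP + INaleak + 3*Ipump."""
        return self.INaT + self.INaP + self.INaleak + 3.0 * self.Ipump


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def _gating_scalar(V: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Steady states and time constants at one voltage, plain floats.

    Boltzmann forms 1/(1+exp((V-Vh)/k)) with the fitted midpoints/slopes;
    tau(mNaP) = 1 ms and tau(hKf2) = 116 ms are voltage independent.
    """
    mNaT_inf = 1.0 / (1.0 + math.exp((V + 29.13) / -8.922))
    tau_mNaT = 3.861 - 3.434 / (1.0 + math.exp((V + 51.35) / -5.98))
    hNaT_inf = 1.0 / (1.0 + math.exp((V + 40.0) / 6.048))
    tau_hNaT = 2.834 - 2.371 / (1.0 + math.exp((V + 21.9) / -2.641))
    mNaP_inf = 1.0 / (1.0 + math.exp((V + 48.77) / -3.68))
    mKf_inf = 1.0 / (1.0 + math.exp((V + 17.55) / -7.27))
    tau_mKf = 1.94 + 2.66 / (1.0 + math.exp((V - 8.12) / 7.96))
    hKf1_inf = 1.0 / (1.0 + math.exp((V + 45.0) / 6.0))
    hKf2_inf = 1.0 / (1.0 + math.exp((V + 44.2) / 1.5))
    tau_hKf = 1.79 + 515.8 / (1.0 + math.exp((V + 147.4) / -28.66))
    nKs_inf = 1.0 / (1.0 + math.exp((V + 12.85) / -19.91))
    tau_nKs = 2.03 + 1.96 / (1.0 + math.exp((V - 29.83) / 3.32))
    x_inf = (mNaT_inf, hNaT_inf, mNaP_inf, mKf_inf, hKf1_inf, hKf2_inf, nKs_inf)
    tau = (tau_mNaT, tau_hNaT, 1.0, tau_mKf, tau_hKf, 116.0, tau_nKs)
    return x_inf, tau


def gating_kinetics(V: float) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state values and time constants of the 7 gating variables.

    Parameters
    ----------
    V : float
        Membrane potential, mV.

    Returns
    -------
    (x_inf, tau)
        Arrays of length 7 ordered as :data:`GATING_NAMES`; ``x_inf`` in
        [0, 1], ``tau`` in ms (all positive).
    """
    if not math.isfinite(V):
        raise ModelInputError("membrane potential must be finite")
    x_inf, tau = _gating_scalar(float(V))
    return np.array(x_inf), np.array(tau)


def resting_gating(V: float) -> GatingState:
    """Gating state with every variable at its steady state for voltage V."""
    x_inf, _ = gating_kinetics(V)
    return GatingState(*x_inf)


# ---------------------------------------------------------------------------
# Pump and Nernst
# ---------------------------------------------------------------------------

def pump_current(Na_in: float, pump: PumpParameters = PumpParameters()) -> float:
    """Na/K pump current (pA, outward positive) at sodium concentration Na_in.

    Sigmoidal, instantaneous activation:
    Ipumpmax / (1 + exp((NaH - [Na+]) / NaS)); strictly increasing in
    [Na+] and bounded in (0, Ipumpmax).
    """
    if not (Na_in > 0):
        raise ModelInputError("intracellular sodium must be positive")
    return pump.Ipumpmax / (1.0 + math.exp((pump.NaH - Na_in) / pump.NaS))


def nernst_sodium(Na_in: float, env: SodiumEnvironment = SodiumEnvironment()) -> float:
    """Sodium Nernst reversal potential (mV): (RT/F) ln(Na_out / Na_in)."""
    if not (Na_in > 0):
        raise ModelInputError("intracellular sodium must be positive")
    return env.RT_over_F * math.log(env.Na_out / Na_in)


# ---------------------------------------------------------------------------
# Currents and the right-hand side
# ---------------------------------------------------------------------------

def membrane_currents(
    state: NeuronState,
    params: MembraneParameters = MembraneParameters(),
    pump: PumpParameters = PumpParameters(),
    env: SodiumEnvironment = SodiumEnvironment(),
    switches: VariantSwitches = VariantSwitches(),
) -> CurrentBreakdown:
    """All instantaneous membrane currents for a given state.

    The fast potassium current mixes its two inactivation variables as
    0.95*hKf1 + 0.05*hKf2 (a slow minor component with a fixed 116 ms time
    constant).  E_Na is the frozen resting reversal unless the reversal
    switch is dynamic, in which case it is the Nernst potential of the
    momentary [Na+].
    """
    g = state.gating
    ENa = (
        nernst_sodium(state.Na_in, env) if switches.ena_dynamic else env.ENa_rest
    )
    dNa = state.V - ENa
    dK = state.V - params.EK
    return CurrentBreakdown(
        INaT=params.gNaT * g.mNaT**3 * g.hNaT * dNa,
        INaP=params.gNaP * g.mNaP * dNa,
        INaleak=params.gNaleak * dNa,
        IKf=params.gKf * g.mKf**4 * (0.95 * g.hKf1 + 0.05 * g.hKf2) * dK,
        IKs=params.gKs * g.nKs**4 * dK,
        IKleak=params.gKleak * dK,
        Ipump=pump_current(state.Na_in, pump),
        ENa_effective=ENa,
    )


def state_to_vector(state: NeuronState) -> np.ndarray:
    """Pack a state into the flat vector [V, 7 gating variables, Na_in]."""
    return np.array([state.V, *state.gating.as_array(), state.Na_in])


def vector_to_state(y: np.ndarray) -> NeuronState:
    """Inverse of :func:`state_to_vector`; clips gating rounding noise."""
    gating = GatingState(*np.clip(y[1:8], 0.0, 1.0))
    return NeuronState(V=float(y[0]), gating=gating, Na_in=float(y[8]))


def rhs(
    t: float,
    y: np.ndarray,
    I_inj,
    params: MembraneParameters,
    pump: PumpParameters,
    env: SodiumEnvironment,
    switches: VariantSwitches,
) -> np.ndarray:
    """Right-hand side of the model ODEs on the flat state vector.

    ``I_inj`` is a callable t (ms) -> injected current (pA); positive
    injected current depolarizes.  Written with scalar math (not numpy ops)
    because adaptive solvers evaluate it millions of times per run.
    """
    V = y[0]
    mNaT, hNaT, mNaP, mKf, hKf1, hKf2, nKs = y[1:8]
    Na = y[8]

    if switches.ena_dynamic:
        ENa = env.RT_over_F * math.log(env.Na_out / Na)
    else:
        ENa = env.ENa_rest
    dNa_drive = V - ENa
    dK_drive = V - params.EK

    INaT = params.gNaT * mNaT * mNaT * mNaT * hNaT * dNa_drive
    INaP = params.gNaP * mNaP * dNa_drive
    INaleak = params.gNaleak * dNa_drive
    IKf = params.gKf * mKf**4 * (0.95 * hKf1 + 0.05 * hKf2) * dK_drive
    IKs = params.gKs * nKs**4 * dK_drive
    IKleak = params.gKleak * dK_drive
    Ipump = pump.Ipumpmax / (1.0 + math.exp((pump.NaH - Na) / pump.NaS))

    dV = -(INaT + INaP + INaleak + IKf + IKs + IKleak + Ipump - I_inj(t)) / params.C

    x_inf, tau = _gating_scalar(V)
    out = np.empty(9)
    out[0] = dV
    out[1] = (x_inf[0] - mNaT) / tau[0]
    out[2] = (x_inf[1] - hNaT) / tau[1]
    out[3] = (x_inf[2] - mNaP) / tau[2]
    out[4] = (x_inf[3] - mKf) / tau[3]
    out[5] = (x_inf[4] - hKf1) / tau[4]
    out[6] = (x_inf[5] - hKf2) / tau[5]
    out[7] = (x_inf[6] - nKs) / tau[6]
    if switches.na_dynamic:
        out[8] = -(INaT + INaP + INaleak + 3.0 * Ipump) / (FARADAY * env.Vol)
    else:
        out[8] = 0.0
    return out


def state_derivative(
    t: float,
    state: NeuronState,
    I_inj: float,
    params: MembraneParameters = MembraneParameters(),
    pump: PumpParameters = PumpParameters(),
    env: SodiumEnvironment = SodiumEnvironment(),
    switches: VariantSwitches = VariantSwitches(),
) -> np.ndarray:
    """Time derivative of the flat state vector for a constant injection.

    Returns d/dt of [V (mV/ms), gating (1/ms), Na_in (mM/ms)].
    """
    if not math.isfinite(I_inj):
        raise ModelInputError("injected current must be finite")
    return rhs(t, state_to_vector(state), lambda _t: I_inj, params, pump, env, switches)
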