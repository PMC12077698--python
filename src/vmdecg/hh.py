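"""Hodgkin-Huxley membrane simulation and the three arrhythmia signal classes.

The membrane is modelled as a single excitable patch obeying the classical
four-variable Hodgkin-Huxley equations

    Cm dV/dt = I - gNa m^3 h (V - ENa) - gK n^4 (V - EK) - gL (V - EL)

with first-order kinetics for the gating variables m, h, n driven by the
voltage-dependent rate functions alpha/beta.  Three signal classes are
produced:

* ``model0`` - the unmodified equations (normal rhythm),
* ``model1`` - the applied current I is multiplied by the exponentially
  attenuated sinusoid ``psi(t) = exp(-4 t) sin(2 pi t)``,
* ``model2`` - the right-hand side of dh/dt is multiplied by ``psi(t)``,

which perturb, respectively, the excitation drive and the sodium
inactivation recovery, producing two distinct arrhythmic morphologies.

``psi`` takes its time argument in seconds measured from the onset of each
stimulus period (it restarts every beat), so the arrhythmic character
persists across a periodized record instead of decaying away after the
first beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HHParameters",
    "HHState",
    "StimulusProtocol",
    "ARRHYTHMIA_MODELS",
    "gating_rates",
    "steady_state_gating",
    "psi",
    "hh_derivatives",
    "simulate_membrane",
]

#: Valid arrhythmia-model tags.
ARRHYTHMIA_MODELS = ("model0", "model1", "model2")

# Window (mV) around a removable singularity inside which the series limit
# of the alpha_m / alpha_n rate expressions is used instead of the 0/0 form.
_SINGULARITY_EPS = 1e-7


@dataclass(frozen=True)
class HHParameters:
    """Membrane parameters (classical squid-axon values by default).

    Units: Cm in uF/cm^2, conductances in mS/cm^2, potentials in mV.
    """

    Cm: float = 1.0
    gNa: float = 120.0
    gK: float = 36.0
    gL: float = 0.3
    ENa: float = 50.0
    EK: float = -77.0
    EL: float = -54.4

    def __post_init__(self) -> None:
        if not self.Cm > 0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        if min(self.gNa, self.gK, self.gL) < 0:
            raise ValueError("conductances must be non-negative")


@dataclass
class HHState:
    """Instantaneous membrane state: potential V (mV) and gates m, h, n."""

    V: float
    m: float
    h: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n], dtype=float)


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular current pulses.

    amplitude in uA/cm^2; pulse_start, pulse_duration and period in ms.
    The default drives rhythmic firing (one suprathreshold 1 ms pulse every
    300 ms).  For a 1 ms pulse the firing threshold of the default membrane
    sits near 14 uA/cm^2, so 20 uA/cm^2 gives a robust full-overshoot spike.
    """

    amplitude: float = 20.0
    pulse_start: float = 5.0
    pulse_duration: float = 1.0
    period: float = 300.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if not self.period > self.pulse_duration >= 0:
            raise ValueError("require period > pulse_duration >= 0")

    def current(self, t: float) -> float:
        """Applied current at time t (ms), periodic in ``period``."""
        tau = t % self.period
        if self.pulse_start <= tau < self.pulse_start + self.pulse_duration:
            return self.amplitude
        return 0.0


def gating_rates(V):
    """Rate constants (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n).

    ``V`` may be a scalar (mV) or an array; rates are in ms^-1.  The
    removable singularities of alpha_m (V = -40) and alpha_n (V = -55)
    evaluate to their analytic limits (1.0 and 0.1 respectively).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")

    xm = V + 40.0
    with np.errstate(divide="ignore", invalid="ignore"):
        am = np.where(
            np.abs(xm) < _SINGULARITY_EPS,
            1.0,
            0.1 * xm / (1.0 - np.exp(-xm / 10.0)),
        )
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    xn = V + 55.0
    with np.errstate(divide="ignore", invalid="ignore"):
        an = np.where(
            np.abs(xn) < _SINGULARITY_EPS,
            0.1,
            0.01 * xn / (1.0 - np.exp(-xn / 10.0)),
        )
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    if V.ndim == 0:
        return (float(am), float(bm), float(ah), float(bh), float(an), float(bn))
    return am, bm, ah, bh, an, bn


def steady_state_gating(V):
    """Steady-state gate values (m_inf, h_inf, n_inf) = alpha/(alpha+beta)."""
    am, bm, ah, bh, an, bn = gating_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def psi(t):
    """Exponentially attenuated sinusoid ``exp(-4 t) sin(2 pi t)``, t in s."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("psi is defined for t >= 0")
    out = np.exp(-4.0 * t) * np.sin(2.0 * np.pi * t)
    return float(out) if t.ndim == 0 else out


def hh_derivatives(state, t, params=None, stim=None, model="model0"):
    """Time derivatives (dV/dt, dm/dt, dh/dt, dn/dt) at time t (ms).

    ``model`` selects the signal class: the arrhythmic variants multiply the
    applied current (model1) or the whole dh/dt right-hand side (model2) by
    ``psi`` evaluated at the time since beat onset, in seconds.
    """
    params = params or HHParameters()
    stim = stim or StimulusProtocol()
    if model not in ARRHYTHMIA_MODELS:
        raise ValueError(f"unknown arrhythmia model {model!r}")
    if isinstance(state, HHState):
        V, m, h, n = state.V, state.m, state.h, state.n
    else:
        V, m, h, n = state
    I = stim.current(t)
    t_beat_s = (t % stim.period) / 1000.0  # seconds since beat onset
    if model == "model1":
        I = I * psi(t_beat_s)
    am, bm, ah, bh, an, bn = gating_rates(V)
    dV = (
        I
        - params.gNa * m**3 * h * (V - params.ENa)
        - params.gK * n**4 * (V - params.EK)
        - params.gL * (V - params.EL)
    ) / params.Cm
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    if model == "model2":
        dh = dh * psi(t_beat_s)
    return dV, dm, dh, dn


def _rhs_scalar(y, t, params, stim, model, I=None):
    """Scalar-math RHS used inside the integrator loop (avoids numpy overhead).

    ``I`` overrides the instantaneous stimulus (the integrator holds the
    rectangular pulse constant across each step, sampled at the step
    midpoint, so stage evaluations at step edges cannot mis-sample it).
    """
    V, m, h, n = y
    tau = t % stim.period
    if I is None:
        I = (
            stim.amplitude
            if stim.pulse_start <= tau < stim.pulse_start + stim.pulse_duration
            else 0.0
        )
    ts = tau / 1000.0
    psi_t = math.exp(-4.0 * ts) * math.sin(2.0 * math.pi * ts)
    if model == "model1":
        I = I * psi_t

    xm = V + 40.0
    am = 1.0 if abs(xm) < _SINGULARITY_EPS else 0.1 * xm / (1.0 - math.exp(-xm / 10.0))
    bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    xn = V + 55.0
    an = 0.1 if abs(xn) < _SINGULARITY_EPS else 0.01 * xn / (1.0 - math.exp(-xn / 10.0))
    bn = 0.125 * math.exp(-(V + 65.0) / 80.0)

    dV = (
        I
        - params.gNa * m * m * m * h * (V - params.ENa)
        - params.gK * n * n * n * n * (V - params.EK)
        - params.gL * (V - params.EL)
    ) / params.Cm
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    if model == "model2":
        dh = dh * psi_t
    return dV, dm, dh, dn


def simulate_membrane(
    params=None,
    model="model0",
    stim=None,
    duration=300.0,
    dt=0.01,
    fs=300.0,
    V0=-65.0,
    return_gates=False,
):
    """Integrate the membrane ODEs and return the trace resampled to ``fs``.

    Fixed-step fourth-order Runge-Kutta at step ``dt`` (ms, default 0.01),
    initial condition V = ``V0`` with gates at their steady-state values,
    linear resampling of V(t) to the output rate ``fs`` (Hz).  Gating
    variables are clamped to [0, 1] after every step (the dynamics keep
    them inside up to roundoff; model2's sign-flipping dh/dt can graze the
    boundary).

    Returns ``(t_out_ms, v_out_mV)``, or ``(t_out_ms, v_out_mV, gates)``
    with the (m, h, n) history resampled to the same grid when
    ``return_gates`` is set.  Raises ``FloatingPointError`` naming the
    offending time if the integration produces non-finite values.
    """
    params = params or HHParameters()
    stim = stim or StimulusProtocol()
    if model not in ARRHYTHMIA_MODELS:
        raise ValueError(f"unknown arrhythmia model {model!r}")
    if not (duration > 0 and dt > 0):
        raise ValueError("duration and dt must be positive")

    m0, h0, n0 = steady_state_gating(V0)
    y = (float(V0), float(m0), float(h0), float(n0))
    n_steps = int(round(duration / dt))
    t_grid = np.empty(n_steps + 1)
    v_grid = np.empty(n_steps + 1)
    g_grid = np.empty((n_steps + 1, 3)) if return_gates else None
    t_grid[0], v_grid[0] = 0.0, y[0]
    if return_gates:
        g_grid[0] = y[1:]

    rhs = _rhs_scalar
    for i in range(n_steps):
        t = i * dt
        I_step = stim.current(t + 0.5 * dt)  # held constant across the step
        k1 = rhs(y, t, params, stim, model, I_step)
        y2 = tuple(y[j] + 0.5 * dt * k1[j] for j in range(4))
        k2 = rhs(y2, t + 0.5 * dt, params, stim, model, I_step)
        y3 = tuple(y[j] + 0.5 * dt * k2[j] for j in range(4))
        k3 = rhs(y3, t + 0.5 * dt, params, stim, model, I_step)
        y4 = tuple(y[j] + dt * k3[j] for j in range(4))
        k4 = rhs(y4, t + dt, params, stim, model, I_step)
        y = tuple(
            y[j] + dt / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j]) for j in range(4)
        )
        # clamp gates to [0,1]; they can graze the boundary by roundoff
        y = (
            y[0],
            min(1.0, max(0.0, y[1])),
            min(1.0, max(0.0, y[2])),
            min(1.0, max(0.0, y[3])),
        )
        if not all(math.isfinite(v) for v in y):
            raise FloatingPointError(
                f"integration produced non-finite state at t={t + dt:.4f} ms"
            )
        t_grid[i + 1] = t + dt
        v_grid[i + 1] = y[0]
        if return_gates:
            g_grid[i + 1] = y[1:]

    if fs is None:  # raw integrator grid, no resampling
        if return_gates:
            return t_grid, v_grid, g_grid
        return t_grid, v_grid
    t_out = np.arange(0.0, duration, 1000.0 / fs)
    v_out = np.interp(t_out, t_grid, v_grid)
    if return_gates:
        gates = np.column_stack([np.interp(t_out, t_grid, g_grid[:, j]) for j in range(3)])
        return t_out, v_out, gates
    return t_out, v_out
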