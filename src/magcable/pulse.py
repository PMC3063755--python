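"""Stimulator pulse: capacitor discharge through a series RLC circuit.

The magnetic stimulator is a capacitor charged to ``V0`` discharging through
the coil (inductance ``L``), its resistance ``R`` and capacitance ``C``.
With I(0) = 0 and dI/dt(0) = V0/L the discharge current is either

* overdamped  (R > 2 sqrt(L/C)):  I(t) = V0/(L*beta) * exp(-alpha t) sinh(beta t)
* underdamped (R < 2 sqrt(L/C)):  I(t) = V0/(L*omega) * exp(-alpha t) sin(omega t)

with alpha = R/(2L), omega0^2 = 1/(LC), beta^2 = alpha^2 - omega0^2 and
omega^2 = omega0^2 - alpha^2.  The critically damped boundary
R = 2 sqrt(L/C) is classified as overdamped and evaluated with its exact
limit I(t) = (V0/L) t exp(-alpha t).  The temporal factor fed to the field
is the analytic derivative dI/dt.

All quantities SI (volts, ohms, henries, farads, seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RLCParams",
    "PulseTrace",
    "classify_mode",
    "waveform",
    "device_energy",
    "effective_duration",
    "pulse_trace",
]


@dataclass(frozen=True)
class RLCParams:
    """Series RLC discharge parameters.

    ``V0`` is the capacitor charge voltage -- the stimulus strength and the
    variable searched over by the magnetic-threshold protocols.
    """

    V0: float
    R: float
    L: float
    C: float

    def __post_init__(self) -> None:
        for name in ("R", "L", "C"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.V0 < 0:
            raise ValueError("V0 must be >= 0")

    @property
    def alpha(self) -> float:
        """Damping rate R/(2L), 1/s."""
        return self.R / (2.0 * self.L)

    @property
    def omega0(self) -> float:
        """Undamped angular frequency 1/sqrt(LC), rad/s."""
        return 1.0 / np.sqrt(self.L * self.C)

    @property
    def omega(self) -> float:
        """Underdamped angular frequency sqrt(omega0^2 - alpha^2), rad/s."""
        d = self.omega0**2 - self.alpha**2
        return float(np.sqrt(d)) if d > 0 else 0.0

    def with_voltage(self, v0: float) -> "RLCParams":
        return replace(self, V0=v0)


def classify_mode(params: RLCParams) -> str:
    """'underdamped' iff R < 2 sqrt(L/C); the boundary counts as overdamped."""
    return "underdamped" if params.R < 2.0 * np.sqrt(params.L / params.C) else "overdamped"


def waveform(t, params: RLCParams):
    """Coil current I(t) and its exact derivative dI/dt(t).

    ``t`` may be a scalar or array of times in seconds; times before zero
    return zero (no current before the discharge is triggered).
    """
    t = np.asarray(t, dtype=float)
    a = params.alpha
    vl = params.V0 / params.L
    disc = a**2 - params.omega0**2
    tt = np.where(t >= 0, t, 0.0)
    if disc < 0:  # underdamped
        w = np.sqrt(-disc)
        env = np.exp(-a * tt)
        i = vl / w * env * np.sin(w * tt)
        didt = vl / w * env * (w * np.cos(w * tt) - a * np.sin(w * tt))
    elif disc == 0.0:  # critical boundary (classified overdamped)
        env = np.exp(-a * tt)
        i = vl * tt * env
        didt = vl * env * (1.0 - a * tt)
    else:  # overdamped
        b = np.sqrt(disc)
        env = np.exp(-a * tt)
        i = vl / b * env * np.sinh(b * tt)
        didt = vl / b * env * (b * np.cosh(b * tt) - a * np.sinh(b * tt))
    i = np.where(t >= 0, i, 0.0)
    didt = np.where(t >= 0, didt, 0.0)
    if i.ndim == 0:
        return float(i), float(didt)
    return i, didt


def device_energy(params: RLCParams) -> float:
    """Initial capacitor energy (1/2) C V0^2, joules."""
    return 0.5 * params.C * params.V0**2


def effective_duration(params: RLCParams) -> float:
    """A documented, monotone-in-C pulse-duration metric, seconds.

    Underdamped: one full oscillation period 2 pi / omega.  Overdamped: time
    for |I| to decay to 5 % of its peak (found by root bracketing after the
    current peak).  Both choices grow as sqrt(C) at fixed L for small R.
    """
    if classify_mode(params) == "underdamped":
        return 2.0 * np.pi / params.omega
    p = params if params.V0 > 0 else params.with_voltage(1.0)
    a, o0 = p.alpha, p.omega0
    disc = a**2 - o0**2
    if disc == 0.0:
        t_peak = 1.0 / a
    else:
        b = np.sqrt(disc)
        t_peak = np.arctanh(b / a) / b  # where dI/dt = 0
    i_peak, _ = waveform(t_peak, p)
    target = 0.05 * abs(i_peak)

    def f(t):
        return abs(waveform(t, p)[0]) - target

    hi = t_peak
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, t_peak, hi, xtol=1e-12))


@dataclass
class PulseTrace:
    """A sampled discharge: times, I(t) and dI/dt(t), plus the damping mode."""

    mode: str
    times: np.ndarray
    current: np.ndarray
    dcurrent: np.ndarray
    params: RLCParams


def pulse_trace(params: RLCParams, dt: float, t_stop: float) -> PulseTrace:
    """Sample the closed-form waveform on a uniform grid (for export/plots)."""
    times = np.arange(0.0, t_stop + 0.5 * dt, dt)
    i, didt = waveform(times, params)
    return PulseTrace(classify_mode(params), times, i, didt, params)
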