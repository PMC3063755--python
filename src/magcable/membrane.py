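"""Membrane mechanisms: classic Hodgkin-Huxley, passive leak, and myelin.

The excitable membrane is the classic squid-axon Hodgkin-Huxley model at
6.3 degC with the standard constants (the same set NEURON ships as its
``hh`` defaults):

    gNa = 0.120 S/cm^2   ENa =  50.0 mV
    gK  = 0.036 S/cm^2   EK  = -77.0 mV
    gL  = 0.0003 S/cm^2  EL  = -54.3 mV
    cm  = 1 uF/cm^2      axial resistivity Ra = 35.4 ohm*cm
    v_init = -65 mV

Myelinated internodes are idealised as zero-conductance membrane with the
capacitance reduced to 0.04 uF/cm^2; nodes of Ranvier carry full HH.
Passive dendrites default to g_pas = 1/30000 S/cm^2, e_pas = -65 mV (the
source experiments leave these unstated; both are configurable and the
sweep drivers report sensitivity to them).

An optional ``na_shift`` (mV) moves the Na activation and inactivation
curves toward hyperpolarised potentials, the manipulation used to vary
current threshold: small shifts (up to ~3 mV) lower it monotonically;
larger shifts make the classic HH cell spontaneously active.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HH",
    "MechanismSpec",
    "CableConstants",
    "default_mechanisms",
    "hh_rates",
    "hh_steady_state",
    "hh_resting_potential",
    "membrane_current",
]


class HH:
    """Classic Hodgkin-Huxley constants (6.3 degC)."""

    GNA = 0.120  # S/cm^2
    GK = 0.036
    GL = 0.0003
    ENA = 50.0  # mV
    EK = -77.0
    EL = -54.3
    CM = 1.0  # uF/cm^2
    RA = 35.4  # ohm*cm
    V_INIT = -65.0  # mV
    CELSIUS = 6.3


@dataclass(frozen=True)
class MechanismSpec:
    """Membrane parameters for one mechanism kind.

    ``kind`` is one of 'hh', 'passive', 'myelin'.  Conductances in S/cm^2,
    reversals in mV, ``cm`` in uF/cm^2, ``Ra`` in ohm*cm.  ``na_shift``
    shifts Na activation/inactivation toward hyperpolarised potentials (mV).
    """

    kind: str
    gnabar: float = 0.0
    gkbar: float = 0.0
    gl: float = 0.0
    ena: float = HH.ENA
    ek: float = HH.EK
    el: float = HH.EL
    g_pas: float = 0.0
    e_pas: float = -65.0
    cm: float = HH.CM
    Ra: float = HH.RA
    na_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("hh", "passive", "myelin"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        for name in ("gnabar", "gkbar", "gl", "g_pas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cm <= 0 or self.Ra <= 0:
            raise ValueError("cm and Ra must be > 0")

    def replace(self, **kw) -> "MechanismSpec":
        return replace(self, **kw)


def default_mechanisms() -> dict[str, MechanismSpec]:
    """Mechanism table keyed by section tag.

    'soma', 'axon' and 'node' tags carry full HH; 'dend'/'apic' are passive;
    'myelin' is capacitance-only (cm = 0.04 uF/cm^2, g = 0).
    """
    hh = MechanismSpec("hh", gnabar=HH.GNA, gkbar=HH.GK, gl=HH.GL)
    passive = MechanismSpec("passive", g_pas=1.0 / 30000.0, e_pas=-65.0)
    myelin = MechanismSpec("myelin", cm=0.04)
    return {
        "hh": hh,
        "soma": hh,
        "axon": hh,
        "node": hh,
        "passive": passive,
        "dend": passive,
        "apic": passive,
        "myelin": myelin,
    }


def hh_rates(v, na_shift: float = 0.0):
    """HH rate constants (1/ms) at 6.3 degC; removable singularities handled.

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n).  ``na_shift``
    (mV, positive = hyperpolarising) is applied to the m and h rates only.
    """
    v = np.asarray(v, dtype=float)
    vna = v + na_shift
    with np.errstate(over="ignore", invalid="ignore"):  # extreme-v exp overflow is benign
        x = vna + 40.0
        am = np.where(np.abs(x) < 1e-7, 1.0, 0.1 * x / (1.0 - np.exp(-x / 10.0)))
        bm = 4.0 * np.exp(-(vna + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(vna + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(vna + 35.0) / 10.0))
        xn = v + 55.0
        an = np.where(
            np.abs(xn) < 1e-7, 0.1, 0.01 * xn / (1.0 - np.exp(-xn / 10.0))
        )
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def hh_steady_state(v, na_shift: float = 0.0):
    """Steady-state gating values (m_inf, h_inf, n_inf) at potential v (mV)."""
    am, bm, ah, bh, an, bn = hh_rates(v, na_shift)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def membrane_current(mech: MechanismSpec, v, gates=None):
    """Total ionic membrane current density, mA/cm^2 (outward positive).

    For 'hh' pass ``gates = (m, h, n)``; for 'passive'/'myelin' gates are
    ignored.  Myelin with zero conductance returns 0 (purely capacitive
    membrane).
    """
    v = np.asarray(v, dtype=float)
    if mech.kind == "hh":
        if gates is None:
            raise ValueError("hh mechanism needs gates (m, h, n)")
        m, h, n = gates
        ina = mech.gnabar * m**3 * h * (v - mech.ena)
        ik = mech.gkbar * n**4 * (v - mech.ek)
        il = mech.gl * (v - mech.el)
        return ina + ik + il
    return mech.g_pas * (v - mech.e_pas)


def hh_resting_potential(mech: MechanismSpec, bracket=(-90.0, -40.0)) -> float:
    """Resting potential: root of the steady-state HH ionic current, mV."""
    from scipy.optimize import brentq

    def f(v):
        return float(membrane_current(mech, v, hh_steady_state(v, mech.na_shift)))

    return float(brentq(f, *bracket, xtol=1e-10))


@dataclass(frozen=True)
class CableConstants:
    """Passive cable constants of a cylinder of given diameter.

    r_a: axial resistance per length (ohm/cm); r_m: membrane resistance times
    length (ohm*cm); lambda_um: space constant sqrt(r_m / r_a) in um; tau_ms:
    membrane time constant r_m_specific * cm in ms.
    """

    r_a: float
    r_m: float
    lambda_um: float
    tau_ms: float

    @classmethod
    def from_mech(cls, mech: MechanismSpec, diameter_um: float) -> "CableConstants":
        """Derive constants from a mechanism and a diameter.

        The membrane conductance used is the mechanism's total resting leak
        (g_pas for passive/myelin, gl for hh -- the leak sets the passive
        length scale of an HH cable).
        """
        if diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        g = mech.gl if mech.kind == "hh" else mech.g_pas
        if g <= 0:
            return cls(
                r_a=4.0 * mech.Ra / (np.pi * (diameter_um * 1e-4) ** 2),
                r_m=np.inf,
                lambda_um=np.inf,
                tau_ms=np.inf,
            )
        d_cm = diameter_um * 1e-4
        rm_specific = 1.0 / g  # ohm*cm^2
        r_m = rm_specific / (np.pi * d_cm)  # ohm*cm
        r_a = 4.0 * mech.Ra / (np.pi * d_cm**2)  # ohm/cm
        lam_cm = np.sqrt(r_m / r_a)
        tau = rm_specific * mech.cm * 1e-3  # (ohm*cm^2)(uF/cm^2) -> ms
        return cls(r_a=r_a, r_m=r_m, lambda_um=lam_cm * 1e4, tau_ms=tau)
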