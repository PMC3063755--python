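"""Branched cable solver under magnetic-stimulation drive.

The neuron tree is flattened into compartments (one node per compartment
centre, axial conductances between neighbouring centres, sealed ends).  The
membrane carries classic Hodgkin-Huxley, passive, or myelin mechanisms; the
magnetically induced drive enters each compartment as a current source with
zero reversal potential,

    I_j = [E_a(p_start) - E_a(p_end)] / r_a                      (amperes)

the difference form of the cable drive -(1/r_a) dE_a/da, where E_a is the
projection of the induced field onto the compartment axis and r_a the axial
resistance per unit length.  Positive I_j depolarises.  E_a separates as
S(x, y) . a_hat  times the temporal factor dI/dt, so the per-compartment
coefficients are computed once per geometry and scaled analytically at each
step (midpoint evaluation, consistent with the implicit stepper); no field
grid or interpolation is involved.

Spatial discretisation follows the d_lambda rule: compartments no longer
than ``d_lambda`` (default 0.1) times the AC length constant at 100 Hz.
Time integration is the theta method on the tree (backward Euler by default,
theta = 0.5 gives Crank-Nicolson), with staggered exponential-Euler gate
updates; the tree system is solved exactly per step by Hines elimination.

Internal units: um, ms, mV, nA, uS, nF (the NEURON convention); the coil
field module is SI and is converted here, in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .coil import Coil, spatial_field_many
from .membrane import HH, CableConstants, MechanismSpec, default_mechanisms, hh_steady_state
from .morphology import Neuron
from .pulse import RLCParams, waveform

__all__ = [
    "SimConfig",
    "SimResult",
    "IClamp",
    "SynapticEvent",
    "CableModel",
    "SimulationDiverged",
    "build_model",
    "induced_segment_currents",
    "activating_function_profile",
    "run",
    "input_resistance",
]


class SimulationDiverged(RuntimeError):
    def __init__(self, t_ms: float, comp: int, site: str):
        super().__init__(
            f"simulation diverged (non-finite membrane potential) at "
            f"t = {t_ms:.4f} ms in compartment {comp} ({site})"
        )
        self.t_ms = t_ms
        self.comp = comp


@dataclass
class SimConfig:
    """Simulation controls.

    dt in ms (default 0.001 = 1 us); ``record`` lists (section_name, pos)
    sites; ``pulse_delay`` shifts stimulus onset; ``settle_ms`` of unstimulated
    integration precedes t = 0 so every run starts from membrane steady state.
    ``theta`` = 1 is backward Euler, 0.5 Crank-Nicolson.
    """

    dt: float = 0.001
    t_stop: float = 5.0
    record: list = dc_field(default_factory=list)
    pulse_delay: float = 0.0
    settle_ms: float = 5.0
    theta: float = 1.0
    d_lambda: float = 0.1
    max_seg_um: float | None = None
    store_full: bool = False
    full_every: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_stop < self.pulse_delay:
            raise ValueError("t_stop must be >= pulse_delay")
        if not (0.5 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0.5, 1]")


@dataclass(frozen=True)
class IClamp:
    """Square current step at a site: positive amplitude depolarises."""

    site: tuple[str, float]
    amp_nA: float
    delay_ms: float = 0.0
    dur_ms: float = 1e9


@dataclass(frozen=True)
class SynapticEvent:
    """Alpha-function conductance synapse g(t) = gmax (t/tau) exp(1 - t/tau)."""

    site: tuple[str, float]
    onset_ms: float
    gmax_uS: float
    tau_ms: float = 2.0
    e_rev_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.gmax_uS < 0:
            raise ValueError("synaptic peak conductance must be >= 0")
        if self.tau_ms <= 0:
            raise ValueError("synaptic time constant must be > 0")


# ---------------------------------------------------------------------------
# model assembly


def _lambda_100hz_um(diam_um: float, Ra: float, cm: float) -> float:
    # NEURON's d_lambda rule: AC length constant at 100 Hz, in um
    return 1e5 * np.sqrt(diam_um / (4.0 * np.pi * 100.0 * Ra * cm))


@dataclass
class CableModel:
    """Flattened compartmental model (arrays indexed by compartment)."""

    neuron: Neuron
    mechanisms: dict[str, MechanismSpec]
    # geometry
    p0: np.ndarray  # (n, 3) um
    p1: np.ndarray
    diam: np.ndarray  # um
    length: np.ndarray  # um
    area: np.ndarray  # um^2
    sec_index: np.ndarray
    sec_pos: np.ndarray  # centre arclength fraction within section
    sec_names: list
    # electrical
    parent: np.ndarray  # compartment parent index, -1 at root
    g_axial: np.ndarray  # uS to parent
    cm_nF: np.ndarray
    is_hh: np.ndarray
    gna_uS: np.ndarray
    gk_uS: np.ndarray
    gl_uS: np.ndarray
    ena: np.ndarray
    ek: np.ndarray
    el: np.ndarray
    gpas_uS: np.ndarray
    epas: np.ndarray
    na_shift: np.ndarray
    r_a_ohm_per_m: np.ndarray
    mech_of_comp: list

    @property
    def n_comp(self) -> int:
        return len(self.diam)

    def comp_at(self, site: tuple[str, float]) -> int:
        """Compartment index nearest to (section name, arclength fraction)."""
        name, pos = site
        idx = self.sec_names.index(name)
        mask = self.sec_index == idx
        comps = np.where(mask)[0]
        return int(comps[np.argmin(np.abs(self.sec_pos[comps] - pos))])

    def site_of(self, comp: int) -> tuple[str, float]:
        return self.sec_names[int(self.sec_index[comp])], float(self.sec_pos[comp])


def build_model(
    neuron: Neuron,
    mechanisms: dict[str, MechanismSpec] | None = None,
    d_lambda: float = 0.1,
    max_seg_um: float | None = None,
) -> CableModel:
    """Discretise a neuron into compartments with mechanism arrays.

    Each geometric interval is subdivided so compartments are no longer than
    min(``max_seg_um``, ``d_lambda`` x the 100 Hz length constant).
    """
    mechs = dict(default_mechanisms())
    if mechanisms:
        mechs.update(mechanisms)

    sec_lookup = {id(s): i for i, s in enumerate(neuron.sections)}
    for s in neuron.sections:
        if s.parent is not None and sec_lookup[id(s.parent)] >= sec_lookup[id(s)]:
            raise ValueError("sections must be ordered parents-first")
        if s.mechanism not in mechs:
            raise ValueError(
                f"section {s.name}: no mechanism for tag {s.mechanism!r}"
            )

    cols: dict[str, list] = {k: [] for k in (
        "p0", "p1", "diam", "length", "sec_index", "sec_pos")}
    mech_of_comp: list[MechanismSpec] = []
    first_comp: dict[int, int] = {}
    last_comp: dict[int, int] = {}
    comp_parent: list[int] = []
    comps_of_sec: dict[int, list[int]] = {}

    n = 0
    for si, sec in enumerate(neuron.sections):
        mech = mechs[sec.mechanism]
        target = d_lambda * _lambda_100hz_um(float(np.min(sec.diams)), mech.Ra, mech.cm)
        if max_seg_um is not None:
            target = min(target, max_seg_um)
        arc0 = 0.0
        total = sec.length
        sec_comps: list[int] = []
        for seg in sec.segments:
            nsub = max(1, int(np.ceil(seg.length / target)))
            for k in range(nsub):
                a = seg.p_start + (seg.p_end - seg.p_start) * (k / nsub)
                b = seg.p_start + (seg.p_end - seg.p_start) * ((k + 1) / nsub)
                ln = seg.length / nsub
                cols["p0"].append(a)
                cols["p1"].append(b)
                cols["diam"].append(seg.diameter)
                cols["length"].append(ln)
                cols["sec_index"].append(si)
                cols["sec_pos"].append((arc0 + (k + 0.5) * ln) / total)
                mech_of_comp.append(mech)
                if sec_comps:
                    comp_parent.append(sec_comps[-1])
                else:
                    comp_parent.append(-2)  # resolved below
                sec_comps.append(n)
                n += 1
            arc0 += seg.length
        first_comp[si] = sec_comps[0]
        last_comp[si] = sec_comps[-1]
        comps_of_sec[si] = sec_comps

    # resolve section attachments
    parent = np.asarray(comp_parent, dtype=np.int64)
    for si, sec in enumerate(neuron.sections):
        if sec.parent is None:
            parent[first_comp[si]] = -1
        else:
            pi = sec_lookup[id(sec.parent)]
            pcomps = np.asarray(comps_of_sec[pi])
            pos = np.asarray([cols["sec_pos"][c] for c in pcomps])
            parent[first_comp[si]] = int(pcomps[np.argmin(np.abs(pos - sec.parent_pos))])

    diam = np.asarray(cols["diam"], dtype=float)
    length = np.asarray(cols["length"], dtype=float)
    area = np.pi * diam * length  # um^2

    cmv = np.array([m.cm for m in mech_of_comp])
    Ra = np.array([m.Ra for m in mech_of_comp])
    cm_nF = cmv * area * 1e-5  # uF/cm^2 * um^2 -> nF (pairs with uS, mV, ms, nA)
    is_hh = np.array([1 if m.kind == "hh" else 0 for m in mech_of_comp], dtype=np.int64)
    to_uS = area * 1e-2  # S/cm^2 * um^2 -> uS
    gna = np.array([m.gnabar for m in mech_of_comp]) * to_uS
    gk = np.array([m.gkbar for m in mech_of_comp]) * to_uS
    gl = np.array([m.gl for m in mech_of_comp]) * to_uS
    gpas = np.array([m.g_pas for m in mech_of_comp]) * to_uS
    ena = np.array([m.ena for m in mech_of_comp])
    ek = np.array([m.ek for m in mech_of_comp])
    el = np.array([m.el for m in mech_of_comp])
    epas = np.array([m.e_pas for m in mech_of_comp])
    nshift = np.array([m.na_shift for m in mech_of_comp])

    # half-compartment axial resistance, Mohm
    r_half = Ra * (length / 2.0) / (np.pi * (diam / 2.0) ** 2) / 100.0
    g_axial = np.zeros(n)
    for i in range(n):
        j = parent[i]
        if j >= 0:
            g_axial[i] = 1.0 / (r_half[i] + r_half[j])  # uS (1/Mohm)

    r_a_si = 4.0 * (Ra * 1e-2) / (np.pi * (diam * 1e-6) ** 2)  # ohm/m

    return CableModel(
        neuron=neuron,
        mechanisms=mechs,
        p0=np.asarray(cols["p0"], dtype=float),
        p1=np.asarray(cols["p1"], dtype=float),
        diam=diam,
        length=length,
        area=area,
        sec_index=np.asarray(cols["sec_index"], dtype=np.int64),
        sec_pos=np.asarray(cols["sec_pos"], dtype=float),
        sec_names=[s.name for s in neuron.sections],
        parent=parent,
        g_axial=g_axial,
        cm_nF=cm_nF,
        is_hh=is_hh,
        gna_uS=gna,
        gk_uS=gk,
        gl_uS=gl,
        ena=ena,
        ek=ek,
        el=el,
        gpas_uS=gpas,
        epas=epas,
        na_shift=nshift,
        r_a_ohm_per_m=r_a_si,
        mech_of_comp=mech_of_comp,
    )


# ---------------------------------------------------------------------------
# induced drive and the activating function


def _endpoint_field_projection(model: CableModel, coil: Coil) -> tuple[np.ndarray, np.ndarray]:
    """S . a_hat at each compartment's start and end (V/m per A/s)."""
    if np.any(model.p0[:, 2] != 0) or np.any(model.p1[:, 2] != 0):
        raise ValueError(
            "induced-field evaluation requires a planar neuron (z = 0); "
            "got nonzero z coordinates"
        )
    ahat = model.p1 - model.p0
    ahat = ahat / np.linalg.norm(ahat, axis=1)[:, None]
    s0 = spatial_field_many(model.p0[:, :2] * 1e-6, coil)
    s1 = spatial_field_many(model.p1[:, :2] * 1e-6, coil)
    ea0 = np.einsum("ij,ij->i", s0, ahat[:, :2])
    ea1 = np.einsum("ij,ij->i", s1, ahat[:, :2])
    return ea0, ea1


def induced_coefficients(model: CableModel, coil: Coil) -> np.ndarray:
    """Per-compartment induced current per unit dI/dt, nA per (A/s).

    I_j = [E_a(start) - E_a(end)] / r_a ; positive values depolarise.  The
    sign is fixed by the cable derivation (drive = -(1/r_a) dE_a/da) and
    pinned by the straight-axon polarity behaviour in the tests.
    """
    ea0, ea1 = _endpoint_field_projection(model, coil)
    return (ea0 - ea1) / model.r_a_ohm_per_m * 1e9


def induced_segment_currents(
    model_or_neuron, coil: Coil, dIdt: float, mechanisms=None
) -> np.ndarray:
    """Per-compartment induced transmembrane current (nA) at a given dI/dt (A/s)."""
    model = (
        model_or_neuron
        if isinstance(model_or_neuron, CableModel)
        else build_model(model_or_neuron, mechanisms)
    )
    return induced_coefficients(model, coil) * dIdt


def activating_function_profile(
    model_or_neuron, coil: Coil, mechanisms=None
) -> np.ndarray:
    """lambda^2 dE_a/da per compartment, in mV per unit temporal factor.

    Signed so that positive values predict depolarisation (the drive is
    -lambda^2 dE_a/da along the fibre).  Compartments with zero membrane
    conductance (myelin) have an infinite passive lambda and return inf.
    """
    model = (
        model_or_neuron
        if isinstance(model_or_neuron, CableModel)
        else build_model(model_or_neuron, mechanisms)
    )
    ea0, ea1 = _endpoint_field_projection(model, coil)
    lam_m = np.array(
        [
            CableConstants.from_mech(m, d).lambda_um * 1e-6
            for m, d in zip(model.mech_of_comp, model.diam)
        ]
    )
    dea_da = (ea1 - ea0) / (model.length * 1e-6)
    return -(lam_m**2) * dea_da * 1e3  # V -> mV


# ---------------------------------------------------------------------------
# the time-stepping kernel


@njit(cache=True)
def _kernel(
    v, m, h, n_g,
    parent, g_ax, cm_nF,
    is_hh, gna, gk, gl, ena, ek, el, gpas, epas, nshift,
    coef, gtemp,
    ic_node, ic_amp, ic_k0, ic_k1,
    syn_node, syn_gmax, syn_tau, syn_e, syn_t0,
    dt, theta,
    rec_idx, rec_out,
    full_out, full_every,
    crit, first_cross, cross_dvdt, vmax,
):
    nc = v.shape[0]
    nst = gtemp.shape[0]
    a_off = np.empty(nc)
    diag = np.empty(nc)
    rhs = np.empty(nc)
    gtot = np.empty(nc)
    egtot = np.empty(nc)

    for r in range(rec_idx.shape[0]):
        rec_out[r, 0] = v[rec_idx[r]]
    if full_out.shape[0] > 0:
        for i in range(nc):
            full_out[0, i] = v[i]

    for k in range(nst):
        # --- gate update (exponential Euler, rates at current v)
        for i in range(nc):
            if is_hh[i] == 1:
                vv = v[i] + nshift[i]
                x = vv + 40.0
                if abs(x) < 1e-7:
                    am = 1.0
                else:
                    am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
                bm = 4.0 * np.exp(-(vv + 65.0) / 18.0)
                ah = 0.07 * np.exp(-(vv + 65.0) / 20.0)
                bh = 1.0 / (1.0 + np.exp(-(vv + 35.0) / 10.0))
                xn = v[i] + 55.0
                if abs(xn) < 1e-7:
                    an = 0.1
                else:
                    an = 0.01 * xn / (1.0 - np.exp(-xn / 10.0))
                bn = 0.125 * np.exp(-(v[i] + 65.0) / 80.0)
                sm = am + bm
                sh = ah + bh
                sn = an + bn
                m[i] += (am / sm - m[i]) * (1.0 - np.exp(-dt * sm))
                h[i] += (ah / sh - h[i]) * (1.0 - np.exp(-dt * sh))
                n_g[i] += (an / sn - n_g[i]) * (1.0 - np.exp(-dt * sn))

        # --- membrane conductances and sources
        t_new = (k + 1) * dt
        for i in range(nc):
            g = gl[i] + gpas[i]
            eg = gl[i] * el[i] + gpas[i] * epas[i]
            if is_hh[i] == 1:
                gna_i = gna[i] * m[i] * m[i] * m[i] * h[i]
                gk_i = gk[i] * n_g[i] * n_g[i] * n_g[i] * n_g[i]
                g += gna_i + gk_i
                eg += gna_i * ena[i] + gk_i * ek[i]
            gtot[i] = g
            egtot[i] = eg
            rhs[i] = coef[i] * gtemp[k]

        for s in range(ic_node.shape[0]):
            if ic_k0[s] <= k < ic_k1[s]:
                rhs[ic_node[s]] += ic_amp[s]
        for s in range(syn_node.shape[0]):
            tt = t_new - syn_t0[s]
            if tt > 0.0:
                gs = syn_gmax[s] * (tt / syn_tau[s]) * np.exp(1.0 - tt / syn_tau[s])
                i = syn_node[s]
                gtot[i] += gs
                egtot[i] += gs * syn_e[s]

        # --- assemble theta-method system
        for i in range(nc):
            diag[i] = cm_nF[i] / dt + theta * gtot[i]
            rhs[i] += cm_nF[i] / dt * v[i] + egtot[i] - (1.0 - theta) * gtot[i] * v[i]
            a_off[i] = 0.0
        for i in range(nc):
            j = parent[i]
            if j >= 0:
                diag[i] += theta * g_ax[i]
                diag[j] += theta * g_ax[i]
                a_off[i] = -theta * g_ax[i]
                if theta != 1.0:
                    iax = (1.0 - theta) * g_ax[i] * (v[i] - v[j])
                    rhs[i] -= iax
                    rhs[j] += iax

        # --- Hines elimination (parents precede children)
        for i in range(nc - 1, 0, -1):
            j = parent[i]
            if j >= 0:
                f = a_off[i] / diag[i]
                diag[j] -= f * a_off[i]
                rhs[j] -= f * rhs[i]
        vold0 = v[0]
        v[0] = rhs[0] / diag[0]
        if not np.isfinite(v[0]):
            return k, 0
        for i in range(1, nc):
            j = parent[i]
            vo = v[i]
            v[i] = (rhs[i] - a_off[i] * v[j]) / diag[i]
            if not np.isfinite(v[i]):
                return k, i
            if v[i] > vmax[i]:
                vmax[i] = v[i]
            if first_cross[i] < 0 and vo < crit <= v[i]:
                first_cross[i] = k
                cross_dvdt[i] = (v[i] - vo) / dt
        if v[0] > vmax[0]:
            vmax[0] = v[0]
        if first_cross[0] < 0 and vold0 < crit <= v[0]:
            first_cross[0] = k
            cross_dvdt[0] = (v[0] - vold0) / dt

        for r in range(rec_idx.shape[0]):
            rec_out[r, k + 1] = v[rec_idx[r]]
        if full_out.shape[0] > 0 and (k + 1) % full_every == 0:
            row = (k + 1) // full_every
            if row < full_out.shape[0]:
                for i in range(nc):
                    full_out[row, i] = v[i]
    return -1, -1


# ---------------------------------------------------------------------------
# results


@dataclass
class SimResult:
    """Recorded membrane potentials plus per-compartment spike bookkeeping."""

    times: np.ndarray  # ms
    traces: dict  # site tuple -> mV array
    model: CableModel
    first_cross_ms: np.ndarray  # per compartment, nan if never crossed
    cross_dvdt: np.ndarray
    vmax: np.ndarray
    spike_criterion: float
    full_times: np.ndarray | None = None
    v_full: np.ndarray | None = None  # (n_store, n_comp)

    def trace(self, site) -> np.ndarray:
        if site in self.traces:
            return self.traces[site]
        for key in self.traces:
            if key[0] == site:
                return self.traces[key]
        raise KeyError(f"no recording at {site!r}")

    @property
    def fired(self) -> bool:
        return bool(np.any(np.isfinite(self.first_cross_ms)))

    def to_dataframe(self):
        import pandas as pd

        data = {"time_ms": self.times}
        for (name, pos), tr in self.traces.items():
            data[f"{name}@{pos:.3f}"] = tr
        return pd.DataFrame(data)

    def save_tsv(self, path, metadata: dict | None = None) -> None:
        """Delimited-text export: '#'-prefixed metadata header, then columns."""
        df = self.to_dataframe()
        lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
        Path(path).write_text(
            "\n".join(lines) + ("\n" if lines else "") + df.to_csv(sep="\t", index=False)
        )


def _steady_gates(model: CableModel, v: np.ndarray):
    m = np.zeros(model.n_comp)
    h = np.zeros(model.n_comp)
    n = np.zeros(model.n_comp)
    hhmask = model.is_hh == 1
    if np.any(hhmask):
        # the Na shift applies to m and h only; n follows the unshifted v
        mi, hi, _ = hh_steady_state(v[hhmask] + model.na_shift[hhmask])
        _, _, ni = hh_steady_state(v[hhmask])
        m[hhmask], h[hhmask], n[hhmask] = mi, hi, ni
    return m, h, n


def run(
    model_or_neuron,
    coil: Coil | None = None,
    pulse: RLCParams | None = None,
    mechanisms: dict[str, MechanismSpec] | None = None,
    config: SimConfig | None = None,
    iclamps: Sequence[IClamp] = (),
    synapses: Sequence[SynapticEvent] = (),
    v_init: float = HH.V_INIT,
    spike_criterion: float = 0.0,
) -> SimResult:
    """Integrate the assembled model and return recorded traces.

    The membrane is initialised at ``v_init`` with gates at steady state and
    relaxed for ``config.settle_ms`` of stimulus-free integration before
    t = 0; the magnetic pulse starts at ``config.pulse_delay``.
    """
    config = config or SimConfig()
    model = (
        model_or_neuron
        if isinstance(model_or_neuron, CableModel)
        else build_model(
            model_or_neuron, mechanisms, config.d_lambda, config.max_seg_um
        )
    )
    nc = model.n_comp
    dt = config.dt
    nst = int(round(config.t_stop / dt))

    # temporal factor dI/dt at step midpoints, A/s
    gtemp = np.zeros(nst)
    if coil is not None and pulse is not None and pulse.V0 != 0.0:
        tmid = (np.arange(nst) + 0.5) * dt - config.pulse_delay
        _, didt = waveform(tmid * 1e-3, pulse)
        gtemp = np.asarray(didt, dtype=float)
        coef = induced_coefficients(model, coil)
    else:
        coef = np.zeros(nc)

    v = np.full(nc, float(v_init))
    m, h, n = _steady_gates(model, v)

    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0)
    no_full = np.zeros((0, nc))
    no_rec = np.zeros((0, 1))

    if config.settle_ms > 0:
        nsettle = int(round(config.settle_ms / dt))
        fc = np.full(nc, -1, dtype=np.int64)
        err = _kernel(
            v, m, h, n,
            model.parent, model.g_axial, model.cm_nF,
            model.is_hh, model.gna_uS, model.gk_uS, model.gl_uS,
            model.ena, model.ek, model.el, model.gpas_uS, model.epas,
            model.na_shift,
            np.zeros(nc), np.zeros(nsettle),
            empty_i, empty_f, empty_i, empty_i,
            empty_i, empty_f, empty_f, empty_f, empty_f,
            dt, config.theta,
            empty_i, no_rec,
            no_full, 1,
            1e30, fc, np.zeros(nc), np.full(nc, -1e30),
        )
        if err[0] >= 0:
            raise SimulationDiverged(
                (err[0] + 1) * dt - config.settle_ms, err[1],
                "%s@%.3f" % model.site_of(err[1]),
            )

    rec_sites = [tuple(s) for s in config.record]
    rec_idx = np.asarray([model.comp_at(s) for s in rec_sites], dtype=np.int64)
    rec_out = np.zeros((len(rec_sites), nst + 1))

    if config.store_full:
        n_store = nst // config.full_every + 1
        full_out = np.zeros((n_store, nc))
    else:
        full_out = no_full

    ic_node = np.asarray([model.comp_at(c.site) for c in iclamps], dtype=np.int64)
    ic_amp = np.asarray([c.amp_nA for c in iclamps], dtype=float)
    ic_k0 = np.asarray([int(round(c.delay_ms / dt)) for c in iclamps], dtype=np.int64)
    ic_k1 = np.asarray(
        [int(round(min(c.delay_ms + c.dur_ms, config.t_stop) / dt)) for c in iclamps],
        dtype=np.int64,
    )
    syn_node = np.asarray([model.comp_at(s.site) for s in synapses], dtype=np.int64)
    syn_gmax = np.asarray([s.gmax_uS for s in synapses], dtype=float)
    syn_tau = np.asarray([s.tau_ms for s in synapses], dtype=float)
    syn_e = np.asarray([s.e_rev_mV for s in synapses], dtype=float)
    syn_t0 = np.asarray([s.onset_ms for s in synapses], dtype=float)

    first_cross = np.full(nc, -1, dtype=np.int64)
    cross_dvdt = np.zeros(nc)
    vmax = np.full(nc, -1e30)

    err = _kernel(
        v, m, h, n,
        model.parent, model.g_axial, model.cm_nF,
        model.is_hh, model.gna_uS, model.gk_uS, model.gl_uS,
        model.ena, model.ek, model.el, model.gpas_uS, model.epas,
        model.na_shift,
        coef, gtemp,
        ic_node, ic_amp, ic_k0, ic_k1,
        syn_node, syn_gmax, syn_tau, syn_e, syn_t0,
        dt, config.theta,
        rec_idx, rec_out,
        full_out, config.full_every,
        float(spike_criterion), first_cross, cross_dvdt, vmax,
    )
    if err[0] >= 0:
        raise SimulationDiverged(
            (err[0] + 1) * dt, err[1], "%s@%.3f" % model.site_of(err[1])
        )

    times = np.arange(nst + 1) * dt
    fc_ms = np.where(first_cross >= 0, (first_cross + 1) * dt, np.nan)
    traces = {s: rec_out[i] for i, s in enumerate(rec_sites)}
    full_times = None
    v_full = None
    if config.store_full:
        full_times = np.arange(full_out.shape[0]) * config.full_every * dt
        v_full = full_out
    return SimResult(
        times=times,
        traces=traces,
        model=model,
        first_cross_ms=fc_ms,
        cross_dvdt=cross_dvdt,
        vmax=vmax,
        spike_criterion=spike_criterion,
        full_times=full_times,
        v_full=v_full,
    )


def input_resistance(
    model_or_neuron,
    site: tuple[str, float],
    step_nA: float = -0.005,
    mechanisms=None,
    t_stop: float = 200.0,
    dt: float = 0.025,
) -> float:
    """Steady-state input resistance dV/dI at a site, Mohm.

    Injects a small hyperpolarising step and measures the steady-state
    deflection.  Warns if the response to the opposite-sign step differs by
    more than 5 % (nonlinear regime).
    """
    model = (
        model_or_neuron
        if isinstance(model_or_neuron, CableModel)
        else build_model(model_or_neuron, mechanisms)
    )
    cfg = SimConfig(dt=dt, t_stop=t_stop, record=[site], settle_ms=50.0)

    def deflection(amp):
        res = run(
            model,
            config=cfg,
            iclamps=[IClamp(site, amp, delay_ms=0.0)],
            spike_criterion=1e30,
        )
        tr = res.trace(site)
        return tr[-1] - tr[0]

    dv = deflection(step_nA)
    dv_opp = deflection(-step_nA)
    if abs(dv + dv_opp) > 0.05 * abs(dv):
        warnings.warn(
            "input_resistance: asymmetric response to +/- steps; "
            "step amplitude may be in the nonlinear regime",
            stacklevel=2,
        )
    return float(dv / step_nA)
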