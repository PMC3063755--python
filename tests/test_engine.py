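"""Cable engine: analytic passive oracles, induced drive, conservation."""

import numpy as np
import pytest

import magcable as mc
from magcable.engine import (
    IClamp,
    SimConfig,
    SimulationDiverged,
    activating_function_profile,
    build_model,
    induced_coefficients,
    induced_segment_currents,
    input_resistance,
    run,
)
from magcable.membrane import CableConstants, MechanismSpec
from magcable.morphology import Neuron, Section

PAS = MechanismSpec("passive", g_pas=1.0 / 30000.0, e_pas=-65.0)


class TestPassiveOracles:
    def test_exponential_decay_from_end_injection(self):
        # semi-infinite cable: V(x) = V(0) exp(-x/lambda), checked over 3
        # lambda to within 1 %
        lam = CableConstants.from_mech(PAS, 10.0).lambda_um
        axon = mc.straight_axon(10.0, 7 * lam, mechanism="pax")
        model = build_model(axon, {"pax": PAS})
        cfg = SimConfig(dt=0.1, t_stop=400.0, settle_ms=1.0,
                        store_full=True, full_every=4000)
        res = run(model, config=cfg, iclamps=[IClamp(("axon", 0.0), 0.2)],
                  spike_criterion=1e30)
        v = res.v_full[-1] + 65.0
        x = (model.p0[:, 0] + model.p1[:, 0]) / 2 - model.p0[0, 0]
        sel = x < 3 * lam
        pred = v[0] * np.exp(-(x[sel] - x[0]) / lam)
        np.testing.assert_allclose(v[sel], pred, rtol=0.01)

    def test_input_resistance_isolated_soma(self):
        # isopotential sphere-equivalent soma: R_in = 1/(g_pas * area)
        soma = Neuron([Section(
            "soma", np.array([[-10.0, 0, 0], [10.0, 0, 0]]), [20.0], "pax")])
        model = build_model(soma, {"pax": PAS})
        area_cm2 = np.pi * 20.0 * 20.0 * 1e-8
        expected = 1.0 / (PAS.g_pas * area_cm2) / 1e6  # Mohm
        rin = input_resistance(model, ("soma", 0.5), step_nA=-0.001, t_stop=300.0)
        assert rin == pytest.approx(expected, rel=0.01)

    def test_input_resistance_semi_infinite_cable(self):
        # end-injection input resistance of a long cable: sqrt(r_m * r_a)
        cc = CableConstants.from_mech(PAS, 10.0)
        expected = np.sqrt(cc.r_m * cc.r_a) / 1e6  # Mohm
        axon = mc.straight_axon(10.0, 8 * cc.lambda_um, mechanism="pax")
        model = build_model(axon, {"pax": PAS})
        rin = input_resistance(model, ("axon", 0.0), step_nA=-0.01, t_stop=400.0)
        assert rin == pytest.approx(expected, rel=0.02)

    def test_dendrites_lower_somatic_input_resistance(self):
        r = [input_resistance(mc.build_model(mc.soma_n_dendrites(20.0, 1.0, n)),
                              ("soma", 0.5))
             for n in (1, 4, 8)]
        assert r[0] > r[1] > r[2]


class TestInducedDrive:
    def test_radial_segment_receives_no_current(self):
        # a segment along the radial direction is perpendicular to the
        # azimuthal field: zero drive
        coil = mc.Coil(0.02, 30, 0.01)  # axis through the origin
        spoke = Neuron([Section(
            "axon", np.array([[5000.0, 0, 0], [15000.0, 0, 0]]), [10.0], "hh")])
        c = induced_segment_currents(build_model(spoke), coil, 1e6)
        assert np.allclose(c, 0.0, atol=1e-18)

    def test_constant_tangential_field_gives_zero_interior_drive(self):
        # compartments along a circular arc concentric with the coil see a
        # constant field projection: the difference drive vanishes
        coil = mc.Coil(0.02, 30, 0.01)
        th = np.linspace(0.2, 1.2, 41)
        r_arc = 15000.0  # um
        pts = np.column_stack([r_arc * np.cos(th), r_arc * np.sin(th), 0 * th])
        arc = Neuron([Section("arc", pts, np.full(40, 10.0), "hh")])
        model = build_model(arc, d_lambda=1e9)
        c = induced_coefficients(model, coil)
        assert np.max(np.abs(c)) < 1e-9 * np.max(
            np.abs(induced_coefficients(build_model(
                mc.place(mc.straight_axon(10.0, 3e4), offset_cm=(0, -2.0))), coil)))

    def test_sign_reverses_with_didt(self, fig2_axon_model, std_coil):
        c_pos = induced_segment_currents(fig2_axon_model, std_coil, 2.5e6)
        c_neg = induced_segment_currents(fig2_axon_model, std_coil, -2.5e6)
        np.testing.assert_allclose(c_pos, -c_neg, rtol=1e-14)

    def test_subthreshold_polarity_pattern(self, fig2_axon_model, std_coil):
        # depolarisation on one side of the coil, hyperpolarisation on the
        # other (the first discharge phase depolarises the +x lobe here)
        cfg = SimConfig(t_stop=1.0)
        cfg.record = [("axon", 0.4), ("axon", 0.6)]  # symmetric about centre
        res = run(fig2_axon_model, std_coil, mc.standard_pulse(1000.0), config=cfg)
        x = (fig2_axon_model.p0[:, 0] + fig2_axon_model.p1[:, 0]) / 2
        vdev = res.vmax + 65.0
        peak_dep = x[int(np.argmax(vdev))]
        assert peak_dep > 0  # the stronger depolarising lobe is on +x
        assert np.max(vdev[x < 0]) < np.max(vdev[x > 0])
        # during the first discharge phase the -x side hyperpolarises while
        # the mirror site on +x depolarises
        first_phase = res.times < 0.09
        tr_neg = res.trace(("axon", 0.4))[first_phase]
        tr_pos = res.trace(("axon", 0.6))[first_phase]
        assert np.min(tr_neg + 65.0) < -0.05
        assert np.max(tr_pos + 65.0) > 0.05

    def test_nonplanar_neuron_rejected(self, std_coil):
        tilted = Neuron([Section(
            "axon", np.array([[0.0, 0, 0], [1000.0, 0, 50.0]]), [10.0], "hh")],
            planar=False)
        with pytest.raises(ValueError, match="planar"):
            induced_segment_currents(build_model(tilted), std_coil, 1e6)


class TestActivatingFunction:
    def test_zero_where_field_projection_constant(self):
        coil = mc.Coil(0.02, 30, 0.01)
        th = np.linspace(0.3, 0.9, 25)
        pts = np.column_stack([2e4 * np.cos(th), 2e4 * np.sin(th), 0 * th])
        arc = Neuron([Section("arc", pts, np.full(24, 10.0), "hh")])
        f = activating_function_profile(build_model(arc, d_lambda=1e9), coil)
        fig2 = activating_function_profile(
            build_model(mc.place(mc.straight_axon(10.0, 4e4), offset_cm=(0, -2.0))),
            coil)
        assert np.max(np.abs(f)) < 1e-6 * np.max(np.abs(fig2))

    def test_scales_with_lambda_squared(self, std_coil):
        f1 = activating_function_profile(
            build_model(mc.straight_axon(25.0, 4e4), d_lambda=1e9, max_seg_um=500.0),
            std_coil)
        f4 = activating_function_profile(
            build_model(mc.straight_axon(100.0, 4e4), d_lambda=1e9, max_seg_um=500.0),
            std_coil)
        # lambda^2 is proportional to diameter: 4x diameter -> 4x profile
        np.testing.assert_allclose(f4, 4 * f1, rtol=1e-9)

    def test_profile_predicts_passive_polarisation(self, std_coil):
        # low-amplitude passive fibre: the signed polarisation profile during
        # the first discharge phase correlates with the activating function,
        # r > 0.99 (the later oscillation phases flip the drive sign, so the
        # comparison is taken before the first reversal)
        axon = mc.straight_axon(100.0, 16e4, mechanism="pax")
        model = build_model(axon, {"pax": PAS})
        f = activating_function_profile(model, std_coil, {"pax": PAS})
        res = run(model, std_coil, mc.standard_pulse(100.0),
                  config=SimConfig(t_stop=0.08, store_full=True, full_every=10),
                  spike_criterion=1e30)
        vdev = res.v_full[-1] + 65.0
        r = np.corrcoef(f, vdev)[0, 1]
        assert r > 0.99

    def test_initiation_at_activating_maximum(self, fig2_axon_model, std_coil):
        f = activating_function_profile(fig2_axon_model, std_coil)
        hot = (fig2_axon_model.p0[int(np.argmax(f)), 0]
               + fig2_axon_model.p1[int(np.argmax(f)), 0]) / 2
        res = run(fig2_axon_model, std_coil, mc.standard_pulse(14000.0),
                  config=SimConfig(t_stop=5.0))
        site = mc.initiation_site(res)
        comp = res.model.comp_at(site)
        x_init = (res.model.p0[comp, 0] + res.model.p1[comp, 0]) / 2
        assert abs(x_init - hot) < 2000.0  # within 2 mm on a 16 cm axon


class TestNumerics:
    def test_subthreshold_linearity_passive(self, std_coil):
        axon = mc.straight_axon(100.0, 8e4, mechanism="pax")
        model = build_model(axon, {"pax": PAS})
        cfg = SimConfig(t_stop=1.0)
        r1 = run(model, std_coil, mc.standard_pulse(50.0), config=cfg,
                 spike_criterion=1e30)
        r2 = run(model, std_coil, mc.standard_pulse(100.0), config=cfg,
                 spike_criterion=1e30)
        np.testing.assert_allclose(
            r2.vmax + 65.0, 2 * (r1.vmax + 65.0), rtol=1e-6, atol=1e-9
        )

    def test_temporal_convergence(self, small_soma_cell):
        coil = mc.standard_coil()
        model = build_model(small_soma_cell)
        peaks = []
        for dt in (0.002, 0.001, 0.0005):
            res = run(model, coil, mc.standard_pulse(3e4),
                      config=SimConfig(dt=dt, t_stop=3.0), spike_criterion=1e30)
            peaks.append(np.max(res.vmax))
        assert abs(peaks[-1] - peaks[-2]) < 0.1

    def test_spatial_convergence_of_threshold(self):
        cell = mc.soma_n_dendrites(20.0, 1.0, 3)
        coil = mc.standard_coil(x_shift_m=-mc.gradient_max_x())
        thr = []
        for dl in (0.05, 0.025):
            t = mc.find_magnetic_threshold(
                build_model(cell, d_lambda=dl), coil, mc.standard_pulse(1.0),
                config=SimConfig(t_stop=5.0), resolution=100.0,
                bounds=(3e4, 3e5))
            thr.append(t.threshold)
        assert abs(thr[1] - thr[0]) / thr[0] < 0.01

    def test_charge_balance_per_step(self):
        # backward-Euler residual of the assembled system, recomputed from
        # stored states on a passive cell, balances to solver tolerance
        cell = mc.soma_n_dendrites(20.0, 1.0, 3)
        pas_all = {"soma": PAS, "dend": PAS}
        model = build_model(cell, pas_all)
        dt = 0.01
        cfg = SimConfig(dt=dt, t_stop=0.1, settle_ms=0.0,
                        store_full=True, full_every=1)
        clamp = IClamp(("soma", 0.5), 0.05)
        res = run(model, config=cfg, iclamps=[clamp], spike_criterion=1e30)
        v = res.v_full
        n = model.n_comp
        inj = np.zeros(n)
        inj[model.comp_at(("soma", 0.5))] = 0.05
        for k in (1, 5, 9):
            resid = model.cm_nF / dt * (v[k] - v[k - 1]) \
                + model.gpas_uS * (v[k] - model.epas) - inj
            for i in range(n):
                j = model.parent[i]
                if j >= 0:
                    iax = model.g_axial[i] * (v[k][i] - v[k][j])
                    resid[i] += iax
                    resid[j] -= iax
            assert np.max(np.abs(resid)) < 1e-9

    def test_crank_nicolson_agrees_with_backward_euler(self, small_soma_cell):
        model = build_model(small_soma_cell)
        coil = mc.standard_coil()
        out = []
        for theta in (1.0, 0.5):
            res = run(model, coil, mc.standard_pulse(2e4),
                      config=SimConfig(dt=0.001, t_stop=2.0, theta=theta),
                      spike_criterion=1e30)
            out.append(np.max(res.vmax))
        assert out[0] == pytest.approx(out[1], abs=0.05)

    def test_divergence_reported_with_location(self):
        # a non-finite source must be caught and reported with the first
        # offending time and compartment, not propagated silently
        cell = mc.soma_n_dendrites(20.0, 1.0, 1)
        with pytest.raises(SimulationDiverged, match="soma"):
            run(build_model(cell), config=SimConfig(dt=0.01, t_stop=1.0),
                iclamps=[IClamp(("soma", 0.5), float("inf"))])


def test_simresult_export(tmp_path, small_soma_cell):
    cfg = SimConfig(dt=0.01, t_stop=1.0, record=[("soma", 0.5)])
    res = run(small_soma_cell, config=cfg)
    out = tmp_path / "trace.tsv"
    res.save_tsv(out, metadata={"note": "unit test"})
    text = out.read_text()
    assert text.startswith("# note = unit test")
    assert "soma@0.5" in text.splitlines()[1]
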