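# magcable

Magnetic stimulation of compartmental neuron models: the electric field
induced by a current-pulsed circular coil, injected as per-segment currents
into a branched cable model with Hodgkin–Huxley excitability, plus the
threshold and sweep protocols built on top (magnetic threshold vs. fibre
diameter, coil position, morphology, pulse duration, and neuronal state).

It is written for computational neuroscientists who want to ask *which part
of a neuron does a TMS-style coil excite, and at what stimulator setting* —
without a head model: a planar neuron under a parallel coil, the standard
reduction used to study the biophysics of magnetic excitation.

## Model in brief

A coil of radius *r* with *N* turns at standoff *z* above the neuron plane,
discharged through a series RLC circuit from capacitor voltage *V₀*, induces

    E(x, y, t) = S(x, y) · dI/dt,    S = −N · A_φ(ρ, z) · φ̂,

with `A_φ` the loop vector potential in complete elliptic integrals
(`m = k²` parameter convention, pinned by a Biot–Savart line-integral
oracle).  The field component along each neurite drives the cable as a
zero-reversal current source in difference form,

    I_j = [E_a(start) − E_a(end)] / r_a        (positive depolarises),

the discrete counterpart of the activating function `−λ² ∂E_a/∂a`.  The
branched cable with classic 6.3 °C Hodgkin–Huxley membrane (passive
dendrites, idealised myelin, nodes of Ranvier) is integrated implicitly
(backward Euler / Crank–Nicolson, Hines elimination, 1 µs steps).  The
*magnetic threshold* is the minimal V₀ that elicits an action potential,
found by verified bisection.

See `docs/methods.md` for assumptions, numerics, and a calibration analysis
of the historical reference values (absolute thresholds here are in
kilovolts; locations and monotonicities are scale-free).

## Worked example

```python
import magcable as mc

# 100 um x 16 cm straight HH axon under the reference coil (r = 2 cm,
# 30 turns, 1 cm standoff, shifted one radius) and the underdamped pulse
axon  = mc.build_model(mc.straight_axon(100.0, 16e4))
coil  = mc.standard_coil()
pulse = mc.standard_pulse(1.0)                     # V0 set by the search

thr = mc.find_magnetic_threshold(axon, coil, pulse,
                                 config=mc.SimConfig(t_stop=5.0))
print(f"magnetic threshold: {thr.threshold:.2f} V")

res  = mc.run(axon, coil, pulse.with_voltage(thr.threshold + 1),
              config=mc.SimConfig(t_stop=25.0,
                                  record=[("axon", 0.0), ("axon", 1.0)]))
site = mc.initiation_site(res)
comp = res.model.comp_at(site)
x0   = (res.model.p0[comp, 0] + res.model.p1[comp, 0]) / 2
print(f"initiation at x = {x0/1e4:.2f} cm from the coil's vertical midline")
print("spikes at -x end:", mc.detect_spikes(res.times, res.trace(("axon", 0.0))))
print("spikes at +x end:", mc.detect_spikes(res.times, res.trace(("axon", 1.0))))
```

prints

```
magnetic threshold: 13654.38 V
initiation at x = 1.73 cm from the coil's vertical midline
spikes at -x end: [21.678]
spikes at +x end: [15.544]
```

The action potential starts where the field *gradient* along the axon is
maximal (x ≈ 1.66 cm, `mc.gradient_max_x()`), not at the field-magnitude
maximum (ρ = 1.98 cm, `mc.locate_radial_maximum(coil)`), and two APs travel
to the two ends — the nearer (+x) end fires first.  The threshold voltage is
on the kilovolt scale of real stimulators; `docs/methods.md` explains how
this relates, by a single constant factor, to the 36 V historical reference.

Sweeps are one call each and return tidy tables:

```python
df = mc.run_experiment("fig5_dendrites", dict(n_dendrites=(1, 3, 5)))
#    n_dendrites  magnetic_threshold_V  current_threshold_nA  input_resistance_MOhm
# 0            1              90530.25              0.053125                  67.03
# 1            3             123192.25              0.115610                  61.98
# 2            5             148936.25              0.184293                  57.65
```

— each added passive dendrite is a current sink: thresholds rise, input
resistance falls, and the magnetic threshold tracks the current threshold.

## Command line

```sh
magcable validate-config run.yaml      # schema + unit check (exit 2 on error)
magcable threshold run.yaml            # magnetic threshold for the config
magcable simulate run.yaml -o out.tsv  # one run, traces as TSV + manifest
magcable experiment fig3b_shift        # named sweep -> table
magcable field-export run.yaml --extent 4mm --resolution 10um -o grid
```

Configs use explicit unit suffixes (`radius: 2cm`, `L: 13uH`, `C: 200uF`);
every command writes a JSON manifest with the fully resolved configuration,
and the core is deterministic — reruns are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the straight-axon magnetic threshold (bisection on
the full simulation), the radial location of the induced-field maximum
(0.01 cm scan), the Rall 3/2-law daughter diameter, and the soma-shift at
which action-potential initiation switches from the axon to the soma for the
myelinated-axon cell (coarse-then-fine sweep at 0.01 cm), and writes them as
JSON.  Runtime is a few minutes on one CPU.
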