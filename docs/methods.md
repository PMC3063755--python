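# Methods

`magcable` simulates magnetic stimulation (MS) of neurons: a circular coil
driven by a capacitor discharge induces an electric field in the plane of a
neuron, and the component of that field along each neurite drives
transmembrane current in a branched compartmental cable model with
Hodgkin–Huxley (HH) excitability.  This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do
and do not establish.

## Physical model

**Induced field.**  The coil (radius *r*, *N* turns, current *I(t)*) lies in
the plane `z = standoff`, parallel to the neuron plane `z = 0`.  With
negligible charge accumulation the induced field is `E = −∂A/∂t`, where the
azimuthal vector potential of one loop has the classical closed form in
complete elliptic integrals,

    A_φ(ρ, z) = (µ0 / 4π) · (4r / √((r+ρ)² + z²)) · [((2−m)K(m) − 2E(m)) / m],
    m = k² = 4 r ρ / ((r+ρ)² + z²).

`K(m)`/`E(m)` follow the *parameter* convention of `scipy.special.ellipk`
(`m = k²`); the convention is pinned by an independent Biot–Savart
line-integral oracle (the classic silent failure mode here is passing the
modulus where the parameter is expected).  Because the coil is parallel to
the neuron plane, `E` separates into a spatial vector factor and a scalar
temporal factor:

    E(x, y, t) = S(x, y) · dI/dt,       S = −N · A_φ(ρ, standoff) · φ̂,

with `φ̂` the azimuthal unit vector about the coil axis.  `S` is evaluated
analytically at compartment endpoints on demand; sampled grids exist only as
an export/interchange format (they reproduce the analytic values exactly at
cell centres).  Arbitrary coil shapes go through the same line-integral
quadrature that serves as the oracle.

**Stimulator.**  A series RLC discharge from capacitor voltage `V0`:
underdamped (oscillatory) when `R < 2√(L/C)`, overdamped otherwise, with the
boundary counted as overdamped and evaluated by its exact critical limit.
`I(0) = 0`, `dI/dt(0) = V0/L`; both `I` and `dI/dt` are closed-form and are
verified against adaptive ODE integration to 1e−6 relative.  The reference
pulse (0.09 Ω, 13 µH, 200 µF) is underdamped with a full period of 0.33 ms;
the conventional "0.4 ms" label for this pulse is treated as a display label
only — all computations key on (V0, R, L, C).

**Coupling to the cable.**  The field acting on the cytoplasmic (axial)
resistance adds a membrane drive `−(1/r_a) ∂E_a/∂a` per unit length, where
`E_a = E·â` is the field projection on the local fibre direction and `r_a`
the axial resistance per unit length.  Per compartment this is applied in
difference form as a current source with zero reversal potential,

    I_j = [E_a(p_start) − E_a(p_end)] / r_a        (positive = depolarising).

The sign follows from the cable derivation (depolarisation where the field
projection *decreases* along the fibre) and is pinned by the straight-axon
polarity test: under the one-radius-shifted coil, the first discharge phase
depolarises one half of the axon and hyperpolarises the other.

This difference scheme produces exactly zero drive for a spatially uniform
field along a straight uniform fibre — in particular, **no terminal "end
effect"**: a fibre end in a uniform field receives no boundary source.  This
is a known limitation of the scheme (a continuum treatment gives an end
polarisation ∝ E·λ); it is retained deliberately because it is the scheme
the coupled-current formulation defines, and it matters for the
initiation-site results below.

The diagnostic *activating function* is reported per compartment as
`−λ² ∂E_a/∂a` (positive = depolarising), with `λ = √(r_m/r_a)` the passive
space constant.

## Membrane and cable

Classic squid HH at 6.3 °C with the standard constants (gNa = 0.120,
gK = 0.036, gL = 0.0003 S/cm²; ENa = 50, EK = −77, EL = −54.3 mV;
cm = 1 µF/cm²; axial resistivity 35.4 Ω·cm; rest −65 mV).  Passive dendrites
default to g_pas = 1/30000 S/cm², e_pas = −65 mV (unstated in the source
experiments; configurable).  Myelin is idealised as zero conductance with
cm = 0.04 µF/cm²; nodes of Ranvier carry full HH.  An optional `na_shift`
moves Na activation *and* inactivation toward hyperpolarised potentials;
small shifts (≤ ~3 mV) lower the somatic current threshold monotonically,
larger shifts make the classic HH cell spontaneously active, at which point
a threshold is no longer defined.

Somata specified by diameter are cylinders with length = diameter (same
area as the sphere).  Spatial discretisation follows the d_lambda rule:
compartment length ≤ 0.1 × the 100 Hz AC length constant (convergence is
tested: halving the compartment size changes a magnetic threshold by < 1%,
halving dt changes peak depolarisation by < 0.1 mV).  Time stepping is the
theta method (backward Euler by default, Crank–Nicolson via θ = 0.5) with
staggered exponential-Euler gate updates; the branched system is solved
exactly per step by Hines elimination on the tree.  Every run starts from
steady state (gates at their fixed points, a settle interval before
stimulus onset); the temporal factor `dI/dt` is evaluated analytically at
step midpoints.  Internal units are the compartmental-modelling convention
(µm, ms, mV, nA, µS, nF); the field side is SI with one conversion layer.

## Protocols

The *magnetic threshold* is the minimal `V0` for which any compartment
crosses 0 mV upward; the *current threshold* is the analogous somatic
square-pulse amplitude.  Both use bisection on a verified bracket with
automatic bracket expansion; equality with a brute-force incremental scan is
asserted in the tests.  Initiation sites are earliest-crossing compartments,
ties broken by dV/dt.  Unexcitable-at-cap points are reported as censored
values, not exceptions, so sweeps continue.

The sweep drivers reproduce: threshold vs. fibre diameter and vs. coil
shift for a 16 cm straight axon; bend / bifurcation / diameter-step
dendrite cells; threshold and input resistance vs. dendrite count;
strength–duration via the capacitance; the soma-shift initiation-site
transition of a soma + myelinated-axon cell; and state dependence (EPSP or
a preceding action potential).  Small artificial cells are placed with
their axis along x at the activating-function hot spot of the standard
shifted configuration (the along-axis field-gradient maximum, x ≈ 1.66 cm);
at the nominal "matrix centre" placement the along-axis gradient can vanish
by symmetry, and the original cell orientation is unstated.  For the bend
sweep the coil is mirrored so the post-bend limb tilts *into* the field
(depolarising kink drive); in the opposite orientation a bend *raises* the
threshold.  For the soma + axon cell the axon trails the soma (extends away
from the hot spot): only then does the threshold fall with the shift toward
a minimum at the gradient maximum, as a leading axon always covers the hot
spot.

## Field-scale calibration (why absolute thresholds are in kilovolts)

The implementation is strict SI electromagnetism, pinned by the
line-integral oracle.  Under the reference configuration the resulting
absolute scale disagrees with the historical reference values by a single
constant factor:

* The straight-axon magnetic threshold computes to 13 654 V (stable to
  < 0.1% under dt, dx and t_stop refinement).  The historical reference is
  36 V.  The ratio, 379.3, equals 4π·N (= 376.99 for N = 30) to within
  0.6% — i.e. our simulation reproduces the reference value *exactly* up to
  a constant field-scale factor of 4π·N, the signature of a Biot–Savart
  prefactor (µ0 vs µ0/4π) and a doubled turns factor in the original field
  export.  Physically, 36 V across 13 µH yields ~100 A peak (~0.1 T), far
  below the tesla-scale fields of real stimulators; kilovolt thresholds are
  the physically consistent ones.  No correction factor is applied — the
  package reports what the stated physics gives.
* The induced-field magnitude on the plane 1 cm under a 2 cm coil peaks at
  ρ = 1.98 cm, not the often-quoted 1.6 cm.  The 1.98 cm value is
  corroborated by the field-matrix placement used in the original CNS
  simulations (centred 1.98 cm from the coil axis).  The 1.6 cm figure
  instead matches the *gradient* maximum along the one-radius-shifted axon
  (1.66 cm here), i.e. the activating hot spot, exposed as
  `protocols.gradient_max_x`.

All location-, monotonicity- and correlation-based results are invariant to
the field scale; only quantities printed in volts (or joules) carry it.

## What the synthetic experiments establish — and what they do not

Green tests establish: the closed-form field against an independent
quadrature; the RLC discharge against ODE integration and energy
conservation; the passive cable against analytic decay and input-resistance
formulas; tree integrity, convergence, determinism; and the qualitative
physiology — polarity pattern, initiation at the activating-function
maximum, two counter-propagating APs, thresholds monotone in dendrite count
and correlated with current threshold (r > 0.99 here), threshold minimum at
a one-radius coil shift, state dependence (EPSP lowers, refractoriness
raises the threshold).

Deliberately red (asserted as specified, failing honestly):

* absolute 36 V threshold and the 1.6 cm field maximum (field-scale and
  location analysis above);
* the initiation-site transition at a 0.05 cm soma shift: the pure
  activating-function crossover λ²_soma·f(Δx) = λ²_node·f_max lands at
  0.050 cm exactly, but the full cable simulation of the stated scheme
  switches at 0.62 cm (for a 2 cm axon; the location depends on the
  unstated axon length), because a compact soma's polarisation is not the
  infinite-cable activating function;
* the inverse-square threshold-vs-diameter law: the converged exponent is
  ≈ −1 for the unmyelinated axon (polarisation ∝ λ² ∝ d) and −1.45 to −1.6
  for the soma cell (between the compact-source 1/d² limit and large-soma
  saturation).  The inverse-square law is a myelinated-fibre result, where
  internode length ∝ d contributes the second power;
* bend-angle flatness below 60° (the kink drive grows as 1 − cos θ, so half
  the 90° effect already exists at 60°; the drop itself, and its
  monotonicity, are green);
* monotone-increasing device energy over C ∈ [50, 700] µF (in the
  charge-dominated regime V_th falls faster than 1/√C, making
  E = ½·C·V_th² non-monotone; scale-invariant, so not attributable to the
  calibration issue).

The generic cells used here do not emulate layer-5 pyramidal neurons
(multi-channel dendrites, Ca²⁺ spikes, axon initial segments); results that
depend on those models are out of scope and are covered only by the
qualitative analogues above.

## Defaults that matter

| parameter | default | note |
|---|---|---|
| coil | r = 2 cm, N = 30, standoff 1 cm, µ0 | reference configuration |
| pulse | R = 0.09 Ω, L = 13 µH, C = 200 µF | underdamped, period 0.33 ms |
| dt | 1 µs | backward Euler; θ configurable |
| d_lambda | 0.1 | compartment ≤ 0.1 λ(100 Hz) |
| settle | 5 ms | steady-state initialisation |
| spike criterion | 0 mV upward crossing, ≥ 1 ms apart | configurable |
| bisection resolution | 0.25 V (magnetic), 0.01 nA (current) | bracket verified |
| dendrite length | 600 µm | unstated in the source experiments |
| passive dendrites | g_pas = 1/30000 S/cm², e_pas = −65 mV | unstated; configurable |
| myelinated axon | 198 internodes (≈ 2 cm) | unstated; sensitivity reported |
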