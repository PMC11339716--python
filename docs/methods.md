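# Methods

## Model and assumptions

The package simulates pure-tone, steady-state vibration of the human
cochlea as a linear frequency-domain transmission line — the classical
"box model" — rather than a 3D time-domain fluid–structure simulation.
The choice is deliberate: the stimuli of interest are acoustic-amplitude
pure tones (linear regime), the quantities of interest are steady-state
transfer ratios, and the one-dimensional long-wave formulation is the
standard desk-scale description of cochlear macro-mechanics. What is lost
relative to a 3D model is discussed under Limitations.

Two incompressible fluid ducts (scala vestibuli, scala tympani; the scala
media is merged into the scala vestibuli, which barely affects BM motion)
run from base to apex along x ∈ [0, L], L = 35 mm, and exchange volume
through the basilar-membrane partition and, at the apex, the helicotrema.
Walls are rigid (the cochlea sits in temporal bone), so the oval and round
windows at the base are the only ports. Discretely, the model is a ladder
network solved by nodal analysis on the 2n segment-center pressures:

- series duct impedance per segment: iωρ·dx/A plus a Poiseuille viscous
  loss 8πμ·dx/A² (a small correction; full 3D viscous boundary layers are
  out of scope);
- shunt partition impedance per segment: z_p(x, f)/(w(x)·dx), with
  z_p = iωm + [αm + βk + c] + k/(iω) locally reacting;
- an apical helicotrema shunt, modeled as a fluid plug of area 0.3 mm²
  and effective length 1 mm;
- lumped window impedances z_ow (stapes footplate in the stapedial
  annular ligament) and z_rw (round-window membrane) at the base.

### Partition mass, stiffness, damping

m(x) is the structural BM mass (density 1000 kg/m³ times thickness) plus
a near-field fluid co-mass of ρ·w(x) — the local 3D flow around a strip
of width w loads it with a mass of order ρw per unit area; the long-wave
duct inertia is carried separately by the series elements, so only this
local term is added. k(x) = C·E_X·t(x)³/w(x)⁴ is clamped-beam bending
across the width: the BM's collagen fibres run widthwise, so the large
transverse modulus E_X (2×10⁶ Pa) governs bending, while the
two-orders-smaller longitudinal modulus E_Y justifies the locally
reacting (no longitudinal coupling) approximation. The single constant C
is calibrated once, by a secant iteration on the solved normal-forward
model, so the 1-kHz traveling-wave peak sits at the Greenwood place
(x̂ = 0.600); the local-resonance estimate seeds the iteration but the
calibration targets the actual damped peak, which sits basal of
resonance. Damping combines Rayleigh terms (α = 100 s⁻¹ on mass,
β = 6.43×10⁻⁷ s on stiffness) with the BM surface damping pressure
P = −c·V, c = 5000; c is interpreted as Pa per m/s (pressure per
velocity), the only reading dimensionally consistent with its use as a
surface pressure law, and it dominates the partition resistance.

### Window impedances

Round window: a clamped circular plate of equivalent radius
a = √(2.3 mm²/π), thickness 70 μm (literature value), E = 5×10⁶ Pa,
ν = 0.49. Acoustic stiffness 192D/(πa⁶) follows from the uniform-load
deflection shape w₀(1 − (r/a)²)²; acoustic mass combines the
shape-weighted membrane mass, the one-sided baffled-piston radiation
co-mass, and any attached mass. The resulting window resonance falls near
1.4 kHz, in the physiological range.

Oval window: the footplate (4.2 mm²) is a rigid piston suspended in a
shear-loaded annular ligament of width 0.1 mm and depth 0.2 mm;
mechanical stiffness G·perimeter·depth/width with G = E/(2(1+ν)). The SAL
baseline modulus is not an independently published constant for this
model family; the default 1×10⁵ Pa (with ν = 0.3) is a literature-range
value carrying a documented multiplicative calibration scalar, left at
1.0 because the resulting middle-ear transfer function already lies
inside the plausibility band below. The moving mass is the stapes
(3.3 mg) plus the piston radiation co-mass, giving an oval-window
resonance near 1.4 kHz.

Pathology staging multiplies the relevant window's Young's modulus by 100
or sets it to bone (200 GPa, ossification); ν and masses are unchanged,
and the BM partition never changes across scenarios. "Stiffness ×100" is
implemented as modulus ×100 — for a plate the two are proportional at
fixed geometry (equivalently a 100^(1/3) ≈ 4.6-fold thickening).

### Orthotropic bookkeeping

Shear moduli follow G_ij = E_i·E_j/(E_i + E_j + 2E_j·ν_ij); the
complementary Poisson ratios follow the compliance symmetry
ν_ij/E_i = ν_ji/E_j. A variant of the third symmetry relation with the
moduli swapped circulates in the cochlear-modelling literature; it is
exposed behind a `printed_variant` flag but the standard form is the
default, because only it satisfies the symmetry of the compliance tensor.
The BM's primary Poisson ratios are not published for this parameter set;
the default 0.3 is a mid-range structural value, and the derived shear
moduli are only weakly sensitive to it when E_Y ≪ E_X. With the default
moduli the derived ν_zy exceeds the isotropic admissibility bound — a
consequence of the strong anisotropy — and construction warns rather than
fails; the reduced-order solver consumes only E_X.

### Stimulus calibration

Both pathways are referenced to 60 dB SPL at the ear canal with a fixed
middle-ear pressure gain set to 26 dB (surface ratio
20·log₁₀(80/5.1) ≈ 24 dB plus a 2.5 dB ossicular lever; the computed
total, 26.4 dB, is deliberately replaced by the set constant). Forward
stimulation applies 86 dB SPL over the 5.1 mm² oval-window membrane;
reverse applies the exact equal-force level, 92.92 dB SPL, over the
2.3 mm² round window (93 dB when rounded for reporting; rounding happens
only at reporting time). The delivered force is ~2.05 μN at either
window, and is scenario-independent: the transducer drive is fixed,
pathologies change only what the cochlea does with it. The forward
stimulus is placed on the oval-window membrane rather than the stapes
head because only the 5.1/2.3 mm² area pair is consistent with the
86 → 93 dB equal-force calibration; the stapes-head area (0.58 mm²) is
retained as a geometry constant.

## Solution method

With rigid walls the interior network has exactly two ports, so the exact
solution is a single loop flow u from oval window to round window: the
interior network is solved once per frequency for a unit volume-velocity
injection (sparse LU; all entries uniformly scaled), and
u = Δp_source/(z_ow + z_rw + Z_net) with Z_net the interior two-terminal
impedance. This makes window volume-velocity conservation structural —
exactly what incompressibility demands — and keeps the tiny window flows
of ossified (near-rigid) stages numerically meaningful, where a direct
pressure-source solve loses them to cancellation. The reconstructed field
is checked against the fully assembled pressure-source system; relative
residuals are below 3×10⁻¹¹ across the entire run matrix. Grid
convergence: the peak BM displacement changes by <0.2% when n doubles
from the default 500 segments (chosen for converged solutions at
milliseconds per frequency).

Two consequences of the two-port structure are worth stating because they
shape the results. First, the forward volume-displacement ratio
|U_RW|/|U_OW| is exactly 1 — the model realizes the incompressibility
argument for that measurement identically. Second, by network
reciprocity, equal source *pressures* at either window produce identical
BM magnitude profiles, so under equal *force* the reverse pathway exceeds
the forward one by exactly the area ratio, 20·log₁₀(5.1/2.3) = 6.92 dB,
at every frequency and in every scenario — including round-window
ossification. The study conditions this package emulates found the
reverse advantage reversed under RWM ossification; capturing that
requires source-coupling physics beyond an ideal pressure source on the
membrane (the transducer's ability to move an ossified membrane), which
is out of scope, and the rwm_ossified cell is therefore treated as the
permitted exception in the ordering checks.

## Metrics and conventions

x runs base → apex; window volume velocities are positive into the
cochlea; BM displacement is positive toward scala tympani; phase is in
cycles re the basal BM segment, unwrapped base → apex, negative = lag.
The CF place is the arg-max of |d(x)| with parabolic sub-grid refinement
(ties toward the base; monotone profiles return the endpoint with a
warning). The vestibule pressure probe sits 200 μm from the oval window
(linear interpolation between segment centers); U_stapes is the footplate
piston volume velocity, and in reverse runs the outward sign is used so
Z_ME_R has a passive real part. "Maximum BM displacement" is max over x
of |d| in dB re 1 m; only differences of this quantity are ever reported,
so the reference cancels. Relative amplitudes (the hearing-threshold
proxy) are evaluated at the CF places of the *normal forward* runs for
both pathways' curves, with 0 dB defined as normal forward hearing. In
the ordering checks, decrement comparisons use the amplitude loss
max(0, −Δ): a decrement is by definition a reduction, and the x100 stages
can show sub-dB amplitude *increases* at 4 kHz (window-reactance
cancellation in a lumped model) that would otherwise flip a 0.1-dB
comparison between two non-decrements.

Plausibility bands (logged constants, not fitted): METF within
(−70, −10) dB ref μm/Pa — the normal model runs −17 dB (125 Hz) to
−67 dB (4 kHz), at or below the lower range of published measurements and
with a steeper high-frequency roll-off, the known cost of piston-only
stapes motion and a 1D fluid description; |Z_C| and |Z_ME_R| within
(10⁶, 10¹²) Pa·s/m³ — the model spans 1.3×10⁹–4.3×10¹¹. The Greenwood
constants (A = 165.4 Hz, a = 2.1, k = 0.88) are the standard human
values, config-overridable. After the single 1-kHz calibration, the
model's CF map tracks the Greenwood curve within a factor of 1.4 in
frequency at all six study frequencies and is identical between pathways.

## Synthetic inputs and the perturbation ensemble

No external data exists for this model: the fixtures module *is* the data
source. It generates the geometry (the five window/membrane areas are
fixed constants of the emulated study; BM length/taper, duct areas and
helicotrema are standard human box-model values, all config-overridable
and recorded in an emitted resolved-config file), the five pathology
scenarios, and optional parameter-perturbation ensembles (independent
unit-median lognormal factors of chosen relative spread, seeded). Passing
tests on these inputs demonstrates internal consistency and the model's
qualitative orderings, not agreement with any individual ear: real
cochleae are coiled, have tapered ducts and a compliant cochlear
aqueduct, and their METF varies by tens of dB across subjects.

## Known limitations

- No cochlear amplifier: the model is passive and linear; levels are
  interchangeable and only relative amplitudes are meaningful.
- Piston-only stapes motion: rocking modes above ~2 kHz, and the angled
  velocity components that laser measurements pick up, are not modeled;
  high-frequency METF and impedance comparisons inherit this.
- Ideal pressure sources at the windows: transducer–membrane coupling is
  not modeled, so the rwm_ossified reverse cell keeps the reciprocal
  6.9 dB advantage instead of reversing (see above).
- The BM phase lag at the CF place grows from 0.54 cycles at 125 Hz to
  0.90 cycles at 4 kHz (mean 0.7): the 1D transmission line accumulates
  more traveling-wave phase at mid/high frequencies than 3D models of
  this family, which report roughly half a cycle at CF across
  frequencies.
- The two-duct areas are equal and uniform by default; the split between
  scala vestibuli and scala tympani after merging the scala media is not
  constrained by the emulated study and is flagged in the config.
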