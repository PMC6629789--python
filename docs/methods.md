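# Methods

## Model overview

The package simulates pulsatile blood flow in the large epicardial
coronary arteries as a network of one-dimensional compliant tapering
tubes, coupled to (i) structured-tree impedance models of the
intramyocardial vascular beds, (ii) a time-varying-elastance model of
both ventricles that supplies the myocardial feedback pressure, and
(iii) a minimal lumped model of the aortic root that drives the inlets.
All internal arithmetic is CGS (g, cm, s); pressures cross the API in
mmHg (1 mmHg = 1333.22 dyn cm⁻²).

### Large-artery network

The network is read from a comma-delimited table (name, length,
proximal/distal radius in mm, parent). The packaged default is a
17-segment tree measured from CT angiography: the left main artery
branching into LAD, LCX and DIAG, with LAD/LCX chains and marginal
branches, and the right coronary artery branching into PDA and PLA.
The single trifurcation at the LMCA is replaced by two adjacent
bifurcations via a short untapered intermediate segment (radius
0.185 cm, length 0.25 cm). The intermediate radius is the reported
anatomical value rather than a radius-exponent recomputation, because
the exponent relation applied to the measured daughter radii does not
reproduce it; both numbers are configurable.

### Governing equations and scheme

Continuity and momentum (boundary-layer friction with oscillatory layer
thickness δ = √(ν t_c / 2π)), closed by the tube law
p − p0 = (4Eh/3r0)(1 − √(A0/A)) with the empirical stiffness
Eh/r0 = k1 e^{k2 r0} + k3. A literal-linear variant of the tube law is
available behind a flag for sensitivity studies; it is implemented in
the monotone form p − p0 = f(1 − A0/A), since a (1 − A/A0) reading has
negative dp/dA and is not hyperbolic. The reference pressure p0 of each
tree is the time average of the corresponding ventricular pressure,
recomputed each run.

The interior is advanced with the two-step (Richtmyer) Lax–Wendroff
scheme in conservation form, with taper and stiffness-gradient source
terms; the scheme conserves interior volume exactly with respect to its
half-step interface fluxes, which is also how the per-vessel mass
budget is measured. Boundaries are closed with the outgoing Riemann
invariant of each vessel (W± = u ± κ(c0 − c(A)), κ = 4 for the adopted
law), interpolated at the foot of the characteristic:

* **Inlets** — prescribed inflow (default) or prescribed pressure.
* **Bifurcations** — common static pressure and flow conservation,
  solved by a damped Newton iteration on the junction pressure (the
  parametrization by the common pressure makes the residual monotone,
  so the iteration is unconditionally stable); residuals are driven
  below 10⁻¹¹ of the local flow scale.
* **Terminal outlets** — p(L,t) = Σ_τ z(τ) q(L, t−τ) Δτ + p_f(t),
  solved together with the outgoing characteristic; the convolution
  uses the previous period's outflow history (zero-padded and flagged
  on the first cycle).

Time step: the CFL-limited step is rounded down to an integer number of
sub-steps per impedance-kernel sample, so the convolution indexes the
history exactly. A compiled (numba) implementation of the cycle loop is
the production path; a vectorized numpy implementation of identical
semantics is retained as the reference and cross-checked by a test.

### Structured-tree vascular beds

Each terminal artery is loaded with the root impedance of a
self-similar binary tree: daughter radii α·r and β·r (α = 0.9,
β = 0.6), vessel length l_rr·r (l_rr = 25), terminating when a daughter
would fall below r_m = 10 μm. A daughter below r_m is not created, and
a vessel none of whose daughters exist carries the terminal load
(default 0, a pressure reservoir at the bed outlet); treating missing
daughters as zero-impedance parallel branches would short-circuit the
bed and is physically wrong. Within the bed, linearized pulsatile flow
gives a lossless transmission line per vessel with the Womersley
viscous factor K = 1 − F_J(w0), F_J = 2J₁(i^{3/2}w0)/(i^{3/2}w0 J₀(i^{3/2}w0)),
w0 = r0√(ωρ/μ), compliance C = 3A0r0/2Eh, wave speed c = √(A0K/ρC) and
characteristic admittance g = √(CA0K/ρ). Sibling impedances combine in
parallel; the line transform is evaluated with the e^{+iωt} convention
(matching numpy's inverse FFT), under which the matched-load,
zero-length and half-wavelength identities all hold. ω = 0 is the
Poiseuille limit 8μl/πr⁴, accumulated through the same recursion.
Self-similarity lets the recursion run over the (i, j) =
(α-steps, β-steps) radius lattice with memoization; a brute-force
vessel-by-vessel enumeration is kept as a test oracle. The number of
retained harmonics equals the solver's samples per period; the
time-domain kernel is the inverse DFT scaled so mean(z)·T = Z(0).

For the rarefaction scenario the radius exponent ξ is reduced
(2.76 → 2.4). Since the impedance depends on ξ only through the
branching ratios, α and β are recomputed from
α = (1 + γ^{ξ/2})^{−1/ξ}, β = α√γ with the asymmetry ratio γ = 0.41
held fixed (at ξ = 2.76 this gives α = 0.911, β = 0.583, consistent
with the tabulated 0.9/0.6, which the baseline uses as printed).

### Heart model and feedback pressure

Ventricular pressure follows the elastance law with activation
σ(t) = 1 − cos(2πt/t_s) in systole (peak 2, as tabulated; a ½-factor
switch is provided), t_s = 0.4 s, t_c = 0.9 s. The ventricular volume
V(t) is not part of the published parameter set; it is a smooth
prescribed stroke profile (C¹ cosine ejection ramp over 0.02–0.22 s,
hold, C¹ refill over 0.45–0.88 s) with V_ed = 85 ml and SV = 65 ml,
chosen once so that the left peak pressure is ≈120 mmHg and the cardiac
output 4.3 L/min; both ventricles share the volume waveform. The
refill is smooth rather than strictly constant-rate so that dV/dt is
continuous at the phase joints.

Each terminal bed receives p_f = φ p_v + p_s (p_s = 20 mmHg) added to
its outflow boundary, with φ by supply location: left ventricle 33%
(PDA, LAD3, LAD4, DIAG, MARG1–3), right ventricle 25% (PLA), septum 22%
(LAD1, LCX3). Septal and left-ventricular beds use the left ventricular
pressure; the PLA bed uses the right.

### Inlet drive and calibration

The aortic-root pressure comes from the ejection flow max(0, −dV/dt)
passing a diode valve into a 3-element windkessel (R_char 0.06,
R_per 1.05 mmHg·s/ml, C 1.4 ml/mmHg, solved periodically in the
frequency domain; ≈119/64 mmHg). In the default **flow** mode each
root's inflow is estimated from the lumped relation
q_r(t) = (p_a(t) − p_bed,r(t))/R_r, where R_r and the time-varying
source pressure p_bed,r(t) come from a Thevenin reduction of the root's
DC resistance network with the per-bed feedback pressures as sources;
the waveforms are then scaled so total mean coronary inflow is 4.5% of
cardiac output. A **pressure** mode (aortic pressure times a scale
factor calibrated to the same fraction by warm-started secant
iteration) is retained as an alternative. Flow mode is the default
because with the tabulated bed parameters the pressure mode collapses
the inlet pulse (scale ≈ 0.38) and produces large unphysiological
systolic backflow; see Limitations.

Cycles are repeated until the cycle-to-cycle L∞ pressure change is
below 0.5 mmHg (then polished to 0.05 mmHg so the per-cycle mass budget
closes); the baseline converges in 3–4 cycles.

### Wave-intensity analysis

At a probe station (default: vessel midpoint), increments are periodic
first differences over the converged cycle; the split uses the local,
time-varying pulse wave velocity c_p(t) = √(A/ρ ∂p/∂A) evaluated on the
simulated A(t) (for the adopted tube law c_p ∝ A^{−1/4}, i.e. slowly
*decreasing* with distension). WI± = (δp±/δt)(δu±/δt), so forward
intensity is non-negative and backward non-positive by construction.

Lobes are contiguous excursions of |WI±| above 1% of the global |WI|
peak, classified by direction and by the sign of the lobe's net
directional pressure increment, and matched to the expected sequence
a:BCW, b:FCW, c:BCW, d:FDW, e:BDW, f:FCW by an order-preserving
assignment that maximizes matched energy (waves below threshold are
reported as absent, with a warning if fewer than six are found — the
threshold and matching rule are this package's segmentation choices;
the six phases are described narratively in the literature without an
algorithm). Lobe energy is ∫|WI|dt, so backward lobes contribute
positive shares; percentages are shares of the six labeled lobes.
Report tables carry two published invasive-measurement columns as
static comparison metadata.

## Problem sizes and presets

* `default`: dx ≤ 0.1 cm, ≥8 nodes/vessel, 4096 samples/period.
* `coarse` (used by the test suite and the acceptance script):
  dx ≤ 0.2 cm, ≥4 nodes/vessel, 1024 samples/period. The short
  intermediate trifurcation segment otherwise dominates the CFL time
  step with no measurable effect on the solution (halving dx changes
  the peak LCX pressure by <0.1%).
* `fast`: dx ≤ 0.4 cm, 512 samples/period, for smoke tests.

CFL number 0.5 with a 15% wave-speed margin, monitored every step.

## What the synthetic generators do and do not emulate

The toy structured trees and constructed waveforms
(`corowave.fixtures`) validate the machinery, not physiology: toy trees
use the same branching rule at enumerable scale (oracle for the
memoized recursion); synthetic waveforms are exact water-hammer
superpositions with non-overlapping monotone wavefronts, so the
decomposition and labeling can be checked against construction. Real
coronary signals have overlapping, partially reflected waves — passing
these tests shows the algebra and segmentation are correct, not that
the physiological wave pattern is right; that is assessed against the
published waveform features in the acceptance tests.

## Numerical choices

Junction and outlet Newton tolerances 10⁻¹¹–10⁻¹² (relative); areas are
floored at 0.2·A0 inside Newton steps to keep the tube law invertible;
tube-law inversion clips (p−p0)/f at 0.999. The kernel's DC and Nyquist
bins are forced real before the inverse FFT (Hermitian symmetry). The
first simulated cycle uses a zero-padded outflow history (logged); its
transient is discarded by the periodicity criterion. All computations
are deterministic; rerunning a scenario with the same configuration is
bit-identical.

## Known limitations

* **Bed impedance vs printed pressures/flows.** With the tabulated
  structured-tree parameters (α 0.9, β 0.6, l_rr 25, r_m 10 μm) the DC
  resistance of a terminal bed is ~1.3–1.5·10⁴ g cm⁻⁴ s⁻¹, an order of
  magnitude below what physiological coronary beds present at 4.5% of
  cardiac output and ~90 mmHg. Consequently pressure level and flow
  fraction cannot both be physiological: this package enforces the
  stated flow fraction, so simulated coronary pressures sit near
  23–57 mmHg rather than clinical 70–120 mmHg, and pressure-level
  quantities (e.g. the rarefaction peak pressure) are correspondingly
  low, while velocities and wave-energy *shares* are comparable.
* The six-wave table can be partial: waves c and f fall below the
  detection threshold at baseline in this configuration.
* The septal beds have the lowest impedance of all beds, so they absorb
  systolic cross-flow and the LAD (which feeds the largest septal bed)
  is not diastolic-dominant in this parameter regime.
* No venous circulation; the feedback pressure acts at the bed inlets
  only (the structured trees themselves are time-invariant); no
  viscoelastic wall; the lumped inlet model is a minimal stand-in with
  a DC-network flow split between left and right trees.
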