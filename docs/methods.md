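# Methods

## Scope and model chain

`cfesim` predicts electric fields generated in cochlear tissue when an
implanted 8-electrode array delivers constant-voltage electroporation
pulses.  The chain is: (i) a lumped circuit of the electrode–electrolyte
interface, parameterized from electrochemical impedance spectroscopy (EIS);
(ii) a quasi-static finite-element volume conductor for the tissue;
(iii) superposition coupling and field-level area analysis on the target
surface.  Tissue is electrically passive, isotropic and memoryless; all
frequency dependence and nonlinearity live in the interface circuit.

## Interface model

**Constant phase element.**  A platinum electrode in electrolyte shows
`Z = R_s + K/(jω)^m` with a frequency-independent capacitive phase of
`m·90°`.  The measured phase plateau of 65.3° gives `m = θ/90 = 0.7256`
(the two readings of the conversion — `2θ/π` in radians or `θ/90` in
degrees — are the same number).  `eis.fit_cpe` replaces manual tuning with
staged least squares: a coarse grid on `m` (with `K` from the low-frequency
magnitudes and `R_s` from the high-frequency floor) followed by a joint
refinement on equally weighted `log10|Z|` and `phase/90` residual channels.
A 60-seed Monte-Carlo at 2 % multiplicative magnitude noise and 1° phase
noise recovers `m` to ±0.006 and `R_s` to ±1.5 %; the tests assert the
looser envelopes ±0.02 and ±10 %.

**Ladder synthesis.**  For time-domain simulation the CPE is realized as
`n` parallel series-RC branches in geometric progression.  Writing `K` for
the ratio of successive time constants, self-similarity of the admittance
sum forces `R_{n+1}/R_n = K^m` and `C_{n+1}/C_n = K^{1−m}`.  The branch
density parameter `k` is interpreted as the **capacitance ratio** per
branch, so `K = k^{1/(1−m)}` (≈ 1.83 for k = 1.18): a 61-branch ladder then
spans ≈ 15.7 decades of time constant.  The wide span is essential, not a
luxury: a truncated ladder relaxes toward a pure capacitor below its band
over `~1/((1−m) ln K)` branches, so the constant-phase plateau must extend
well beyond the 0.1 Hz–10 kHz measurement window.  Reading `k` directly as
the time-constant ratio (span 4.3 decades) leaves no plateau at all — the
phase slides from 84° to 11° across the sweep and never sits near `m·90°` —
so that reading is rejected on numerical grounds.  The ladder is centered at
the geometric mean of the band.  Phase ripple shrinks as `k → 1` at fixed
span (0.22° peak-to-peak at k = 1.5, < 1e-4° at k = 1.18).

**Magnitude calibration.**  `(θ, k, n)` fix only the shape of `Z(f)`; the
absolute scale is one free parameter.  The middle-branch values are pinned
by requiring `|Z_ladder| = 100 kΩ at 0.1 Hz`, an order-of-magnitude match to
measured low-frequency electrode impedances.  Both the reference frequency
and target are config-exposed; delivered-voltage outputs are insensitive to
this scale at electroporation amplitudes because the Faradaic branch
dominates there (ladder current ≈ 0.2–0.4 mA of ≈ 23 mA at the plateau).

**Faradaic branches.**  Redox charge transfer is phenomenological: an
anti-parallel pair, each a diode in series with a memristor,
`V_if = ±[n V_T ln(1 + I/I_s) + M(q) I]`,
`M(q) = max(M_min, M_0/(1 + |q|/q_0))`, with the delivered charge
`q = ∫ I_F dt` persisting across pulses of a train (configurable reset).
The source literature does not print usable parameter values, so the
defaults are an explicit calibration with two anchors: a 20 V / 50 ms pulse
(1 ms ramps) into tissue loads of 522 Ω and 174 Ω must deliver end-of-
plateau electrode potentials of ≈ 12 V and ≈ 7 V.  A chord analysis of the
two operating points (nearly equal currents ≈ 23 and 40 mA at memristances
≈ 49 and 25 Ω, charge ratio ≈ 1.7) fixes the order of magnitude of `M_0`
and `q_0` analytically; the shipped values `I_s = 1 µA`, `n = 2`,
`V_T = 25.85 mV`, `M_0 = 50 Ω`, `q_0 = 1 mC`, `M_min = 10 Ω` then give
12.06 V and 6.93 V in simulation.  They are stored in config, never
hard-coded in algorithms.

**Read point.**  The circuit is source → interface (ladder ∥ Faradaic pair)
→ spreading resistance `R_s` → tissue load → ground.  The waveform handed to
the field model is the potential at the node feeding the tissue load
(`I·R_tissue`), i.e. the stimulus actually delivered to the tissue past both
the double layer and the spreading resistance.  This choice is forced, not
cosmetic: with the alternative read point (`I·(R_s+R_tissue)`), the two
calibration anchors would require the interface's chord resistance to
*increase* with current between the operating points, which no
diode-plus-decaying-memristor branch can do (the alternate-load run always
passes more current, hence more charge, hence lower memristance) — the best
joint fit misses both anchors by > 1 V.  The upstream node remains available
as `read_point="after_interface"`.

**Integration.**  States are the branch capacitor voltages and the Faradaic
charge.  Each step solves the scalar node equation for the interface voltage
by Newton with a bisection safeguard (the residual is monotone) and advances
the states with the trapezoidal rule — A-stable, second order, fixed step,
hence bit-reproducible.  The default step is 1 µs, and the grid lands
exactly on the pulse corner times; the inner branch-current solve is a
safeguarded scalar Newton with analytic derivative.  Verification: a
single-branch step response matches the closed form to 1e-6 relative, and
the sinusoidal steady state of the full ladder matches the frequency-domain
divider to 0.5 % / 0.5° at 10–1000 Hz (time-domain runs are warm-started on
the phasor steady state to skip the multi-second edge-branch transients).

## Finite elements

Linear (P1) tetrahedra with piecewise-constant conductivity per region;
`E = −∇V` is exact per element.  Quadratic elements were deliberately traded
for refinement-convergence tests on nested meshes (a constriction fixture
shows the monotone resistance convergence expected of conforming elements).
Membranes are duplicated-node sheets coupled by the triangle mass matrix
scaled by `σ_m/d_s` (S/m²); rim nodes stay shared (the membrane is attached
to the surrounding tissue).  The transparent (`d_s → 0`) and insulating
(`σ_m → 0`) limits recover the membrane-free and decoupled solutions.
Electrode surfaces are equipotential Dirichlet patches; all other exterior
boundaries are zero-flux.  The linear solve is a cached sparse LU by default
(CG with Jacobi preconditioning available); the default relative residual
target is 1e-8 — far tighter than needed for engineering answers, but
required for the analytic-oracle comparisons (slab 666.67 Ω; slab plus
90 µm membrane 976.57 Ω, both matched to ≲1e-9 relative on the structured
mesh, where the piecewise-linear-plus-jump solution is exactly
representable).  Electrode currents come from the assembled-matrix residual
at Dirichlet nodes (consistent flux), conserving current to 1e-6 relative.

**Resistance extraction** applies ±V/2 to the anode/cathode banks (any
split gives the same resistance by linearity — asserted) and divides by the
anode-bank current.

## Coupling

The tissue model is linear and memoryless, so the transient field problem
factorizes: one unit solve (+1 V anodes / −1 V cathodes), scaled by the
circuit's delivered potential V(t) at each sample.  A brute-force mode
re-solves the FE problem per sample and is asserted against the scaled
solution in the tests.  Samples are dense (10 µs) on the ramps and sparse
(1 ms) on plateaus, covering ramps and plateaus both.  Note one bookkeeping
consequence of the symmetric ±V(t) application inherited from the source
decomposition: the FE anode-to-cathode span is 2·V(t) while the one-port
circuit delivers V(t) into the extracted resistance, so the consistency
check asserts `I_FE · R_tissue = 2 V(t)` rather than equality of the two
currents.

## Synthetic geometry

The generator emulates the topology and length scales of the guinea-pig
cochlea, not its anatomy: a 16 mm duct (unrolled cochlear length) of
1.0 × 1.6 mm fluid cross-section inside a 0.3 mm soft-tissue shell; scala
tympani (0.7 mm high) under the basilar membrane, scala media (0.3 mm) with
a 0.3 mm-wide nerve-tissue partition on its far side, Reissner's membrane,
scala vestibuli (0.6 mm); membranes end 1 mm before the apical wall
(helicotrema); the electrode array (8 bands of 0.3 mm length and 0.3 mm
spacing on a 0.3 mm square insulating carrier, ring area 0.36 mm² per
electrode ≈ the 0.33 mm² cylindrical metal area) enters at the basal end,
1.2 mm from the wall, riding 0.2 mm under the basilar membrane.  Meshing is
a structured Kuhn (six-tet) grid, conforming and nested under uniform
refinement, default cell 100 µm (≥ 3 elements per electrode band enforced);
feature coordinates snap to the grid.  A spiral coordinate map (variable
radius, uniform pitch) is available behind a flag; it bends the duct but
cannot create contact between turns.

**What the duct reproduces and what it does not.**  Structural results
carry over: tandem loads the source with a higher tissue resistance than
alternate (442 vs 97 Ω here; 522 vs 174 Ω on the original anatomy), tandem
therefore receives the higher delivered potential (11.3 vs 4.6 V), and
tandem covers more target area at low-to-mid field levels.  The *magnitudes*
of the tandem/alternate area ratios do not carry over, and the suite's
field-area-contrast assertions on the duct are expected to fail: in a
sealed straight duct the current leakage length across the membranes,
`λ = sqrt(σ_fluid A_st d_s / (σ_m w))` ≈ 0.6 mm, confines fields to the
array's neighbourhood, whereas in the real spiral the turns lie against one
another and current crossing between turns spreads moderate fields over
basilar-membrane regions far beyond the insertion — the mechanism behind
the reported three-to-fourfold tandem advantage in the 20–100 V/cm band and
the alternate configuration's large ≥ 500 V/cm area.  On the straight duct
at these drives the basilar membrane sees at most ≈ 380 V/cm (tandem) /
≈ 150 V/cm (alternate), so the ≥ 500 V/cm band is empty for both.  Passing
the structural tests on the duct therefore says nothing quantitative about
transfection-relevant areas in a real cochlea; the duct is a testbed for
the machinery, not a surrogate anatomy.

## Field-area analysis

Per-element |E| (constant on P1 elements, element-centroid semantics) is
evaluated on the element adjacent to each target-surface triangle — for
membranes, the scala-tympani side by default, since the transfection targets
are the mesenchymal cells facing the array (side-2 and mean-of-sides are
options).  Triangle areas accumulate into half-open bins `[lo, hi)`; under-
and overflow bins make every row sum to the total surface area exactly.
Default edges 4, 8, 20, 100, 500, 1000 V/cm bracket the named windows of
interest.  Ratios between configurations mark 0/0 as NaN and x/0 as +inf;
the summary ratio is taken at the end-of-plateau sample.

## Numerical choices and degenerate inputs

Capacitive phase is stored positive in [0, 90]°, converted to the negative
electrical convention only inside complex arithmetic.  Pulse width is
measured from onset to the start of the fall ramp; plateau = width − rise.
A pure-resistor spectrum pins the fitted `m` at its lower bound and is
flagged in the diagnostics rather than rejected.  Meshes are validated on
construction and import (positive orientation, conformity, label coverage,
membrane pairing bijection, electrode adjacency to the scala tympani).
Circuit and mesh generation are deterministic; the only randomness in the
package is the EIS noise generator, which takes an explicit seed.

## Known limitations

No electrochemical species balance, pH or water-window modelling; no
electro-permeabilization feedback (conductivities are static during the
pulse); no tissue capacitance or anisotropy; no transfection-probability
model on top of the field maps; no anatomically faithful cochlea.  The
Faradaic parameters are a two-anchor calibration, not an electrochemical
characterization, and delivered-voltage predictions outside the calibrated
load range (≈ 100–5000 Ω) should be treated as extrapolation.
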