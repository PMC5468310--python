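# Methods

## Model

A neuron is a rooted tree of cylindrical sections embedded in the plane.
The y axis is the somato-dendritic axis; dendrites extend toward +y, the
axon toward −y. Each section is divided into an odd number of equal
compartments of length at most `max_compartment_length` (default 10 µm), so
every section — in particular the soma, the canonical recording site — has
a true midpoint compartment. Membrane dynamics are evaluated at compartment
centers; adjacent centers are coupled by the series conductance of the two
intervening half-compartments, g = 1/(R₁/2 + R₂/2) with
Rᵢ = 4·Ra·Δxᵢ/(π·dᵢ²), which reduces to (π d²/4)/(Ra·Δx) on a uniform
cylinder.

A uniform field of amplitude E (mV/mm; positive = anode on the dendritic
side) assigns each compartment center the extracellular potential
V_ext = E·(projection of the center onto the field axis, referenced to the
cathode-side extreme of the morphology). The transmembrane potential is
V = V_in − V_ext, and the axial current between neighbors j,k is
g_jk·((V_k + V_ext,k) − (V_j + V_ext,j)); the field therefore enters the
voltage system as the constant drive L·V_ext (L the axial-conductance
Laplacian) while the field is on. Because L annihilates constants, the
dynamics depend only on V_ext *differences*; the reference-plane choice is
cosmetic and fixed only so stored values are reproducible. Transverse field
coupling is deliberately absent: membranes are treated as insensitive to
the field component perpendicular to the cable axis, and the extracellular
medium is not otherwise modeled. The z dimension is carried through SWC I/O
but ignored by the physics; an off-axis field angle is supported by the
data model but every protocol of record uses 0°.

### Membrane

Passive constants: Cm = 1 µF/cm², Ra = 80 Ω·cm, Rm = 28 kΩ·cm² (leak
conductance 1/Rm), E_leak = −65 mV. Active currents: transient Na⁺
(m³h, 200 pS/µm² everywhere), delayed-rectifier K⁺ (n, 100 pS/µm²
everywhere), A-type K⁺ (n·l, 250 pS/µm² at the soma rising by 250 pS/µm²
per 100 µm of path distance on dendritic sections only), and I_h
(0.5 pS/µm² rising by 1.5 per 100 µm on dendrites only). Path distance is
measured from the soma midpoint, so the soma's half-length contributes to
every attached section. The unit identity 1 pS/µm² = 0.1 mS/cm² is
implemented in exactly one constant and tested against an independent
derivation.

Gating kinetics are data, not code: `data/ca1_kinetics.yaml` describes each
gate in a small algebra of rate forms (linoid alpha/beta pairs,
Boltzmann steady states, thermodynamic Borg-Graham-style time constants
with optional voltage-dependent valence, linear time constants with
floors). The shipped file is this package's transcription of the classic
hippocampal CA1 channel lineage, evaluated at 24 °C with no extra q10
scaling; reversal potentials are the standard values for that lineage
(E_Na = 55, E_K = −90, E_h = −30 mV). Users can point any run at a
different kinetics file; its SHA-256 hash is recorded in every result
bundle.

## Numerics

The integrator takes first-order implicit (backward Euler) steps of
dt = 0.025 ms on the voltage system. Per step: gates advance by the exact
exponential update x ← x∞ + (x − x∞)·e^(−dt/τ) at the frozen start-of-step
voltage (x∞ and e^(−dt/τ) come from tables on a 0.05 mV grid over
−150…100 mV, linearly interpolated and clamped at the ends); channel
conductances are then frozen, making the voltage system linear, and it is
solved by a direct two-sweep elimination on the tree (compartments are
topologically ordered) followed by one step of iterative refinement, which
keeps the per-step nodal current balance at round-off (~1e-15 relative,
asserted < 1e-9 in tests). The stepper is a single numba-compiled kernel.
|V| > 500 mV at any compartment aborts the run with the time and site.

Backward Euler is unconditionally stable on the stiff compartment chain;
accuracy is checked three ways: a single step against the matrix-exponential
solution of a two-compartment passive system (1e-6 mV at dt = 1e-7 ms),
dt-halving self-convergence (< 0.1 mV sup-norm on a passive run), and
Δx-halving stability of polarization profiles (< 1% sup-norm). The
steady-state polarization of a sealed passive fiber in an axial field
matches the closed form ΔV(x) = Eλ·sinh((x−L/2)/λ)/cosh(L/(2λ)),
λ = √(Rm·d/4Ra), to < 0.01% at Δx = λ/50 (x measured toward the cathode:
the anode-side end hyperpolarizes).

Resting state: a passive membrane rests exactly at E_leak (unique fixed
point, set directly). The full model is relaxed by unstimulated simulation
in 100 ms chunks until max |dV/dt| < 1e-5 mV/ms (budget 5 s of model time);
steady-state polarization runs use the same settling criterion with the
field held on, and abort if any compartment crosses 0 mV.

## Protocols

* **Spike detection**: upward crossings of 0 mV at the soma midpoint with a
  2 ms refractory gap. 0 mV is far above all subthreshold dynamics and far
  below AP peaks, so the detector is insensitive to its exact value.
* **EF firing threshold**: with the cell at rest, the field steps on from
  100 ms to 600 ms. A coarse upward scan in 10 mV/mm increments finds the
  first spiking amplitude, then bisection narrows the bracket to the
  requested resolution (default 0.5 mV/mm; 0.1 for headline numbers). The
  reported threshold is the spiking bracket end; the full search log is
  kept. Quiescence without a field is verified first. "No spike up to
  E_max" (default 1000 mV/mm) is a result, not an error.
* **f–E curves**: firing rate over the field-on window only.
* **Morphology sweeps**: rebuild the artificial cell per grid value and
  re-run the threshold search. Size (diameter/length) grids start at the
  default cell's value and increase over 4 points; angle grids span
  0–90°; counts bracket the defaults; dendrite removal proceeds
  distal-first. These desk-scale grids are this package's declared choices.
* **EPSC co-stimulation**: a rectangular current pulse into distal dendrite
  No. 8, by default 2 ms long, arriving 50 ms after field onset. The pulse
  is deliberately brief: the default cell's whole-cell input resistance is
  of order GΩ (≈780 µm² of membrane at Rm = 28 kΩ·cm²), so even 0.01 nA
  *sustained* would spike the cell on its own; a 2 ms pulse is
  charge-limited to an EPSP-sized depolarization and both standard
  amplitudes (0.01, 0.03 nA) stay subthreshold alone, which the protocol
  verifies before searching.
* **AP-site diagnostics**: with every compartment recorded, the initiation
  site is the earliest upward crossing of the detection threshold (ties
  broken by the higher voltage at the crossing sample); peaks are taken in
  a [−1, +5] ms window around the first crossing.
* **Polarization vs field**: settled somatic ΔV over a subthreshold
  amplitude grid, summarized by a least-squares slope (mV per mV/mm) and
  the maximum residual.

## Artificial cell layout conventions

The default cell: 10×10 µm soma centered at the origin, 50 µm × 2 µm axon
from the soma's −y end, four 8 µm × 1 µm proximal dendrites from the +y
end, each carrying two 2 µm × 1 µm distal daughters (14 sections).
Decisions the geometry description leaves open, fixed here
deterministically:

* Proximal dendrites fan at 10° spacing symmetric about +y (for other
  counts, ~1/3 of dendrites are proximal and the rest distal, assigned in
  contiguous blocks — dend7/dend8 belong to dend2, so "No. 8" is a daughter
  of the second proximal dendrite).
* The bend angle tilts each proximal dendrite (rigidly carrying its
  daughters) further from vertical; the bifurcation angle splits daughters
  ±α/2 about the parent axis; the axon bend tilts the whole axon from −y.
* Axon terminal branches (20 µm × 2 µm each) are instantiated only when
  there are ≥ 2 of them or the terminal branch angle is nonzero; a single
  straight "terminal" is just the axon tip, keeping the default cell at 14
  sections.
* `apply_bend` rotates a section about its proximal point in whichever
  sense grows its |x|-extent (ties toward +x), translating descendants
  rigidly.

## Synthetic asymmetric morphologies

The generator emulates the one structural property that controls the sign
of somatic polarization under a uniform field: the fraction of dendritic
cable on the anode (+y) versus cathode (−y) side of the soma. It grows
`n_branches` stems (default 12) of bifurcating subtrees
(`branching_depth` = 2, segment lengths ~ N(60, 15²) µm clipped at 5,
diameter 1 µm) within a ±65° cone of the vertical, each stem entirely on
one side, and partitions stems between sides by a greedy cable balance with
a local-improvement pass; the realized fraction must land within 0.05 of
the target or generation fails loudly. Generation is a pure function of
(spec, seed).

What it does *not* emulate: real reconstructions' tapering, 3-D tortuosity,
spines, section-type statistics, or any specific cell. Tests passing on
these arbors show that the polarization-sign mechanism (cable asymmetry →
soma depolarization sign) holds across random geometries; they say nothing
about quantitative polarization maps of particular real neurons.

## Known disagreements with the reference findings

This package encodes a set of previously reported morphology-threshold
relationships as acceptance expectations. Under the printed model
parameters, four of them come out with the opposite sign, and the tests
that assert them fail by design rather than being weakened:

* With the default geometry the cell's area-weighted center sits ≈10 µm
  below the soma, so a positive field *hyperpolarizes* the soma (slope
  ≈ −0.008 mV per mV/mm) and the most depolarized point is the distal axon
  tip. APs therefore initiate at the distal axon, and the threshold tracks
  axon-tip polarization.
* Consequently: threshold *rises* with soma diameter, *rises* with axon
  bend angle, *rises* with terminal branch angle, and *falls* (then
  saturates non-monotonically) with terminal count — each opposite to the
  reference direction, which presupposes a soma-governed threshold with the
  axon acting as a net current sink. The remaining eleven direction
  relationships and the EPSP ordering match.
* The reference threshold magnitudes (+163.4 / −172.4 mV/mm) are not
  reproduced exactly (+233.8 / −343.0 here at 0.1 mV/mm resolution); the
  asymmetry |T₋| > T₊ is. Exact magnitudes would require the exact gating
  equations and reversal potentials of the original implementation, which
  are not part of the printed description; the shipped kinetics file is a
  faithful-lineage transcription, and all qualitative firing properties
  hold under it.
* At matched diameter grids, the distal dendrite group (8 branches) moves
  the threshold more than the proximal group (4 branches), again consistent
  with tip-governed initiation.

These analyses were verified insensitive to discretization (Δx = 2 µm) and
to plausible alternative readings of the density rules (e.g. extending the
A-type/h gradients along the axon).

## Limitations

Step-on/step-off uniform fields only (no AC or spatially non-uniform
fields); no calcium dynamics, synaptic conductances, stochastic channels,
temperature scaling, or myelination; strictly planar geometry; the EPSC is
a current pulse, not a conductance. Sweeps mutate one parameter at a time.
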