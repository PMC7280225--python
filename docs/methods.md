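# Methods

This note documents the models, numerical choices and limitations behind
`memfes`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Collective-variable space

All analysis happens on two collective variables (CVs): a molecular
torsion Ψ (radians, periodic with period 2π, canonically wrapped into
(−π, π]) and the membrane-normal distance z (nm) between the permeant's
center of mass and the bilayer midplane, bounded to [0, z_max]. Free
energies are in kJ/mol throughout; k_B = 0.008314462618 kJ/(mol·K).

Grids are uniform per axis with values on *bin centers*. The default
analysis grid is 144 Ψ-bins × 120 z-bins over [−π, π] × [0, 4.5 nm],
i.e. ≈ 0.044 rad × 0.0375 nm resolution — fine enough that basin
positions quantize to well under the feature sizes of interest.

## Well-tempered bias and FES estimator

The accumulated bias of a hill stream is the sum of deposited Gaussians

    V(s) = Σ_k h_k exp(−Σ_i d_i(s, c_k)² / (2 σ_{k,i}²)),

with d periodic-aware on Ψ. Gaussians are truncated at 5σ per axis; the
neglected mass is exp(−12.5) < 4·10⁻⁶ of the peak, far below every
tolerance used. The tempering rule for a new hill at s is
w = w₀ exp(−V(s)/(k_B ΔT)) with ΔT = (γ−1)T, and the free-energy
estimator is

    F(s) = −((T + ΔT)/ΔT) V(s) = −(γ/(γ−1)) V(s).

This is the plain sum-of-hills reconstruction from the *final* bias; no
time-dependent offset c(t) correction is applied. That matches what a
grid produced by summing a HILLS file represents, and since only free
energy differences are physical the uniform offset is irrelevant — but
transient early-run hills do contribute, which is a documented
limitation relative to reweighting-based estimators.

Defaults (T = 303.15 K, γ = 10, σ_Ψ = 0.35 rad, σ_z = 0.1 nm,
w₀ = 1.2 kJ/mol, pace 500) are ordinary values for torsion/distance CV
pairs in bilayer metadynamics; they are configuration values, always
overridable and echoed in the report, not values attributed to any
specific study.

### Convergence diagnostic

`convergence_profile` splits the hill stream into n contiguous blocks,
builds an independent FES estimate *per block*, and reports the RMSD
between consecutive estimates after removing each one's mean (the gauge
freedom). Per-block rather than cumulative estimates make the
diagnostic exact for the degenerate case of a literally repeated hill
segment (RMSD 0) and make height decay visible: for a tempered run the
late-block RMSD falls below the early-block RMSD.

## Landscape analysis

**Zero reference.** Following the bulk-solvent convention, F is pinned
to 0 at a chosen CV point — by default (Ψ = 0, z = 4 nm), the fully
water-solvated state — so bound states carry negative F. Only the
additive gauge changes; all pairwise differences are preserved exactly.

**Unexplored nodes.** Nodes never touched by bias are flagged, never
treated as F = 0. Wherever a finite value is needed (path search,
marginalization) they enter at max(explored F) + 20 kJ/mol, which both
blocks spurious low-F shortcuts and contributes essentially nothing to
Boltzmann integrals.

**Basins.** Stable states are strict local minima of the grid
(8-neighborhood, periodic-aware in Ψ) filtered by *depth*: the minimax
escape level (lowest maximum-F over grid paths to any strictly lower
node) minus the minimum's own F must exceed a threshold (default
1 kJ/mol). Depths are computed in one O(N log N) watershed/union-find
sweep. The filter removes the shallow pockets that bias noise imprints
on reconstructed surfaces. Basins are labelled A, B, C, … by ascending
F.

**Saddles.** The lowest crossing between two states is found by minimax
("widest-path") Dijkstra on the 8-connected node graph with Ψ-periodic
edges; ties are broken by path length, then lexicographic node order,
so results are deterministic. Its exactness is cross-checked in the
tests against two independent oracles: literal DFS path enumeration on
tiny grids and threshold-connectivity flood fill on 15×15 grids.

**Barriers.** `barrier` is the signed difference F(crossing) − F(start)
between grid nodes and may be negative; 1D profile barriers use linear
interpolation between bin centers.

## Marginalization to 1D

The 1D profile integrates out the other CV with Boltzmann weights:

    F(s1) = −β⁻¹ ln [ ∫ e^(−β F(s1,s2)) ds2 / ∫∫ e^(−β F(s1,s2)) ds1 ds2 ].

Both integrals use midpoint quadrature on bin centers (each center
represents one bin of width Δ). Midpoint is the natural — and for the
periodic Ψ axis the correct — rule on center-sampled data, and it makes
the self-normalization identity Σ exp(−β F(s1)) Δs1 = 1 hold to machine
precision, which the tests assert at 1e-6 across random landscapes.
Sums are evaluated with log-sum-exp for numerical safety. For
reporting, F(z) is re-zeroed at the bulk-water z reference and F(Ψ) at
its minimum; the applied offset is tracked so the normalized form is
recoverable.

The 2D path barrier and the 1D profile barrier for the same transition
are different observables — the 1D value folds in the Boltzmann weight
of every transverse state — and the report carries both without
reconciling them.

## Minimum free energy paths

Among the family of iterative path-refinement schemes, the
zero-temperature string method was chosen: it is standard,
deterministic given the initial path, and directly testable against the
minimax oracle.

* **Seeding.** The minimax Dijkstra node path between the two basins,
  resampled to 100 points at uniform arc length (cubic spline). If the
  straight Ψ-geodesic segment already achieves the minimax crossing
  level it is preferred for smoothness (on a flat landscape the seed is
  then exactly the geodesic).
* **Relaxation.** Interior points move by −step · ∇⊥F, the component of
  the bilinearly interpolated central-difference gradient perpendicular
  to the local tangent; endpoints stay pinned; the path is
  reparametrized to uniform arc length each sweep. Default step
  5·10⁻⁴ (CV units)²·mol/kJ, tolerance 1e-4 CV units on the largest
  per-sweep displacement, at most 5000 sweeps. A sweep that would move
  a point more than two bin diagonals raises a stability error. Near
  the fixed point the discretized gradient makes plain sweeps
  oscillate, so the step is halved after 25 sweeps without progress;
  hitting the iteration cap is reported (`converged=False`), not an
  error.
* **Periodicity.** Path coordinates are kept unwrapped along the path
  and wrapped only for grid lookups, so paths cross the ±π seam without
  2π jumps.
* **Transition state.** The interior argmax of F along the path, with a
  parabolic fit through its two neighbors for sub-node location and
  energy. A monotone profile (no interior maximum) returns the higher
  endpoint with a warning flag. The pipeline marks the highest TS over
  all requested pairs "global", the rest "local".

## Synthetic data

### Fixture landscape

`make_melatonin_like_fes` builds a closed-form landscape with the
features of a small amphiphilic solute at a cholesterol-free
phosphatidylcholine bilayer: four interface basins near z ≈ 0.8 nm
(folded conformer pair at Ψ = ±1.17 rad, extended pair at ±2.8 rad), a
flat bulk-water shelf at F = 0 beyond z = 3 nm, an interface→water rise
of 25.3 kJ/mol, an interface→membrane-center wall of 40 kJ/mol, and an
attractive interface band that puts the extended↔folded angular saddle
near −6.5 kJ/mol (≈ 18.8 kJ/mol above the deepest basin). The extended
conformer is placed strictly inside ±π because two wells at exactly ±π
coincide on a periodic axis; ±2.8 rad keeps the pair distinct while
staying within the observed spread of extended-conformer torsions.

Because the Gaussian terms overlap, nominal well depths would miss
their targets; depths are instead obtained from a 4×4 linear solve
(overlap matrix × depths = targets − background) with two fixed-point
sweeps for the wall amplitude, making F at each well center hit its
construction target to 1e-9. Residual tilts from neighboring terms
displace each minimum by far less than one grid bin, which the tests
check.

### Langevin + metadynamics simulator

CV-space dynamics are overdamped (Brownian):

    x ← x − D β ∇(U + V) dt + sqrt(2 D dt) η,   η ~ N(0, 1),

with per-CV diffusion constants (default 0.1 CV²/time), Ψ wrapped and
bounded axes reflected at the walls. Only CV-space sampling matters for
validating the analysis chain, so no inertia is modelled. Noise comes
from a single counter-based Philox stream keyed by the seed, making
trajectory and hill stream bit-reproducible given (seed, parameters). A
displacement exceeding 5σ in one step raises a stability error naming
dt.

The double-well recovery benchmark uses U = (h/2)(1 − cos 2Ψ) + harmonic
confinement in z with h = 10 kJ/mol, run for 2·10⁵ steps at dt = 0.05,
D = 0.1, pace 200, w₀ = 1.2 kJ/mol, γ = 10, T = 303.15 K, and five
seeds; these sizes let a laptop-scale run make dozens of barrier
recrossings and recover the marginalized barrier to within
1.5 kJ/mol on the seed mean, with the block-RMSD diagnostic decaying in
every seed. The problem sizes (grid 72×40, 1000 hills per seed) were
chosen as the smallest that keep the discretization error well below
that tolerance.

### What the generator does and does not emulate

It emulates: hill streams with tempered heights over a periodic ×
bounded CV pair, multi-basin landscapes with the printed barrier
magnitudes, bounded-axis reflection, and convergent well-tempered
filling. It does **not** emulate atomistic reality: no solvent or lipid
degrees of freedom, no CV-orthogonal slow modes, no friction anisotropy
along z, no finite-sampling artifacts of a 2-CV projection of a
high-dimensional system. Passing tests therefore demonstrate that the
*analysis machinery* is correct and self-consistent at desk scale — not
that any particular membrane simulation is converged.

## Degenerate inputs and tie-breaking

* Empty hill series → zero bias everywhere; reconstruction gives an
  all-zero (explored) grid.
* Identical path endpoints → a single-point path; TS queries on
  monotone paths warn instead of failing.
* Flat surfaces have no strict minima; the pipeline raises a diagnostic
  error echoing the depth threshold.
* All graph searches break ties deterministically (path length, then
  lexicographic node order); reports serialize floats at 6 significant
  digits, so rerunning on identical inputs is byte-identical.

## Known limitations

* The final-bias estimator carries the transient of early hills; for
  quantitative work on real HILLS data, discard an equilibration prefix
  or reweight externally.
* Minimum-image Gaussians on Ψ (rather than full image sums) are exact
  only for σ_Ψ well below one period; all defaults satisfy this.
* The string method finds the MFEP homotopic to its seed; the minimax
  seed targets the lowest crossing, but strongly multi-channel
  landscapes may hold other locally minimal paths.
* No error bars on F: block bootstrapping of the hill stream is future
  work.
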