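# Methods

## The message force law

A message's state-changing force on a receiver at distance `d` is
`G(d) = w · exp(-beta · d)` for diffusive modalities (chemical, light,
mechanical share the functional form; the modality is metadata) and the
indicator `d == 0` for contact modalities (adhesion molecules, touch).
The pre-decay amplitude `w` defaults to 1 — the force law is dimensionless
with unit amplitude, and any per-message scaling is folded into `w` —
so per-message forces always lie in [0, 1].  Receptor activation is
thresholded per message and per pair *before* aggregation: a pair
contributes only when the sender expresses the ligand, the receiver
expresses the receptor, and the force reaches `activation_threshold`
(comparison is `>=`).  The aggregate field is the plain sum of per-message
matrices; no normalization is applied at this layer.

Message flow is `J = (1/A) dn/dt`, estimated from a sampled amount series
by the central stencil `(n[i+1] - n[i-1]) / (t[i+1] - t[i-1])` with
one-sided differences at the boundaries.  This exact stencil is part of the
contract (tests check it against an independent loop implementation), which
is why it is written out rather than delegated to `np.gradient`, whose
non-uniform-grid formula differs.

Entropy generation density is `sigma = sum_i G_i J_i`; with non-negative
forces and flows it is non-negative, and it is bilinear and additive over
message partitions.  When forces interfere through the full flow vector,
`entropy_production` accepts a callable `G(J)` evaluated at the current
flows; no specific interference form is built in because none is standard.
The entropy *flux* term of the general entropy balance is out of scope:
only generation is accounted.  In trajectory records, sigma uses steady
unit flows (one unit of message per coupled pair per unit time through unit
area, scaled by the coupling), so it measures the capacity of the current
field configuration to drive change, not a kinetic quantity; it is constant
within a stage and grows with population/contact density across stages.

## Phase dynamics

Each subsystem is phase-reduced: `dtheta_j/dt = omega_j + (1/N) sum_k
G_jk h(theta_j - theta_k)`.  Design choices:

* `h(x) = -sin(x)` (attractive Kuramoto coupling) by default — the unique
  standard choice under which the Cauchy mean-field law below holds.  Other
  registered functions fall back to an O(N^2) pairwise evaluation; the
  sine coupling uses the exact trigonometric reduction
  `sum_k G_jk sin(theta_k - theta_j) = cos(theta_j)(G s)_j - sin(theta_j)(G c)_j`,
  which is what makes N = 2000 × 20 000 RK4 steps run in seconds.
* The diagonal of matrix couplings is zeroed.  For odd `h` this is a no-op
  (`h(0) = 0`); it is enforced for numerical hygiene with arbitrary `h`.
* The `1/N` prefactor is kept exactly as written even for sparse coupling
  matrices; no row normalization is applied (a deliberate choice — degree
  effects like the inner/outer force difference are the mechanism of
  interest, not a nuisance).
* Integration is fixed-step RK4 (`dt = 0.01` default), Euler selectable;
  phases are wrapped to [0, 2*pi) each step.  Fixed-step integration gives
  bit-reproducible trajectories for a given seed, which adaptive steppers
  would not.  Step-halving on a reference instance changes final phases by
  < 1e-4.
* Natural frequencies are Cauchy(omega0, gamma), sampled by inverse CDF
  `omega0 + gamma * tan(pi(u - 1/2))` for cross-platform reproducibility.

The order parameter is the modulus/argument decomposition
`(1/N) sum_j e^{i theta_j} = R e^{i Theta}`.  Steady state is the time
average of R over the post-burn-in window (default burn-in fraction 0.5,
horizon 200 for threshold studies).

For Cauchy frequencies and global coupling `G_E` the mean-field stationary
solution is `R_inf = sqrt(1 - 2 gamma / G_E)` above the critical coupling
`G_c = 2 gamma`, and 0 below.  The critical-coupling estimator exploits the
linearity of `R^2` in `1/G`: it simulates steady `R` on a coupling grid
(one shared frequency draw and initial condition across the grid, a paired
design that removes sampling noise from the comparison), keeps points with
`R > 0.3` (below that, the finite-size floor `R ~ N^{-1/2}` dominates), and
returns the negated regression slope, with the intercept (expected ≈ 1) as
a diagnostic.  At N = 2000, horizon 200, grid {2.5, 3, 4, 5, 6, 8} the
estimate lands within ~0.1 of 2 gamma; the incoherent branch time-averages
to R ≈ 0.03–0.05, i.e. 0.0 at one decimal.

## Populations

Cells carry positions, ligand/receptor sets, and a state label; contacts
are an undirected graph with per-edge distances, rebuilt from geometry by
an `O(N^2)` radius rule (edge iff distance <= contact radius; coincident
cells give distance-0 "touching" edges).  Division replaces every cell by
two daughters that inherit expression, label, and (jittered) phase;
daughter frequencies are *redrawn* from the population frequency model by
default — proliferation re-disperses intrinsic rates, which is the
mechanism by which growth breaks synchrony — with an inherit-with-noise
mode for lineages whose rates are heritable.  Compaction scales the contact
radius (default factor 1.4), rebuilds the graph, and adds the adhesion
ligand/receptor to every cell.

Inner/outer classification is a median split on total received force (row
sums of the aggregate field): cells strictly above the median (with a 1e-9
relative tie tolerance, so floating-point summation order cannot flip a
label) are "inner", ties and below are "outer".  A perfectly symmetric
field therefore labels everyone "outer": no asymmetry, no differentiation.

Synchronized sub-populations are detected by thresholding pairwise phase
coherence `cos(theta_j - theta_k)` (default threshold 0.9) and taking
connected components, ordered by size.  The detector also accepts a
(time × N) phase window and then uses time-averaged coherence — two
internally locked populations drifting past each other at Δω average to
near-zero cross-coherence over a window covering several relative cycles,
whereas a single snapshot can catch them momentarily aligned.  The windowed
form is what the embryo demonstration reports.

## The embryo demonstration

Six stages with cell counts (1, 2, 4, 8, 8, 16).  All cells express seven
growth-factor ligands and six receptors (artemin and GDNF share GFRα3 —
forced by seven ligands on six receptors with no other GFRα member in the
receptor list); all seven factors share default kinetics (beta = 1,
secretion 1, threshold 0) since no per-factor constants are modeled.

Geometry: after each division the blastomeres re-pack onto a circle with
nearest-neighbour spacing 1 (contact radius 1.05 → a ring graph), so the
received-force row sums are equal by symmetry at S1–S4 — the symmetric
state.  Compaction (S4→S5) is a single discrete event: the two prospective
inner cells move to the cluster centre (both at the origin — a distance-0,
fully adherent contact on which the E-cadherin contact force acts), the six
outer cells to a unit hexagon, and the contact radius scales by 1.4.  The
two centre cells then receive strictly more force (7 touching-distance
ligand contributions plus adhesion) than the six symmetric outer cells, so
the median split yields exactly 2 inner / 6 outer for every seed, with no
floating-point knife edges.

Frequencies: the demonstration's divisions use the inherit mode with small
Gaussian jitter (sd 0.01 per division) rather than the population module's
default Cauchy redraw.  Early blastomeres are nearly identical cells —
their natural-frequency variation is small, which is precisely why their
divisions synchronize — and a heavy-tailed redraw at N ≤ 16 would, with
appreciable probability per run, produce a single extreme-frequency cell
that no biologically sensible coupling can entrain, turning the two-lineage
outcome into a seed lottery.  The Cauchy model (gamma = 0.05 default)
remains the population-level description and drives the subcritical
control: a run with coupling below 2 gamma and re-dispersed frequencies
loses division synchrony, and the demo emits a warning whenever the
configured coupling is below 2 gamma.

Differentiation (S5→S6): daughters inherit lineage labels; the two
lineages' centre frequencies split by ±0.3 (differentiated cell states run
distinct oscillator programs); cross-lineage coupling is attenuated to 0.1
of the within-lineage value; the cdx2 proxy marks every outer-lineage cell.
The inner and outer populations then lock internally (within-lineage
effective coupling ≫ frequency spread) while drifting apart at ~0.6 rad
per unit time, so the windowed coherence detector reports exactly 2
clusters for every seed.  Dynamics during S1–S5 use the scalar global
coupling (default 1.0 = 20 gamma: the uniform autocrine field saturates all
pairs); the force-field matrices are computed alongside for entropy,
symmetry, and classification.

What the demonstration does and does not show: it establishes that the
force-field mechanism (uniform field → synchrony; contact-driven asymmetry →
median-split differentiation → separate synchronizations) is internally
consistent and reproducible; it does not model gene regulation (cdx2 is a
label, not a transcript), adhesion mechanics, or real embryo geometry, and
its parameter values are schematic defaults, not measurements.

## Discrete models

Transition systems are finite states × finite actions with a total map;
the three roles (causal / surrogate / message) differ only in
interpretation.  Surrogate time actions 0..T act by iterating a one-step
map, which is a monoid action of (N, +, 0) by construction; the checker
verifies the unit and composition laws on all enumerable triples and
returns the first counterexample as a structured record (checks compose —
no exceptions for failures).  Stochastic surrogates are supported as
row-stochastic tables reduced by argmax, since the transition-system layer
itself is deterministic.

Adjunction verification works on the categories *freely generated* by two
systems (objects = states, morphisms = action words, identity = empty word,
composition = concatenation).  Free categories are infinite, so everything
is truncated at a path-length bound (default 4) and restricted to ≤ 10
objects per category; within the bound, hom-table bijectivity is checked
exhaustively and naturality squares are checked on generating morphisms
(sufficient by induction on word length).  The package provides the
verification machinery plus a constructive witness for mutually inverse
relabelings (an isomorphism is an adjunction); it does not construct
canonical adjunctions between the three roles, because no canonical choice
exists — the exported embryo systems instead come with explicit causal →
surrogate and causal → message maps that pass the functor check.

## Problem sizes and tolerances

Large-population acceptance checks use N = 2000, dt = 0.01, horizon 200
(~10 s per run with the sine-coupling reduction); threshold recovery uses
the six-point grid above, and the mean-field comparison allows 0.05
absolute deviation in steady R (finite-N, finite-horizon bias near
threshold is the dominant error).  The embryo demonstration (N ≤ 16,
horizon 100 per stage) runs in ~2 s per seed.  Property suites compare the
vectorized derivative against a double-loop oracle at 1e-12, the entropy
sum against an inner product at 1e-12, and the Cauchy sampler against the
closed-form CDF by a KS test at the 1% level.

## Known limitations

* Only the phase-reduced dynamics are simulated; general vector-field
  limit cycles, delay coupling, and stochastic (Langevin) phase noise are
  out of scope.
* The diffusion PDE is never solved: the exponential force law *is* the
  spatial model, and flows are steady-state proxies.
* Receptor kinetics (binding constants) appear only as the activation
  threshold and coupling scale; light/mechanical transduction is not
  modeled beyond the shared decay law.
* Two-cluster message exchange along different spatial axes is supported
  only as a configurable scenario, without quantitative claims.
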