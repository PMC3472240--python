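# Methods

## Model

`rdvox` samples the reaction–diffusion master equation (RDME) exactly. The
simulation volume is a set of voxels — a single well-mixed compartment, or
the tetrahedra of an unstructured mesh — each assumed internally well-mixed:
non-reactive collisions dominate, molecules are point-like and uniformly
distributed within a voxel, and velocities are thermalized. Reactions follow
mass action; diffusion between face-sharing voxels `k` and `l` is the
reversible first-order channel pair with rates

```
d_kl = D * S / (V_k * dx_kl),     d_lk = D * S / (V_l * dx_lk)
```

(`S` shared-face area, `V` source-voxel volume, `dx` the symmetric
barycenter-to-barycenter distance). Compartment boundaries are reflective:
diffusion directions exist only toward neighbors in the same compartment.
Patches (triangle sets between compartments) hold surface species and host
surface reactions coupling inner volume, surface and outer volume.

## Stochastic kinetics conventions

* Units are SI internally (m, s, m³); concentrations are molar at the user
  boundary, so a volume reaction of order *n* has `k` in (M^(1−n))/s and a
  propensity `k (N_A V 10³)^(1−n) × Π n_i^(falling ν_i)`.
* Identical reactants: `A + A` has propensity `k n (n−1) / (N_A V)`, so the
  matching deterministic limit is `d[A]/dt = −2 k [A]²`. The RK4 solver uses
  exactly that bookkeeping, which keeps stochastic means and ODE solutions
  mutually consistent at large copy number.
* Surface reactions of order 2 with one volume-located reactant are scaled
  by that reactant's own volume element (`k n_A n_B / (N_A V_inner)`); when
  both reactants are surface-bound there is no natural volume and the rate
  scaling must be supplied explicitly per reaction (`surface_scale`), never
  defaulted silently. Zero-order surface production takes `k` directly as
  events/s per element.
* Reversible reactions are stored as two irreversible records; orders are
  capped at 3 (volume) and 2 (surface).

## Event loop

Waiting times are exponential, `dt = −ln(u)/a_total` with open-interval
uniforms (u = 0 rejected). Channel selection uses the composition–rejection
scheme: group `g` holds channels with propensity in `[2^(g−1), 2^g)`; a
group is drawn by composition over the (few) group sums and a member by
rejection with acceptance `a / 2^g`. Choices fixed here:

* propensities below 2⁻³² are treated as zero (far below any biological
  rate) and live outside all groups;
* group sums and the total are maintained incrementally and rebuilt exactly
  (`math.fsum`) every 10⁶ updates to cancel floating-point drift;
* a rejection loop exceeding 10³ iterations — impossible with correct
  brackets — raises an internal-consistency error rather than looping.

A dependency graph maps each firing to the channels whose reactant (or
diffusion-source) entries changed; grouped diffusion channels store their
dependents per direction, since a hop touches only the source and the chosen
destination. Randomness comes from one Mersenne Twister (MT19937) generator
per run; replicate seeds are spawned from a root `SeedSequence`, so a run is
fully reproducible from (inputs, seed).

`run(t)` semantics: events are applied while the next event time is ≤ t,
then the clock is set to t (state between events is constant). Clamped
(species, location) pairs ignore count changes from events while still
driving propensities — the standard fixed-boundary-condition device; clamps
hold *counts* per location, which at fixed voxel volume is the same as
holding concentration. Injection of N molecules into a mesh compartment
distributes them multinomially with tet-volume weights.

## Geometry and meshes

Internal indices are 0-based and contiguous; importer proxies keep the
bijection to the file's own indices. Tets with volume below 10⁻¹⁸ of the
bounding-box volume are rejected at construction (the diffusion rates divide
by V). Quality metrics — radius-edge ratio (circumradius / shortest edge,
√6/4 ≈ 0.612 for a regular tet) and Aspect Ratio Beta (circumradius / 3 ×
inradius, 1 for a regular tet) — are report-only: a poor mesh still runs,
by design, since any internal tolerance would be arbitrary.

The box-mesh generator uses the Kuhn subdivision (six tetrahedra per cube
sharing a main diagonal). It is translation-invariant, hence face-conforming
across cubes, exactly volume-preserving, and — usefully for the stationary
birth–death test — yields equal-volume tets. Patch triangles must be mesh
faces bounding their inner (and, if given, outer) compartment.

## Voxel-size window

Both bounds come from one event-ratio criterion — about ten diffusion events
per event of the fastest reaction per voxel — evaluated for a regular
tetrahedron of edge `h`, whose total hop rate per molecule is
`4 × 9D/h² = 36 D/h²`:

* upper bound (continuous concentrations):
  `h_max ∝ sqrt(36 D / (10 r))` with `r` the per-molecule consumption rate
  of the fastest reaction;
* lower bound (discrete occupancy): a voxel holding one molecule of each
  reactant of a second-order reaction fires at `k/(N_A V(h))`; requiring ten
  hops per such firing gives `h_min ∝ k/(N_A D)`. First-order reactions do
  not constrain the lower bound (their rate does not grow as voxels shrink).

Each bound carries a single calibration constant fixed once so that the
reference parameter set (k = 100 /µM·s, [A] = [B] = 1 µM, D = 0.1 µm²/ms)
yields the (0.02 µm, 0.4 µm) window, i.e. roughly 100–10⁶ tets per µm³. The
constants are module-level and never adjusted per model; diagnostics expose
the uncalibrated criterion values. This is an explicit approximation with a
fixed functional form (√D upper, 1/D lower scaling), not a derivation from
first principles; for slower diffusion it predicts a window narrower from
both sides, consistent in direction and bracket with the reference numbers
but not a unique reconstruction of them.

## Validation suite: what is emulated, and at what size

The well-mixed harness runs five reaction systems and scores, at 110 fixed
measurement points, whether the closed-form mean lies in the 95% t-CI of the
replicate mean (Poisson pmf values per count bin for the stationary model,
with per-replicate bin frequencies as the replicated statistic). Frozen
parameters, all in a 1 µm³ compartment:

| model | parameters | points × replicates |
|---|---|---|
| first-order irreversible | N₀ = 1000, k = 1 /s, t ∈ [0.25, 5] s | 20 × 1000 |
| first-order reversible | A₀ = 600, kf = 0.4, kb = 0.2 /s | 14 × 100 |
| second-order, equal | N₀ = 1000 each, k = 10⁶ /M·s, t ≤ 1 s | 40 × 100 |
| second-order, unequal | A₀ = 1200, B₀ = 800, A and B at 10 times | 20 × 100 |
| production–degradation | λ = 20, k_deg = 1 /s, bins n = 12…27 | 16 × 100 |

For the second-order models the "analytic mean" is the deterministic closed
form; the stochastic mean deviates from it by O(1/N₀), so initial counts
(~10³) and maximum consumption (≤ ~65%) are chosen to keep that bias well
below the CI width — the comparison validates the solver, not the
deterministic approximation. All scored statistics are replicate means of
counts (or of count-bin frequencies), which are linear, so their t-CIs are
unbiased for the analytic targets; a per-replicate *ratio* statistic for
the unequal-reactant model was rejected because A − B is exactly conserved
there, making E[A/B] = 1 + Δ·E[1/B] Jensen-biased by a non-negligible
fraction of the CI width. A deliberate-fault control (all rates × 1.5)
collapses coverage below 50% and guards against a vacuously passing
harness.

Spatial cases run on box meshes with 0.25 µm voxels and D = 10 µm²/s, mean
of 10 iterations, profiles binned axially (or radially) with bins aligned to
the mesh slabs and concentration = Σ counts / (N_A Σ V) per bin:

* plane source, clamped boundary, constant influx (realized as a clamped
  precursor species P with a local P → P + A reaction) and a
  degradation–diffusion front in a 4 µm tube (aspect 16:1);
* a 3D point source in the central tet of a 2 µm cube, with comparisons
  excluded within two voxel edge lengths of the source — the source has
  finite volume, so early/near-source bins deviate by construction; the
  analogous end-slab bins are excluded in the 1D source cases.

All field solutions (image-series, erfc, ierfc-flux, erf front) are verified
against an independent Crank–Nicolson PDE oracle to < 0.5% in the tests, so
the simulator comparison is against a validated reference. The mesh-
resolution invariance check runs the reference second-order model on 162-
and 750-tet meshes (voxel edges inside the size window), 10 iterations each,
and requires the mean trajectories to agree within sampling error (mean
squared z < 4). These problem sizes — ~10³–10⁴ molecules, ~10⁵–10⁶ events
per case — are chosen so the full suite completes in a couple of minutes;
they emulate the study conditions at reduced replication, which widens CIs
but does not bias the comparisons. What passing does *not* show: fidelity on
highly irregular meshes near the window edges, surface-reaction-dominated
systems, or performance-scale behavior (millions of voxels).

## Known limitations

* Surface species do not diffuse laterally within a patch; surface–surface
  second-order kinetics need an explicit user-provided scaling.
* No approximate accelerations (tau-leaping) and no mixing of well-mixed and
  mesh compartments in one stochastic run.
* The event loop is pure Python: throughput is roughly 10⁵–10⁶ events/s,
  adequate for validation-scale problems, not for production neuroscience
  meshes.
* The deterministic solver integrates volume reactions only, with a fixed
  step (no adaptive control, no surface coupling).
* `find_tet` is a linear scan; fine for picking an injection site, not for
  bulk point location.
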