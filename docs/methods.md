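# Methods

This note documents the models behind `pbs4d`, the study conditions its
defaults encode, the design choices made where several readings were
defensible, and what the synthetic setup does and does not tell you about
real patients.

## Delivery-time model

Delivery of a spot list decomposes into four time components:

* **Beam-on**: `mu / beam_current` per spot instance.
* **Spot transitions**: the x and y scanning magnets move concurrently, so
  travel takes `max(|Δx|/vx, |Δy|/vy)`; a serial magnet preparation and
  verification time is added per transition, and the first spot of each
  layer incurs the preparation time alone. Scanning speeds are specified at
  the maximum energy (230 MeV) and scale inversely with beam momentum
  (`pc = sqrt(E² + 2E·m₀c²)`, m₀c² = 938.272 MeV): the magnets ramp at a
  fixed rate of field change, so lower-rigidity beams sweep faster.
* **MEE layer switches**: within a spill, switching to the next (lower)
  energy layer costs `mee_layer_switch_time` and retains
  `recapture_efficiency × L` of the unspent ledger `L`.
* **Spill changes**: refilling the synchrotron costs `spill_change_time`
  and resets the ledger to `max_mu_per_spill`.

The spill **ledger** works as follows. A spill opens with
`L = max_mu_per_spill` and layer counter `k = 1`. Delivering a spot
requires `L ≥ mu` (with 1e-9 relative slack so `n`-fold rescanned weights
summing back to the budget do not trip on the last bit) and decrements `L`.
At a layer boundary the spill continues as an MEE switch when `k` is below
the per-spill layer limit **and** the recaptured ledger still covers the
next spot; otherwise — and whenever the ledger cannot cover the next spot
mid-layer — the spill closes. Spots are atomic and never split across
spills (spot weights are far below the spill budget in realistic plans).
"Unlimited" MEE layers (the 2025B preset) means `k` never ends a spill.
Layers are delivered in strictly descending energy, the natural order for
decelerating extraction. Whether the physical control system applies
recapture once per switch or continuously, and whether magnet preparation
overlaps the layer switch, is not public; this ledger is one consistent
reading, and an independently coded event-walk oracle pins its behavior in
the tests. All timing arithmetic is double precision; hand-checked
timelines are asserted to 0.1 ms.

The timeline is an exact tiling of beam-on events and dead-time gaps from
the first beam-on (t = 0) to the last beam-off; BDT is last beam-off minus
first beam-on. No gap is emitted before the first spot so that the tiling
invariant holds exactly.

## Scaled layer rescanning

For rescan number `n`, every layer's spot sequence is replaced by `n`
consecutive repetitions of the original pattern, each instance carrying
`mu/n` — total MU is conserved exactly up to floating point (asserted at
1e-9 relative). Spot order within a pass is the original order (no
serpentine reversal between passes), no extra dead time is assumed between
passes beyond ordinary spot transitions, and the rescanned plan is a
persisted artifact that round-trips through the text plan format.
`validate_min_mu` checks instances against the 3 mMU planning constraint
and the 0.1 mMU hardware floor.

## Phantom, motion, and phases

The phantom is an analytic slab geometry voxelized on an isotropic 2-mm
grid: a 30-mm posterior soft-tissue wall (density 1.00 g/cm³), an 80-mm
lung-equivalent slab (0.26 g/cm³), an anterior tissue wall, and a 25-mm
soft-tissue sphere whose baseline center sits at 90 mm depth on the beam
axis. The beam enters posteriorly along +y. Water-equivalent depth is the
exact line integral of density (density ≈ relative stopping power) through
slabs plus the sphere chord, evaluated analytically at arbitrary points.

Target motion is sinusoidal, rigid, one-dimensional (superior–inferior,
perpendicular to the beam) with a 5-s period, discretized into 10 phases;
phase 0 is maximum displacement (cosine convention) and each phase's
geometry is frozen at its bin-center time `t_p = (p + 0.5)·T/10`. The
accumulation reference is the 50% phase (index 5). A spot instance belongs
to the phase containing its beam-on midpoint; whole spots are never split
across phases.

**Motion amplitude convention.** The "10-mm amplitude" of the study
conditions is read as the amplitude of the programmed waveform
`A·cos(2πt/T)`, i.e. a 20-mm peak-to-peak excursion — the waveform
convention of common dynamic-phantom controllers, and a representative SI
excursion for lower-lobe lung SBRT. The alternative peak-to-peak reading
(±5 mm) is available via `MotionModel(amplitude_is_peak_to_peak=True)`;
under it the synthetic case's interplay is weak enough that rescanning is
barely needed on any machine generation, which is why the half-excursion
reading is the default study condition.

## Pencil-beam dose engine

Per spot, dose is `mu · C · d(WET; E) · G₂(r; σ(WET))`:

* Range–energy: `R = 0.0022·E^1.77` cm of water.
* Depth dose `d`: a rising plateau (0.30 at the surface to 0.75 at the
  peak) under an erfc distal sigmoid, plus a unit Gaussian peak at `z = R`
  with width `sqrt(3² + (0.012·R)²)` mm (intrinsic smearing plus range
  straggling), hard-clipped to zero beyond `R + 5 mm`. The argmax sits
  within one 2-mm grid step of `R`. The curve is a pluggable analytic
  stand-in: interplay conclusions rest on spot granularity and timing, not
  on Bragg-curve fidelity, and no TPS beam model is reproduced.
* Lateral: a 2-D Gaussian of unit planar integral with
  `σ² = σ_air(E)² + (0.35·√WET)²` mm; `σ_air` interpolates linearly from
  6 mm at 71.3 MeV to 2 mm at 228.8 MeV (the commissioned energy range).
  Gaussians are truncated at 4σ.
* Calibration `C` (Gy·mm²/MU) is fixed at plan generation (below), so the
  absolute protons-per-MU chain is never needed. Dose is reported in
  Gy(RBE) with the constant RBE of 1.1 absorbed into the calibration.

Nuclear halo, aperture scatter, off-axis heterogeneity corrections along
slanted paths, and variable RBE are out of scope. Linearity and exact
superposition are asserted to 1e-12 relative.

## Synthetic plan generation

Energy layers are placed so Bragg peaks tile the water-equivalent depth
band of the target over all phases (≈5-mm water spacing; 6 layers,
72–92 MeV for the default phantom). The lateral lattice is a 5-mm-pitch
grid covering the IGTV silhouette (a capsule: the sphere swept along the
motion) plus one spot-spacing margin.

Spot weights minimize the squared deviation from a uniform per-fraction
prescription (10 Gy) over a strided voxel subsample of two scenario
groups: the IGTV on the reference-phase geometry, and the GTV of each of
the 10 phases on its own geometry, solved by nonnegative least squares.
The per-phase blocks are a lightweight geometric stand-in for the robust
optimization clinical plans of moving targets receive; without them a plan
tuned to one geometry misses the target's depth/position changes in other
phases, and the phase-averaged (well-rescanned) dynamic dose then differs
from the static reference by more than the 2% evaluation band — no rescan
number would ever be "adequate", contradicting the physics the package is
built to show.

The fitted weights are normalized so the static reference-phase IGTV D95
equals the prescription exactly; the calibration constant is then chosen so
the plan totals 180 MU — a realistic monitor-unit scale for a 10-Gy(RBE)
lung fraction at ~10⁹ protons per MU, and one that gives the three presets
no-rescan delivery times (≈44/19/11 s) with the time structure reported
for this machine family. Spots below 3 mMU are pruned and the
normalization repeated. Generation is deterministic.

## D4DD reconstruction and metrics

Per fraction: simulate the timeline, draw a uniform random starting phase,
split spot instances into phases, compute each phase's dose on its
geometry, map it to the reference phase by translating the field by minus
the phase's relative target displacement, and sum. For this rigidly
translating phantom the inverse rigid translation is the exact counterpart
of the deformable accumulation a clinical workflow would use; on the grid
path it is applied with trilinear resampling, and in the influence-matrix
fast path analytically (the phase dose is evaluated directly at the
translated voxel positions, so no resampling error enters). Note the whole
field is translated — exact for the moving insert, approximate for the
static lung shell; healthy-lung metrics inherit a ≤ one-excursion blur.

A course is 5 fractions with independent uniform starting phases from a
seeded generator (all randomness in the pipeline lives here). Accumulated
dose is the voxelwise sum. Metrics: D95 and D5 are interpolated
percentiles of the structure's voxel dose distribution (dose exceeded by
95%/5% of voxels), D5/D95 the homogeneity ratio, Dmean the mean, V20 the
percent volume at ≥ 20 Gy(RBE). Dynamic GTV metrics are evaluated on the
reference-phase GTV and compared to the static reference plan's IGTV
values (computed on the reference-phase geometry, machine-independent);
healthy lung (lung − IGTV) is reported at course scale.

Worst-/best-case scenarios follow the ×5 rule: the selected fraction's
dose-type metrics are scaled by the fraction count, with D5/D95 taken from
that fraction unscaled. The primary ranking is by fraction GTV D95 value
(worst = coldest); ranking by distance from the per-fraction reference is
also exposed, since a fraction can be "worst" by being hot. Note that
`worst-case ≤ accumulated` holds throughout our sweeps, but
`accumulated ≤ best-case` does not: fractions with disjoint sub-5%-volume
cold spots accumulate to a D95 above five times any single fraction's.
That asymmetry is the start-phase-randomness smearing that makes
single-scenario interplay evaluation produce false negatives (a lucky
fraction looks fine) and false positives (the ×5 worst case keeps failing
after the accumulated dose is acceptable), and the sweep reports both.

## The rescan sweep and its fast path

The sweep runs every (machine preset, rescan number) cell for
n ∈ {1, 4, 6, 8, 10, 12, 16, 20, 24} with 20 seeded courses per cell. Two
exact structural facts make it fast: the timeline is deterministic given
plan and machine (randomness only shifts the starting phase), and phase
assignment shifts cyclically with the starting phase — so each cell has
only 10 distinct fraction doses. Because dose is linear in MU and the
geometry rigid, the mapped dose restricted to a fixed evaluation voxel set
is a per-phase linear map of the per-spot MU split; these influence
matrices are precomputed once (float32, full reference-phase GTV plus the
healthy lung strided 2× per axis — lung DVH statistics are smooth and the
stride only trims memory) and each cell reduces to a handful of small
matrix products. A dedicated test pins the fast path to the full-grid
reconstruction (GTV D95 and means to 1%, lung mean to 2%). The full
default sweep runs in a few seconds; the evaluation grid is 2 mm
throughout.

Pass/fail per cell uses the study's criterion: both the accumulated GTV
D95 and D5/D95, as medians over the 20 courses, within ±2% of the static
reference (ratios to reference, not absolute Gy). The "adequate" rescan
number is the smallest swept n that passes.

## Known limitations

* Regular sinusoidal motion only; patient breathing is irregular, so
  adequate rescan numbers here do not transfer to any clinical setting.
* The phantom is rigid and homogeneous slabs; no ribs, no hysteresis, no
  3-D motion, no CT calibration chain. Absolute dose values are not
  comparable to any TPS; only relative/qualitative behavior is meaningful.
* The synthetic field is small (165 spots, 6 layers). Per-layer delivery
  times relative to the breathing period land in the physically relevant
  regimes, but the 2015 preset's spill cadence (20 MU budget + 2-s refill
  ≈ 4.5 s against the 5-s cycle) resonates with the motion and makes the
  slow machine's single fractions more variable than the fast machine's —
  an effect of these operating parameters on a small field, worth keeping
  in mind when comparing across-fraction spreads between presets.
* Worst/best-case scenario ordering relative to the accumulated course is
  empirical, not guaranteed, for percentile metrics (see above).
* The evaluation of lung metrics in the fast path subsamples the lung; the
  full-grid path does not.
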