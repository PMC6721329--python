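# Methods

This note records the models, conventions and design choices behind
`spinechange`, in the order the pipeline applies them.

## Data model and pair extraction

A snapshot is one frame of five forward-tilt angles τ₁…τ₅ (degrees,
sensor 1 lowest on the lumbar spine), with user id, position
(standing / sitting / hinging), guidance label (unguided / guided) and a
timezone-naive timestamp at second resolution. Angles must be finite with
|τ| ≤ 180°. User ids are opaque: the pipeline never interprets them.

Pair extraction keeps, per user and position, the **earliest unguided**
snapshot (t0, the most unlearned realization) and the **latest guided**
one (t1, the current best guided imitation) — exactly one pair even when
more snapshots exist. Groups lacking either kind are skipped and counted.
Two edge rules are ours: timestamp ties break by input-file order (stable
and reproducible), and a group whose latest guided snapshot precedes its
earliest unguided one is skipped, since a pair with t1 < t0 has no
before/after reading. Database summaries report per-position and overall
pair counts and min/mean/median/max unguided-to-guided gaps, formatted
`d hh:mm:ss`.

Input is delimited text (CSV by default). Foreign schemas are adapted
through an explicit column map rather than guessed.

## Spine-curve model

The wearable's curve model itself is not published in full detail, so the
reconstruction here is the simplest model consistent with its stated
structure — six 2D points joined by arc segments, fixed segment length,
first sensor at the origin:

* tangent direction at tilt τ is (sin τ, cos τ); positive τ leans
  anteriorly (+x), consistent with lordotic standing values (sensor 1
  ≈ +20°, sensor 5 ≈ −12°);
* consecutive sensors are joined by a **constant-curvature arc of arc
  length L** whose tangent angle varies linearly from τᵢ to τᵢ₊₁. Its
  chord has the closed form L·sinc(Δ/2)·(sin m, cos m) with
  Δ = τᵢ₊₁ − τᵢ, m the mean angle, sinc(h) = sin(h)/h — exact for all Δ
  and numerically continuous through the straight-segment limit Δ → 0
  (no branch, no cancellation);
* the base point P₀ extends straight down from P₁ by L along sensor 1's
  tangent, since no tangent is defined below sensor 1;
* P₁ = (0,0) by construction. L defaults to 1 model unit; every
  downstream quantity is covariant in L (lengths scale, directions are
  invariant), so the unit choice is immaterial to clustering.

Degrees at the file boundary, radians internally.

The *offset spine shape* of a pair feeds the per-sensor differences
δᵢ = τᵢ|t1 − τᵢ|t0 through the same reconstruction; each point's
x-coordinate gets a sign annotation with zero tolerance 10⁻⁹ model units
('o' effectively marks exact zeros only). Points keep curve order P₀…P₅,
which coincides with increasing y whenever |δ| < 90° — always true for
realistic posture change.

## Change features

For j ∈ {0,2,3,4,5}: lⱼ = ‖Pⱼ|t1 − Pⱼ|t0‖₂ and dⱼ = (Pⱼ|t1 − Pⱼ|t0)/lⱼ.
P₁ is pinned and excluded. Below lⱼ < 10⁻⁹ the direction is undefined and
both are zeroed. The flattened 15-vector layout is fixed
(d₀ₓ,d₀ᵧ,…,d₅ᵧ,l₀,…,l₅) so saved feature matrices are portable.

Note a structural property that matters later: the dⱼ are **unit**
vectors, so when a subpopulation's true displacement at some level is
near zero, the observed direction there is sign-unstable and contributes
O(1) variance regardless of how small the displacement is. The base
level j = 0 is the only level where this can happen in practice, because
displacement at higher levels accumulates all lower sensors' changes.

## Embedding

Features are mean-centered but **not standardized** by default: direction
components are bounded by construction and length components are of
comparable magnitude at L = 1 (a `standardize` flag covers other
regimes). PCA keeps the smallest n whose cumulative explained-variance
fraction reaches the threshold (default 0.95; threshold 1.0 keeps the
rank). t-SNE (scikit-learn) maps the scores to 2D at perplexity 30 with
optimizer settings left at implementation defaults, which only affect
convergence rate; the random seed is mandatory and recorded, with the
map's provenance, in the run manifest. A diagnostic
`conditional_similarities` function exposes the per-point Gaussian
bandwidth calibration (2^entropy = perplexity) that the optimizer applies
internally.

## MST clustering

The map's complete Euclidean graph is reduced to its minimum spanning
tree (exact Kruskal; N is at most a few hundred, so no approximate
neighbor structures), and the k−1 heaviest tree edges are cut; connected
components are clusters. Ties — rare with real-valued coordinates but
possible — prefer the lexicographically smaller (i,j) index pair both
when growing and when cutting, so runs are reproducible. Cluster ids
0..k−1 are assigned by descending component size (ties: smallest member
row index). k is a per-position setting (standing 4, sitting 4, hinging
6 by default, overridable); the package deliberately offers no automatic
k selection.

## Cluster profiles

Per cluster and point level, the member x-coordinates are reduced to the
1/25/50/75/99 percentiles (linear interpolation between closest order
statistics — chosen so bundle tables are bit-reproducible) plus +/o/−
sign tallies. Three machine-readable flags capture the geometric
separations bundles show visually: the unanimous base-point sign (or
none), the sign of the median x at the top level, and the crossing level.
When median signs alternate more than once, the flag reports the lowest
sign change plus a multiplicity count rather than guessing a single
crossing.

## Angle statistics

Descriptive statistics use sample SD (n−1) and the same percentile method
as the bundles. The per-sensor guided-vs-unguided comparison is the
classical two-sided Wilcoxon signed-rank test: zero differences
discarded, midranks on |d|, exact null distribution of W⁺ up to effective
n = 25 via an integer generating-function convolution (doubled ranks make
tied midranks integral, so the exact path is valid with ties), otherwise
a normal approximation with tie-corrected variance and continuity
correction. The n = 25 crossover is an implementation choice; the exact
and approximate p-values agree within 0.01 there. An all-zero sensor
yields p = 1 with a degeneracy warning instead of an error. p-values
below 10⁻⁶ are a display convention ("<1e-06"), not a test parameter. No
multiple-testing correction is applied across sensors or positions;
report headers say so.

## Synthetic databases

The generator's defaults are the package's study conditions:

* baseline t0 angle distributions: Gaussian per sensor with the observed
  per-position unguided means/SDs (standing sensor 1: 19.6° ± 10.3°, …);
* three default change archetypes in trainer vocabulary, as per-sensor
  mean-change templates (degrees):
  `anteversion_loss` (−6,−3,0,2,3), `sway_straightening` (−5,2,5,8,9),
  `anteversion_gain` (8,5,2,4,5), equal weights, change SD 1.0° per
  sensor;
* measurement noise 0.5° per snapshot; timestamps uniform over a year
  with exponential unguided-to-guided gaps (2-day median, 30-minute
  floor), matching the magnitudes of real pair databases.

Every template keeps |mean sensor-1 change| ≥ 5°. This is deliberate: the
base-point feature is a unit direction, so a template with near-zero
sensor-1 change would scatter its users across both base-sign half-spaces
and inflate the within-archetype spread far beyond the nominal change SD,
making the planted labels unrecoverable *by any method that respects the
feature geometry* — the pipeline would instead split that archetype by
base sign, which is precisely the separation logic the bundles encode.

At the defaults the minimum between-template separation (≈10.5°) is about
4× the within-archetype spread norm (change SD 1.0° plus noise on both
snapshots, ≈1.22° per sensor, ≈2.7° in norm) — realistic, and recovery is
already near-perfect. The recovery and stability checks construct the
generator at a slightly cleaner condition (change SD 0.8°, noise 0.3°,
≈5.2× separation) so that the claim being tested — separation at least
five times the within-archetype spread — is actually met by the data.

A contamination mode mixes in a fraction of 5×-wider change draws,
breaking normality the way real angle data does, for exercising the
nonparametric test. What the generator does **not** emulate: real spines'
non-Gaussian baseline asymmetries, within-user correlation across
positions, repeated snapshots per user, or any biomechanical coupling
between sensors. Passing recovery tests therefore show the pipeline
separates angle-space change mixtures of this strength, not that real
posture data contains such clusters.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at 120 users (40 per
archetype), perplexity sweeps over {25,30,35,40}, 200 brute-force MST
instances at N = 12, 100 sign-enumeration Wilcoxon draws at n ≤ 12 and a
2000-replicate null calibration at n = 100 — sizes chosen so the whole
suite completes in well under a minute while keeping every estimate's
Monte-Carlo error far below its acceptance margin. Arc geometry is
verified against Simpson integration of the tangent field (2001 nodes per
arc) over a 1509-pair angle grid with |Δ| ≤ π; agreement is at the 10⁻¹⁴
level, far inside the 10⁻⁶·L contract.

## Known limitations

* The arc parameterization is a documented stand-in for the wearable
  vendor's unpublished model; downstream analysis is invariant to smooth
  reparameterizations, but absolute point coordinates are model-specific.
* k per position is fixed by configuration, not selected from data.
* The Wilcoxon exact path is O(n · Σ2rᵢ) in memory/time and is capped at
  n = 25 by default.
* The CLI's `profile` command reconstructs a `Clustering` from a labels
  file and so reports no cut-edge metadata.
* Real deposited databases are supported through the column-mapping
  reader, but no schema autodetection is attempted.
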