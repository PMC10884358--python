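# Methods

This note documents the models and procedures `msx` implements, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical conventions.  It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Map canonicalization

A scalp map is stored canonical: average-referenced (zero mean over
channels) and unit L2 norm.  "Unit global field power" and "unit vector
length" differ only by √n_channels; we adopt unit L2 norm, under which the
GFP of every canonical map is the montage constant 1/√n.  All similarity
quantities downstream depend only on map direction, so the choice is
internal.  Average referencing uses the plain mean over all channels — no
channel exclusion, no re-referencing options.  A map that is constant
across channels is degenerate (zero after average referencing) and
rejected with a dedicated error.  Electrode coordinates are taken as
head-centered and are never re-centered or sphere-fitted: silently
re-centering a montage the user supplied would corrupt it; users who want
a best-fit sphere can apply one before import.  Whether imported maps were
already canonical is recorded per map (`input_was_canonical`) because
source files in the wild store maps at arbitrary scales.

## Spherical-spline resampling

Cross-montage comparison interpolates maps with the classical spherical
spline: kernel g(x) = (1/4π) Σ_{n=1..N} (2n+1)/(nᵐ(n+1)ᵐ) Pₙ(x), fitted by
the bordered linear system with the coefficients constrained to sum to
zero, evaluated at the target electrodes.  Defaults:

* **m = 4** — the standard spline order for scalp potential maps; smaller
  m gives visibly stiffer surfaces.
* **N = 50** — series terms decay like n^(1−2m) = n⁻⁷ at m = 4, so the
  tail beyond 50 terms is far below 1e−10 (verified against N = 200 in the
  tests).
* **ridge = 1e−8** — a tiny diagonal regularization protecting against
  nearly coincident electrodes.  With ridge 0 the spline interpolates its
  nodes exactly; with the default it still reproduces constants exactly
  (the constant term is unpenalized).

All three are exposed in `SplineConfig` and in the CLI YAML config
(`spline.m`, `spline.n_terms`, `spline.ridge`).  Electrode positions are
projected to the unit sphere per electrode (each position divided by its
own length) — deterministic and montage-agnostic.  Angles come from
clamped dot products of the projected positions.  Because fit and
evaluation are both linear, each montage pair is compiled once into a
single transfer matrix and cached.

When two maps live on different montages, the map from the montage with
*more* electrodes is resampled onto the montage with fewer — information
can only be lost, never invented.  For equal channel counts with different
geometry the second montage is resampled onto the first; this introduces a
formal order dependence that is bounded by spline fidelity.  Resampled
maps are re-canonicalized, since interpolation preserves neither the zero
mean nor the norm exactly.

Fidelity: a low-order smooth field (spherical harmonics up to degree 2)
survives a 64→19→64 round trip with shared variance ≥ 99.9%; at degree 3
the 19-channel montage no longer carries enough information for the
up-sampling direction and round-trip SV drops to ≈ 98%, although the
64→19 *down*-sampling—the direction actually used for comparisons—still
agrees with the directly evaluated field at SV ≥ 99.9%.  The fidelity
tests therefore state degree-2 smoothness; callers comparing very
high-frequency topographies across sparse montages should expect larger
losses.

## Similarity, dissimilarity, MDS

For canonical maps, the spatial Pearson correlation over channels reduces
to the dot product r = uᵀv.  Shared variance SV = 100·r² is the similarity
reported everywhere; it is invariant to polarity, scaling, and argument
order.  The global map dissimilarity uses the polarity-folded form
d = √(2(1 − |r|)), equal to min(‖u−v‖, ‖u+v‖) — consistent with SV and
with the microstate convention that a map and its negation are one state.
Whether signed r would be more faithful to older dissimilarity usage is
genuinely open; the signed variant (d = ‖u−v‖) is available behind
`polarity_invariant=False`, with |r| the default.

The embedding is classical (Torgerson) MDS: double-center −D²/2,
eigendecompose, scale eigenvectors by √λ.  It is deterministic — no
iterations, no seed — and each axis's sign is fixed so its
largest-magnitude coordinate is positive.  With polarity folding active
(|r|), the dissimilarities are distances on a projective quotient rather
than a Euclidean space, so slightly negative eigenvalues are expected for
atlases with genuinely opposite-polarity map pairs; when all pairwise
correlations are positive, D is exactly Euclidean and the spectrum is
non-negative (tested).

## Meta-microstate clustering

Items are the studies' template maps (one vector each) resampled to a
user-chosen common montage — not EEG samples, so GFP-peak selection does
not apply.  The default common montage is the built-in idealized
19-channel 10–20 set, a reasonable lowest common denominator; any montage
can be supplied.  Weights are the studies' subject counts, applied inside
the scatter matrix S_k = Σ wᵢxᵢxᵢᵀ rather than by item replication (exact
and fast; the equivalence with replication is property-tested).

The modified k-means alternates the polarity-invariant assignment
Lᵢ = argmax_k (xᵢᵀt_k)² (ties to the lowest class index) with the update
t_k ← dominant eigenvector of S_k, which is the global maximizer of the
class's weighted explained variance.  Convergence: assignments unchanged,
or relative objective change < 1e−9, or 500 iterations.  An emptied class
is reseeded with the currently worst-fit item.  Initialization draws K
distinct items without replacement per restart; 50 restarts by default.
Restart count, initialization, and tolerances are not dictated by the
method itself — the values here were chosen for determinism-in-practice
on atlas-sized problems (tens to hundreds of items) and are all exposed.
The objective is non-decreasing in K and invariant to polarity flips of
items or class maps.  Dominant eigenvectors come from a symmetric
eigendecomposition of the n_channels × n_channels scatter; their sign is
fixed so the largest-magnitude element is positive.

Solutions are computed for K = 4…7 by default (the range in common use).
Each K draws an independent child seed from the run seed, so changing the
range does not perturb other solutions.  Classes are aligned across K by
maximum-total-shared-variance one-to-one matching (Hungarian algorithm)
of solution K+1 against solution K, with the unmatched new class appended
last; the smallest-K solution is ordered against a user-supplied reference
set if given, else by descending assigned weight.  A manual permutation
override is accepted and recorded.  No automatic selection of the "right"
K is attempted — the explained-variance-per-K profile is reported and the
choice is left to the user.

## Backfitting and commonality

Backfitting study maps assigns each map to argmax_k SV(map, t_k), ties to
the lowest class.  Backfitting EEG canonicalizes each sample (average
reference, unit norm) and applies the same polarity-invariant argmax; by
default *every* sample is labeled — no GFP-peak restriction and no
temporal smoothing, both available as off-by-default options
(`min_gfp`, `smooth_half_width`) since whether the original analyses
excluded low-GFP samples is unknown.  A zero-variance sample inherits the
previous sample's label (class 0 if first) and is counted in a degenerate
tally.  Assignment is invariant to per-sample positive rescaling and to
polarity flips of the data.

The commonality matrix between a K_from series a and a K_to series b is
C[j,k] = 100·#{t: a_t=k ∧ b_t=j}/#{t: a_t=k}: columns are the classes of
the solution named first, and each column over a non-empty source class
sums to exactly 100%.  Empty source classes give zero columns and are
flagged.  Class labels are 0-based integers internally (arrays index
directly); the CLI's findings query takes 1-based class numbers, matching
how solutions are labeled in output.

## Synthetic fixtures

The generators emulate the *structure* of a multi-study template-map
collection and of microstate EEG, not its biophysics:

* **Montages** — the idealized 10–20 set is constructed geometrically
  (circumferential ring at azimuths ±18/54/90/126/162°, midline and
  coronal electrodes at 45° inclination, F3/F4/P3/P4 as great-circle arc
  midpoints) on the unit sphere.  Other channel counts use a seeded
  golden-ratio spiral on the upper hemisphere, which guarantees good
  angular separation.
* **Prototypes** — smooth random fields built from real spherical
  harmonics up to degree `smoothness` (default 3), stored as coefficients
  so the same field evaluates consistently on any montage.  Candidates
  are drawn sequentially and accepted only if pairwise shared variance
  with all accepted fields stays below 25%, which also makes draws nested:
  the K+1 draw extends the K draw, the construction the nested-solution
  commonality analyses rely on.
* **Atlases** — each study map is its prototype rotated on the map
  hypersphere by a *fixed* angle (default 0.3 rad) toward a random
  orthogonal zero-mean direction, so the expected shared variance with
  the prototype is exactly 100·cos²(0.3) ≈ 91.3% (tested).  Subject counts
  are drawn uniformly from 10–50; montages cycle through 19/32/64
  channels; ground-truth classes are recorded in study metadata.
* **EEG** — a piecewise-constant label sequence with geometric
  (memoryless) run lengths (default mean 80 ms at 250 Hz), per-sample
  random polarity and positive amplitude times the state's prototype,
  plus spatial white noise scaled per sample so the GFP signal-to-noise
  ratio equals `snr` (default 4).  Data is average-referenced.

Not emulated: volume-conducted lead fields, spatially correlated or 1/f
noise, artifacts, GFP modulation within states, inter-subject topography
variability within a study.  Passing tests therefore demonstrate the
correctness of the algorithms under clean cluster structure, not
performance on real recordings, where lower SNR and correlated noise will
reduce recovery and commonality values.

The commonality dominance checks generate EEG from the shared (nested)
prototype subset: when the data also contains the extra state, its samples
necessarily scatter across the columns of the smaller solution and pull
some diagonals down — the "all but one class stable" pattern rather than
an all-classes bound.  Both situations are exercised in the tests; the
quantitative >90% diagonal bound is asserted in the shared-subset design
where it is well-posed for every class.

Problem sizes used by the test suite and acceptance script — 20 studies ×
5 maps for clustering recovery (5 atlas seeds, 50 restarts), 60 s of
250 Hz EEG for backfitting, 64→19-channel spline oracles — were chosen as
the smallest sizes at which the measured quantities are stable to well
within the asserted margins; the whole suite runs in well under a minute.

## Findings database

Effects are normalized to direction ∈ {More, Less, NoFinding} × parameter
∈ {Duration, Occurrence, Contribution, GEV, CurrentDensity, Other(text)},
the vocabulary observed in published findings tables, with free text
preserved verbatim for the Other escape and for contrasts.  NoFinding
rows must have empty contrast and parameter; non-NoFinding rows require
both.  Queries are pure functions of (atlas, selection): results are
deterministically sorted by (study, map, parameter, contrast, direction).
A meta-class query is definitionally backfit-then-select, so the K
per-class tables partition the atlas's maps.  CSV is the canonical export
(bit-stable, diff-able); spreadsheet formats can be produced from it.

## Known limitations

* Spline resampling assumes a spherical head and electrode directions
  that are meaningful from the head center; strongly non-spherical
  montages should be sphere-fitted by the user first.
* The equal-channel-count, different-geometry comparison is order
  dependent (second montage resampled onto the first) within spline
  fidelity.
* Modified k-means is a local optimizer; the restart default makes
  repeated runs agree in practice on atlas-sized problems but carries no
  global-optimality guarantee beyond the small instances checked
  exhaustively in the tests.
* MDS with polarity folding is a projection of a quotient space; distances
  between near-orthogonal maps with ambiguous polarity are mildly
  distorted.
* The findings vocabulary is intentionally small; anything outside it
  lands in Other(text) untyped.
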