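# Methods

`nucleoid3d` reconstructs the spatial organization of a small circular
bacterial chromosome from binned Hi-C contact counts and relates that
organization to transcription.  This note documents the models the
package implements, the parameters that matter, what the synthetic-data
generator emulates, and the numerical choices made where the design was
genuinely open.

## Contact matrices and iterative correction

A contact map is a symmetric `n x n` matrix `M(i,j)` of contact counts
between genomic bins on a circular genome (bins are 0-based, half-open,
and the final partial bin is kept: 816,394 bp at 10 kb gives 82 bins, at
3 kb gives 273).  Genomic distance is always circular,
`d(i,j) = min(|i-j|, n-|i-j|)`.

Read pairs are classified before binning: pairs on the same or
circularly adjacent restriction fragments facing inward are dangling-end
or re-ligation (non-ligation) products, remaining same-fragment pairs
are self-ligation circles, and only the remaining valid products are
pooled.  The class names are standard; the exact rule table (inward
beats same-fragment where the two overlap) is this package's choice and
matches common Hi-C practice.

Iterative correction (ICE) repeats the multiplicative update

    m_ij <- m_ij * T / (r_i * r_j)

with `T` the grand total and `r_i` the bin totals, until the maximum
relative deviation of bin totals from their mean is below 1e-5 (default;
`max_iter` 2000 because the multiplicative form converges slowly on
high-dynamic-range maps).  Zero-total bins are auto-blacklisted with a
warning.  After convergence the scores are rescaled to mean 1 over
usable off-diagonal cells so magnitudes are comparable across maps; this
rescale also makes the operation exactly idempotent.  Blacklisted bins
keep their rows (indexing is stable) but are excluded from the update
and all downstream statistics.

Control-library filtering zeroes cells, among a user-supplied set of
affected bins, that lie at circular distance >= 2 from the diagonal and
whose depth-normalized control value exceeds a quantile (default 0.99)
of the control's off-diagonal values.  The quantile is explicit
configuration: the published procedure names only the affected-bin list
and the off-diagonal rule.

The matrix-modelling-potential (MMP) score combines matrix size, the
number of eigenvalues exceeding the spectral background of shuffled
matrices, and the skewness/kurtosis of z-scores of log10 contact values,
through a configurable linear map clipped to [0, 1].  The combination
coefficients of the original score are defined in external work and are
not reproduced here; the defaults in `MMP_WEIGHTS` are this package's
own calibration, chosen so that the spectral term (the only component a
random shuffle destroys) dominates.  Treat absolute MMP values from this
package as comparable only to each other.

## Restraint-based 3D modelling

Each bin is a particle of radius `bin_size * scale / 2` (defaults:
scale 0.0201 nm/bp, so 100.5 nm at 10 kb).  Restraints are harmonic:

- consecutive circular particles: equilibrium at the sum of their radii;
- pairs whose z-score (of log10 positive normalized frequency, computed
  over non-adjacent usable pairs) exceeds the upper cutoff (-0.2):
  attraction at a distance interpolated linearly in z between the
  proximal distance (`maxdist`, 250 nm) at the cutoff and the sum of
  radii at the maximum z;
- pairs below the lower cutoff (-0.6), including zero-frequency pairs:
  a one-sided lower bound at `maxdist` (penalized only when closer);
- pairs between the cutoffs: unrestrained.

The log10 z-score space for the cutoffs and the linear interpolation are
package choices (monotone and bounded; the published cutoffs are applied
to an unprinted transformed scale).  Force constants default to 5
(adjacent) and 1 (attract/lower bound) in consistent arbitrary units.

Sampling is Monte-Carlo simulated annealing from uniform random
coordinates in a `maxdist` cube: geometric cooling (60 temperatures,
T 1e4 -> 1, three single-particle Gaussian moves per particle per
temperature, step shrinking with sqrt(T)), followed by a deterministic
local quench (L-BFGS on the same objective) that finishes the schedule's
zero-temperature limit.  The annealing stage provides basin diversity —
including the two mirror-image families a chiral restraint set admits —
and the quench gives accurate minima (a single attract pair reaches its
equilibrium distance to within 1%).  Every model derives its random
stream from a master seed and its run index, so ensembles are
bit-reproducible and independent of execution order.

The `n_keep` lowest-penalty models (defaults 1,000 of 5,000; the
analysis scripts use 100 of 500 to keep desk-scale runtimes) are
clustered by coordinate RMSD after Kabsch superposition restricted to
proper rotations, so mirror images separate; `allow_reflection=True`
merges them.  The tree is cut at half the maximum merge height, with an
absolute floor of 1% of the mean radius of gyration so ensembles of
near-identical (or achiral) conformations form one cluster.  A cluster's
centroid is the member closest to the aligned mean coordinates.

Ensemble geometry per model: length = largest inter-particle distance,
width = twice the radius of gyration, volume = prolate ellipsoid
`(4/3) pi (L/2) (W/2)^2`.  Medians are taken over per-model values — the
median volume is a median of volumes, deliberately not the ellipsoid
volume of the median length and width, which is a different (larger)
number.  The model contact map is the fraction of models in which two
particles are closer than a cutoff; the default cutoff (225 nm) is the
midpoint of the attract equilibrium range under the default
configuration, i.e. the distance scale the restraints themselves define
as "in contact".

## Domain detection

Chromosome interaction domains (CIDs) are called on the raw
high-resolution map after a single ICE cycle.  The model: counts in the
band of the first 20 diagonals are Poisson with mean
`alpha_k * E(d)` inside domain k, where `E(d)` is the genome-wide
expectation at circular distance d and `alpha_k` a free per-domain
intensity; cells spanning two domains keep `alpha = 1`.  A dynamic
program maximizes the total log-likelihood gain over segmentations with
a BIC penalty of `0.5 * bic_multiplier * log(n_cells)` per domain
(ties broken toward the earliest split).  The origin bin is a free
border of the circular genome, so the number of domains equals the
number of borders.

Two numerical choices matter:

- **Expectation**: `E(d)` defaults to the empirical per-distance mean of
  the working matrix (`decay_fit="means"`), the same expectation the
  density definition uses.  A pure power-law fit (`"powerlaw"`) is
  available but is biased when block structure modulates the distance
  profile, which degrades border recovery on maps with strong domains.
  Both are realizations of the same decreasing-expectation Poisson
  model.
- **Scale invariance**: the working matrix is rescaled to a reference
  mean of 10 per banded cell before the likelihood, so multiplying the
  input by a positive constant cannot change the segmentation.

Border confidence (1-10) counts the geometrically spaced penalty levels
(10 multipliers from the default to 10x) at which the border persists in
the optimal segmentation; the origin border is structural and scores 10.
The published confidence scale is reproduced in spirit — its exact
construction is not printed.  `min_domain` defaults to 3 bins (9 kb),
admitting the smallest reported treated-cell domain.  Increasing the
penalty multiplier never increases the border count.

Domain density is the sum of within-domain contacts divided by the sum
of per-distance average contacts over the same cells; the whole genome
as one domain has density exactly 1.  Because the per-distance average
absorbs whatever boost is common to most of the genome, a planted boost
is read off cleanly as the *ratio* of boosted-block to background-block
densities (the generator validation uses an alternating-boost design for
exactly this reason), and density comparisons are made on raw maps —
balancing partially absorbs block-level intensity into bin visibilities.

Border alignment across segmentations groups borders within a tolerance
(default 1 bin, circular).  A border counts as conserved when at least
`max(2, ceil(k/2))` of the k segmentations carry it — the floor of 2
keeps the two-replicate case meaningful.  The alignment null test
redraws each segmentation's border positions uniformly (conserving their
number) and reports the upper-tail empirical p-value.  Two segmentations
share a conserved domain when both its flanking borders match within
tolerance.

## Border feature tests

A domain border is two bins: the last bin of the preceding domain and
the first of the following one (d domains on a circle give 2d border
bins).  Feature enrichment or depletion is tested by a circular-shift
permutation: each permutation rotates the entire border set by one
uniform random offset, preserving domain number and sizes exactly; the
p-value is the fraction of null statistics >= (or <=) the observed
border mean (sum mode available; the published statistic's choice
between the two is not stated).  The plain ratio estimator is the
default; `plus_one` enables (k+1)/(N+1).  Under a track independent of
the borders the p-values are approximately uniform (checked by a
200-dataset KS suite).

Convergent / divergent junction tracks classify adjacent gene pairs by
strand ((+,-) convergent, (-,+) divergent), marking the bin of the
junction midpoint; circular genomes include the wrap-around junction,
and overlapping genes use the overlap midpoint with a logged note.

## Co-expression

The co-expression tendency of genes g, h over all unordered sample
pairs (s, t) is `(concordant - discordant) / total`, where a pair is
concordant when `(g_s - g_t)(h_s - h_t) > 0`.  Ties count to neither
side but remain in the denominator, so constant profiles score 0 and
|value| <= 1.  The implementation is a sign-matrix product; tests verify
exact equality with brute-force pair enumeration.  The Pearson matrix is
the drop-in alternative; both are symmetric with unit diagonal and agree
in sign on monotone associations.  Replicate-paired samples are used
as-is by default (all 282 columns); `collapse_replicates` averages each
condition's replicates first.

Genes are assigned to the domain containing their midpoint bin.  The
within/between comparison reports mean |co-expression| over same-domain
and different-domain gene pairs with both Mann-Whitney and Welch t-test
p-values, plus per-domain means (domains with fewer than two genes are
excluded with a note).  The border test takes gene pairs facing each
other across a border (one gene per border bin), uses the same joint
circular rotation null, and reports the lower-tail p.  The
distance-stratified curves bucket pairs by circular midpoint distance up
to 30 kb (3 kb bins) and contrast same-CID vs cross-CID pairs below
12 kb.

## Imaging-side geometry

Rotational cell volume from an axial radial profile: consecutive radii
over one slice height h contribute `pi min^2 h + (pi/3)(max^2 - min^2) h`
— a cylinder of the smaller radius completed by a cone.  This is the
closest reading of a cylinders-plus-cones decomposition (it is not the
exact conical frustum); it is additive over concatenation, cubic under
uniform rescaling, and reduces to the pure cylinder and pure cone in the
limits.  Per-tilt-image volumes are averaged.  Marker-referenced locus
distances are reduced by subtracting the midpoint-marker median, and
model/imaging agreement is a plain Pearson correlation over paired
medians.

## Synthetic data

The generator mirrors the detectors' models so every stage is testable
offline:

- **Genome**: 816,394 bp circular, 869 genes tiling both strands in runs
  (strand-switch probability 0.25, coding fraction 0.85), a smooth
  seeded GC profile around 0.40, and a Poisson restriction-site track
  with one site per 450 bp (the printed average cutting frequency; the
  deposited fragment count implies ~579 bp — the generator does not
  reconcile the two and the rate is a parameter).
- **Contact maps**: Poisson counts with expectation
  `depth * d^b * boost * (1 + eps * antidiagonal)`, b = -1, planted
  domain boost 3 applied to same-domain pairs (optionally only to a
  subset of domains), and a Gaussian-profiled secondary diagonal
  (eps = 0.3, width 2 bins) emulating inter-arm contacts of the two
  replichores.  Depth 50 per closest bin pair for 3 kb maps,
  borders every 5 bins (~15 kb domains).  Self-contact cells use a
  half-bin effective distance and are flagged.
- **Structure maps**: a closed circular 82-particle chain (chord spacing
  = sum of radii, 2% out-of-plane wobble so seeds differ) with Poisson
  contacts decaying as spatial distance to the -3, depth 200 at the
  closest pair — deep enough that replicate correlations sit in the
  published > 0.9 regime.
- **Expression**: one latent factor per planted domain with loading
  sqrt(rho) (rho_within = 0.5 over 141 conditions, two replicate columns
  per condition with 5% replicate noise), giving within-domain pairwise
  correlation ~ rho and independence across domains.

What the generator does **not** emulate: restriction-fragment geometry
and digestion efficiency, mappability and copy-number biases (beyond the
blacklist mechanism), condition structure in expression (batch effects,
magnitude shifts — the very thing the tendency statistic is robust to),
and any coupling of GC/site tracks to the planted domains.  Passing
tests therefore demonstrate that each method recovers its own generative
signal at realistic scale and noise, not that real-data artefacts are
handled; the border feature tests on synthetic tracks act as negative
controls.

## Problem sizes and limitations

The analysis scripts and the acceptance checks run the full genome scale
(273 bins at 3 kb, 82 particles at 10 kb, 869 genes x 282 samples) but a
reduced ensemble (500 models, 100 kept) — chosen as the size at which
the recovery statistics plateau.  The published 5,000/1,000 protocol is
the library default.  Known limitations: no excluded volume or polymer
physics beyond harmonic restraints, so absolute model dimensions are
restraint-scale artefacts (rank statistics, mirror structure and contact
patterns are meaningful; absolute lengths are not calibrated to the
published medians on synthetic input); the domain caller is flat (no
nesting); and reproducing exact published domain counts from the
deposited matrices may require tuning `bic_multiplier`, which is exposed
for that purpose (`analysis/08_reproduce_published.py`).
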