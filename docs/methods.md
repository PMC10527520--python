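# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic generator does and does not emulate.

## Data model

A localization table holds one row per detected emission event: frame
index, x/y (and optionally z) in nanometres, channel ∈ {1, 2}, and
optional quality columns (photon count, PSF sigma, fitted uncertainty).
Acquisition metadata carried alongside: frame rate (13.4 frames/s for
fixed-cell movies, 50 frames/s for live sequences) and camera pixel size
(160 nm at the sample; coordinates are already in nm, so this is
bookkeeping only). Upstream steps that produce such tables — peak
fitting, drift correction, channel registration, astigmatic z
calibration — are out of scope; the package consumes their output.

ROIs are axis-aligned rectangles with half-open membership
[min, max): a point exactly on the upper edge is outside. This makes
adjacent ROIs partition the plane without double-counting.

## Blinking correction (merging)

One fluorophore blinks several times, so localization counts over-count
molecules. Merging builds a graph on same-channel localizations with an
edge when two events are within a distance threshold *and* within a
temporal gap, and collapses each connected component to one molecule at
the intensity-weighted (unweighted if intensities are absent) mean
position, keeping the first participating frame. Connected components
make the result order-independent; the defaults (20 nm, 50 ms) are the
standard fixed-cell dSTORM settings.

The gap in milliseconds converts to an allowed frame separation of
max(1, ⌈gap·fps⌉): at 13.4 fps a 50 ms gap is less than one frame
interval, and the floor of 1 keeps consecutive frames linkable (a
sub-frame gap still spans two frames).

Recovery of the true molecule count requires the merge radius to cover
the localization jitter: consecutive emissions of one molecule with
per-axis precision σ are separated by a Rayleigh(σ√2) distance, so a
radius of ~4σ links ≈ 98% of consecutive pairs and keeps the expected
over-count of a mean-4 burst near 5%. The paper-standard 20 nm radius
therefore presumes ~5 nm per-axis precision; with the generator's
default 15 nm jitter a 60 nm radius plays the same role. The round-trip
tests exercise both pairings. Merging is only exact on well-separated
molecules; at high density distinct molecules within the radius merge
spuriously, which is inherent to the method, not to this
implementation.

## Pair correlation estimators

For n points in a window W with area |W|, the univariate estimate per
annulus (r₁, r₂] is

    ĝ = (ordered pair count in annulus) / (n(n−1)·π(r₂²−r₁²)/|W|),

whose denominator is the exact expectation under CSR with the toroidal
metric, giving an unbiased flat ĝ = 1 for Poisson input. The cross
estimator replaces n(n−1) by n₁n₂. Default binning is 10 nm from 0 to
500 nm; bins are (e_k, e_{k+1}] for pair counting, while a *readout
radius* r maps to the bin [e_k, e_{k+1}) containing it (so "g at 20 nm"
on 10-nm bins reads the 20–30 nm bin).

Two edge corrections are provided. Toroidal (default): distances use
the minimum-image convention, exact for stationary processes simulated
on a rectangle, and it keeps the oracle tests closed-form; r_max must
not exceed half the shorter window side. Border exclusion (for real,
non-periodic ROIs): per bin, only points further than the bin's outer
edge from every window side serve as reference points.

## Extent of mixing

    EOM(r) = (g₁₂(r) − 1) / (g_pool(r) − 1)

with g_pool the PCF of the pooled two-channel pattern. Under random
labelling, conditioning on the pooled pattern, each of its N(N−1)
ordered pairs becomes a cross pair with probability n₁n₂/(N(N−1)) (both
orders counted), so E[ĝ₁₂] = ĝ_pool exactly with the unbiased
normalizations above — the anchor EOM = 1. Under independence
E[ĝ₁₂] = 1, the anchor EOM = 0. Segregation = 1 − EOM. Values are not
clipped: attraction beyond random labelling can exceed 1, and noise can
push below 0.

Bins where |g_pool − 1| < 0.05 are masked invalid rather than returning
an unstable ratio; a curve with no valid bins is returned (empty valid
set), not raised, since flat pooled patterns legitimately occur for CSR
input. A Monte-Carlo relabelling reference (default 100 relabels) is
provided as a cross-check of the analytic pooled-PCF denominator.

A duplicated pattern (channel 2 ≡ channel 1) is *not* exactly a random
labelling — it fixes N/2 coincident cross pairs — so EOM equals 1 only
up to a factor (2n−1)/2n from the mismatched n² vs N(N−1)
normalizations; the test suite checks it at that O(1/n) tolerance.

Per-cell statistics are computed per ROI/cell and then averaged across
cells with SEM error bars; patterns are never pooled across cells
before estimation, which would confound within-cell structure with
between-cell density variation.

## Nanocluster sizing

DBSCAN with ε = 45 nm and minpts = 2, the published recommendation for
receptor nanocluster analysis at this localization density. minpts
counts the point itself (scikit-learn's convention), so one true
neighbor within ε makes a dimer; with this setting every in-cluster
point is core and the clusters are exactly the connected components of
the ε-neighborhood graph with ≥ 2 members — which is what the
brute-force oracle checks. An exclusive convention (minpts true
neighbors) is flag-selectable. Clustering is 2D; z is ignored even when
present, matching interface-plane analyses. Because it is ambiguous
whether reported dimer/trimer percentages weight clusters or molecules,
both bases are emitted.

## Axial statistics

Channel height separation Δz = mean z₁ − mean z₂ on *merged molecules*
(raw localizations would pseudo-replicate blinking bursts), tested with
a two-sided Mann–Whitney U by default — robust to the skewed,
non-Gaussian z profiles of 3D SMLM — with a Welch t-test alternative.
The null simulation in the tests confirms the nominal 5% type-I error
at n = 30 per channel.

## Synthetic generator

What it emulates: homogeneous Poisson (CSR) and Thomas cluster
processes (Poisson parents, Poisson(mean offspring) children, isotropic
Gaussian scatter); two-channel coupling as independence, random
labelling with P(channel 1) = p, shared parents (co-clustering), or
channel-2 parents displaced by a fixed distance in a random direction
(segregation, continuously tunable and coinciding with co-clustering at
zero displacement); blinking as a geometric (memoryless) emission count
per molecule at consecutive-or-gapped frames with Gaussian localization
jitter; optional per-channel Gaussian z. Children leaving the window
wrap toroidally by default, consistent with the toroidal estimators
(truncation is selectable).

Defaults: 4 µm × 4 µm window (the scale of the zoom regions used at
real interfaces); Thomas with 5 parents/µm², mean 10 offspring, 30 nm
cluster sigma (≈ 50 molecules/µm², pronounced nanoclusters of ~10
molecules — the regime the clustered-interface data occupy); CSR at
100 points/µm²; localization sigma 15 nm, respecting the ~20 nm
effective resolution of dSTORM; geometric mean 4 emissions.

What it does not emulate, hence what passing tests do not show: real
PSF shape or detection noise, fluorophore photophysics beyond emission
counts, multiple fluorophores per antibody (which the real experiment
cannot resolve either — its counts are comparative, not absolute),
drift or registration error, membrane topography (microvilli) coupling
z to xy, or between-cell heterogeneity. Tests passing on this ground
truth validate the estimators and their conventions, not the upstream
imaging chain.

## Cohort stage

Per-condition aggregation reports mean ± SEM per metric and a
two-sided Mann–Whitney U of each condition against the off-target
reference across cells (n ≈ 13–38 cells per condition in the motivating
data; nonparametric is the safe default at that size, Welch
selectable). Stars at 0.05/0.01/0.001 per comparison; no multiplicity
correction by default (Benjamini–Hochberg available). Scalar effector
readouts (ligand-positive fraction by FACS, Ca++ influx, killing
extent) enter as user-supplied per-condition values; excess killing is
killing minus the reference line's killing. Parameters are normalized
column-wise by their maximum across cell lines (so each column's best
line is 1; normalization is idempotent), and Pearson correlations are
computed across lines for every column pair — normalization does not
affect r. With four cell lines a Pearson r rests on 4 points; the
correlation matrix is descriptive, not inferential.

## Pipeline and problem sizes

The pipeline runs simulate → (optional blinking + merge) → per-cell
PCF/EOM/DBSCAN → cohort aggregation, writing per-cell and per-condition
CSVs plus a manifest (config, seed, version) that makes every output
reproducible byte-for-byte under a fixed seed.

Default test and acceptance problem sizes — ~800–1600 points per
pattern, 20–50 replicates per statistic, 1000 null repeats for the
type-I check — were chosen so each Monte-Carlo standard error is a few
per mill to a few percent, comfortably resolving the anchors (0 and 1)
being tested, while a full suite run stays under a minute.

## Known limitations

* Toroidal correction is exact only for patterns that are stationary on
  the torus; real ROIs should use border exclusion.
* EOM is undefined where the pooled pattern is near-CSR (masked bins);
  it cannot measure mixing of two patterns that are not clustered.
* Merging cannot split molecules closer than the merge radius, and
  cannot join bursts separated by more than the temporal gap; counts
  are comparative at realistic densities.
* DBSCAN size classes depend on ε; 45 nm is a recommendation, not a
  universal constant, and should be revisited for very different
  localization densities.
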