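# Methods

This note documents the models implemented in `rnapalm`, the defaults they
ship with, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Cell and nucleoid geometry

Cells are spherocylinders: a cylinder of length L − W capped by hemispheres
of radius W/2, with physical coordinates in μm, origin at the cell centre
and x along the long axis. Defaults are L = 3.0 μm, W = 1.0 μm, a typical
moderately growing *E. coli* cell. Normalized coordinates l, w ∈ [0, 1] are
linear maps of (x, y); the folded coordinate l_f = min(l, 1 − l) pools both
cell ends, so a uniform distribution has exactly half its mass at
l_f ≤ 0.25. Folding is used for all pole-proximity statistics because the
two ends of a cell are statistically equivalent in pooled data.

The nucleoid is a prolate spheroid inset from the poles by a 150 nm gap
(long semi-axis L/2 − 0.150). Its short semi-axis is not independently
constrained by the imaging data; we set it to 0.75·(W/2) so that the 3D
nucleoid is consistent with the 2D nucleoid-area estimate used elsewhere in
the pipeline (cell outline shrunk to 75% in length and width, which makes
the nucleoid cover roughly half of the cell area, as measured for minimal
medium). Region sampling is by rejection from the bounding box; the
spheroid's acceptance rate is exactly π/6.

## Four-population localization simulator

One simulated cell distributes n molecules (1800 for WT- and Δ5-like
configurations, 1200 for Δ6-like, matching measured per-cell copy numbers)
into:

* **mobile** — uniform in the nucleoid volume; 52% of molecules, minus the
  noise share;
* **noise** — uniform in the whole cell volume; default 10% of the mobile
  population (the diverted fraction is not constrained by data; 10% is a
  plausible level for mislocalizations and background);
* **rrn-bound** — 60% of the 48% immobile molecules (the value that best
  matches clustering data within the plausible 30–80% range), split
  equally among the strain's operon sites;
* **small clusters** — the remaining immobile molecules, in clusters at
  uniform nucleoid positions.

Cluster members are isotropic 3D Gaussians (σ = 40 nm, giving 100–200 nm
cluster diameters, consistent with reported RNAP cluster sizes) around
their centres, redrawn until inside the cell. Small-cluster sizes follow an
exponential law sampled by the inverse transform
X = −(1/b) ln(1 − b·u/a); draws with b·u/a ≥ 1 are rejected, X is rounded
and clamped to ≥ 1. Note that the transform is a proper sampler of the
exponential density a·e^(−bx) only when a = b (otherwise its CDF does not
reach 1); the shipped default is a = b = 1/15, i.e. a mean small-cluster
size of 15 molecules — small clusters an order below the >35-molecule
species, as expected for minimal-medium growth. The fitted (a, b) for real
data are not published, so these are explicit defaults, not estimates.

**Operon placement.** Each operon's long-axis position is a linear map of
its genomic distance from *oriC* (42/110/265/306/497/940/1196 kb on a
2320 kb replication arm — the printed values for rrnC/B/E take precedence;
the rest come from the MG1655 annotation): the origin maps to the
pole-proximal nucleoid tip and the terminus to mid-cell, following the
ori–ter longitudinal organization of the slow-growth chromosome. This fixes
a ring of candidate positions around the nucleoid surface; azimuths are
proposed uniformly until all pairwise separations are ≥ 70 nm (an error
after 10⁴ failed proposals). All operon sites of one nucleoid share one
randomly chosen pole, because *oriC* is a single locus; per-site random
poles would split the origin region across both cell ends.

One nucleoid per simulated cell; double-nucleoid (long) cells can be
composed by tiling two cells end to end.

**What the simulator does not emulate:** replication (operon copy numbers
per cell are handled separately by the dosage model), transcription
kinetics, condensates, photophysics beyond Poisson shot noise in the frame
renderer, blinking artefacts in fixed-cell counting, or segmented (bent,
variable-width) cell outlines. Tests passing on these synthetic patterns
show that the *analysis* pipeline is correct and that the *model*
reproduces the qualitative strain orderings; they do not certify absolute
experimental values such as the measured 42%/53% exterior fractions, which
depend on unpublished acquisition details.

## Track simulation and D*

Tracks are two-species Brownian walks: species membership is Bernoulli
(no within-track switching — D* windows are short, 4 steps, and the
mixture model assumes static membership), per-axis step variance 2·D·Δt at
Δt = 15 ms, and independent Gaussian localization error (σ = 35 nm) added
to every localization. Track lengths are geometric (photobleaching)
truncated at the 5-localization minimum, mean 8.

D* uses **exactly** the first four single-frame steps, which makes its
sampling distribution an exact Gamma(4, D_app/4) for a gapless Brownian
track and fixes the mixture's shape parameter. Displacements across a
bridged blink gap are excluded (a two-frame displacement would inflate the
MSD). The apparent coefficient of a bound molecule is the error floor
σ²/Δt = 0.0817 μm²/s, inside the 0.08–0.10 μm²/s control band used to fix
the immobile component.

A caveat made explicit here: because consecutive displacements share one
localization's error, per-localization noise makes the immobile D*
distribution ~30% wider in variance than the shape-4 gamma. The
closed-form gamma limit therefore holds exactly for tracks whose error is
folded into the apparent coefficient, and approximately (recovery within
~±1 point in the mixture fraction) under the per-localization error model;
both regimes are covered by tests.

## Two-gamma fitting

Unbinned maximum likelihood rather than least squares on histogram bins:
it has no bin-width sensitivity and is deterministic. The immobile D* is
fixed (default 0.09 μm²/s, configurable in 0.08–0.10); (f, D_mob) are
optimized by Nelder–Mead from five fixed starting fractions with D_mob
bounded above the immobile value (at the bound the mixture is
unidentifiable; convergence there raises a warning). Exact zeros in D*
(perfectly stationary tracks) are clipped to 10⁻¹² to keep the likelihood
finite. Track classification for maps uses a threshold of 0.16 μm²/s,
boundary inclusive.

## Tracking

Greedy nearest-neighbour linking within a search radius (default 0.48 μm
≈ 5× the RMS single-frame displacement of a mobile molecule; the value
used for the published data is not stated). Candidate links are taken in
increasing distance order with ties broken by localization index; a
one-frame absence is bridged, longer gaps split the track. This is
adequate for sparse photoactivation; no multi-hypothesis or global
assignment is attempted.

## Heatmaps and exterior fractions

50 × 25 bins over (l, w) (bin counts are a presentation choice); one
spatial sample per track — its first localization — so long tracks do not
dominate, matching the convention used for clustering input. Difference
maps normalize each class map to unit mass before subtracting, otherwise
unequal track counts set the sign. The exterior fraction is computed from
folded positions directly when positions are available; computing it from
a binned heatmap is resolution-limited because the 0.25 cutoff falls
inside a bin.

## Clustering

`sklearn.cluster.DBSCAN` (ϵ = 20 nm, MinPts = 4, neighbourhood counting
inclusive of the point itself) behind a thin layer that derives
core/directly-reachable/noise roles and per-cluster sizes. Border points
reachable from several clusters go to the cluster discovered first in
index order — the classical ambiguity, fixed for reproducibility and
verified against a brute-force reference (neighbourhood enumeration +
connected components). Large-cluster summaries use strict thresholds
(> 35, > 70, > 100 molecules) with clustered molecules as denominator.

## Pair correlation and co-localization

g(r) bins all within-cell pair distances (default 10 nm bins to 1 μm) and
divides by the mean histogram of uniform draws in the 3D rotated cell
volume projected to 2D (default 20 draws; tests use more). Bins with an
empty null are undefined (NaN) and excluded from cell averages, which are
unweighted. Because the null fills the whole cell while mobile molecules
fill only the nucleoid, a *uniform-in-nucleoid* population shows g
moderately above 1 at short range (~1.8 with the default geometry) — this
confinement offset is expected and distinct from genuine clustering, which
reaches several-fold enrichment.

Co-localization uses the fraction of queries within 200 nm of the nearest
focus. The random baseline draws points uniformly in the nucleoid *area*
(cell outline scaled by 0.75 in both dimensions — an area model, not a
projection of the 3D volume). Foci positions stated as folded fractions
are interpreted within the shrunk region; with a 3.0 × 1.0 μm cell and
three foci at folded nucleoid positions 0.15/0.15/0.30 the baseline is
23.5%, matching an independent lens-area integration of disc–region
overlap.

## Occupancy model

N_r (RNAPs engaged on *rrn*) is interpolated across doubling times by a
single exponential fitted to ln N_r against ln τ — equivalently the power
law N_r ∝ τ^β, β ≈ −2.7. The shipped six-condition calibration is
collinear on that axis to ~1.5% (leave-one-out error ≤ 1.3%), whereas
fits against τ or growth rate 1/τ mispredict held-out conditions by up to
30%; the log–log axis is therefore the package default.

Gene dosage is 2^((C(1−m′)+D)/τ). C and D are rarely known directly, so
C+D is inverted from the *oriC* copy number (m′ = 0 limit) and split
C:D = 2:1, which reproduces all six reference *rrn* copy numbers within
5%; the split ratio is configurable. Ratios are kept unrounded
internally; integer rounding (half away from zero) is applied only at
report time. The physical occupancy ceiling is floor(operon length /
footprint) with defaults 5400 bp (16S + 23S + 5S plus spacers) and 40 bp
per elongating RNAP, i.e. 135. The ori:ter helper is plain 2^(ΔCt)
arithmetic. Plasmid-only strains (Δ7-like) are supported through an
explicit plasmid copy parameter but are not part of the reference table
because their plasmid copy number is poorly constrained.

## Localization

Detection is difference-of-Gaussians (σ = 1 and 3 px) with a mean + 4 SD
threshold and 3×3 local maxima; refinement fits a free elliptical
Gaussian + offset in a 7 × 7 px window (100 nm pixels) by least squares.
These operator parameters are declared defaults — the published pipeline
names the operators but not their settings. Duplicate fits from plateau
maxima are merged within one pixel; border-clipped candidates are skipped
and counted. Fixed-cell repeat localizations are merged when within
100 nm in consecutive frames. No drift correction, astigmatic 3D or
sCMOS noise modelling.

## Problem sizes

Default analysis runs use 200 simulated cells per strain and 5000 tracks;
the verification suite uses up to 2000 cells per strain for strain
orderings, 100 replicates of 10⁴ tracks for mixture recovery, and 10⁵+
points for Monte-Carlo baselines. The pair-correlation null histogram is
computed once per (geometry, point count) and shared across cells, which
is statistically identical to per-cell draws since simulated cells share
a geometry.
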