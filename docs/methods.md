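# Methods

## Shape representation

A particle is its closed 2D outline. After segmentation and subpixel
boundary tracing, the outline is resampled to N equally spaced points
(N = 1024 by default, a power of two for the FFT) and reduced to the
radial signature r(t), the distance from the contour's area centroid to
boundary point t. The descriptor is the discrete Fourier transform of
r(t) with the forward 1/N convention, so c₀ is the mean radius; the
feature vector used in all statistics is the one-sided normalized
amplitude spectrum aₖ = 2|cₖ|/c₀ for k = 1..K (K = 512, half the
signature length — enough to keep every resolvable harmonic).

Invariances are structural: translation (centroid-relative distances),
scale (c₀ division), rotation and start point (amplitudes discard phase,
and resampling always starts at the vertex farthest from the centroid,
near-ties broken by smallest polar angle with a 1e-9 snap at the 0/2π
branch cut so symmetric shapes get a platform-stable start). The radial
signature was chosen over elliptic Fourier descriptors because branched
particles are star-shaped about their centroid, the signature is real,
and its amplitudes are invariant without further normalization; elliptic
descriptors remain a possible alternative backend. Non-star-shaped
contours are processed (the arc-length signature stays well defined) but
flagged with a warning.

### Resampling

Equal spacing is driven to a fixed point by iterated arc-length
resampling, making consecutive chord lengths equal to 1e-6 relative and
the operation idempotent. The first point is pinned at the canonical
start. Perimeter is preserved within 0.1% whenever the sharpest boundary
feature spans several sample spacings; needle-like protrusions finer
than perimeter/N (extreme urchins) are traced with graceful corner
rounding — increase N to resolve them. Reconstruction from a truncated
spectrum is exact at K = N/2 and monotone in truncation error.

## Segmentation

Global Otsu thresholding (micrograph fields of well-spread dark
particles on a bright background are bimodal; a global threshold is
deterministic), hole filling, 4-connected labeling, removal of
border-touching components (unbiased shape statistics) and of components
below a minimum area. Boundary tracing runs marching squares at the 0.5
level of the mask smoothed with a σ = 1 px Gaussian: tracing the raw
binary staircase overestimates a disk's perimeter by ~5%, while the
smoothed iso-contour is accurate to well under 2% for radii ≥ 30 px.
Touching particles are not split — overlapping placements are outside
the imaging protocol the renderer emulates, and the renderer rejects
them.

## Shape space

PCA is fit on the pooled feature matrix of exactly the ensembles under
comparison — coordinates are comparison-specific, not global — with
centering but no per-feature standardization (harmonic amplitudes share
units; standardizing would inflate high-frequency noise). Full SVD, all
components kept, and a fixed sign convention (each component's
largest-magnitude entry is positive) for cross-platform reproducibility.
The working dimension is m = 3 components; plots and ellipses use 2.

The 95% confidence ellipse of an ensemble comes from its sample mean and
covariance: semi-axes √(λᵢ q) with q the χ²(2) quantile at the coverage
level. Dispersity is summarized as the distribution of particle
distances to the ensemble centroid, smoothed by a Gaussian KDE at the
Silverman bandwidth on a 512-point grid from 0 to max + 3 bandwidths;
because distance has a hard boundary at zero the evaluated density is
renormalized on the grid (trapezoid) to integrate to one.

## Overlap and independence

Both ensembles are projected onto the unit vector joining their centers
of gravity (origin at the first centroid; coincident centroids fall back
to the first shape-space axis and are flagged). Each 1D sample gets its
own Silverman-bandwidth Gaussian KDE, evaluated on a shared 512-point
grid spanning the joint range padded by three times the larger
bandwidth, and OVL = ∫ min(f, g) clipped to [0, 1]. OVL is symmetric,
invariant to rigid rotations of the coordinates, and reads as the
fraction of particles common to both distributions; the Bhattacharyya
coefficient ∫ √(fg) is reported as a secondary statistic. The
independence threshold defaults to 0.05 (a declared choice — the
methodology requires a threshold but no canonical value exists) and is
surfaced in every report. At n = 20,000 samples per side the measured
OVL of two unit normals tracks the closed form 2Φ(−Δ/2) within 0.02;
KDE smoothing biases OVL slightly upward at finite n, which is why
ensembles below 20 particles are rejected.

## Synthetic ensembles

The generator emulates branched-particle families as polar curves
r(θ) = R(1 + A Σⱼ g((θ−θⱼ)/s) + ρ·η(θ)) with g a unit-peak von-Mises
bump exp(κ(cos u − 1)), κ = 1/s². Defaults per family: star 5 spikes,
A = 0.55, s = 0.45 (few long arms); flower 10 spikes, A = 0.25,
s = 0.35 (rounded lobes); urchin 40 spikes, A = 0.30, s = 0.08 (fine
needles); sphere 0 spikes — chosen to match the classic TEM morphologies
at a 30 nm base radius. η is a band-limited (32-harmonic, 1/√k
spectrum) unit-RMS periodic noise, ρ = 0.01 by default. Particle-to-
particle variability uses lognormal draws at CV 0.05 (radius) and 0.10
(amplitude, sharpness), a realistic polydispersity for seed-mediated
growth; spike counts, when varied, are rounded truncated normals.
Seeding is hierarchical (ensemble seed → per-particle seeds) so any
particle is reproducible in isolation. Amplitude is capped at 0.9 and
the signature checked positive, so contours never self-intersect the
centroid.

The renderer rasterizes filled particles (intensity 0.15) on a bright
background (0.85) with additive Gaussian noise and rejection-sampled
non-overlapping placement, ≥ 5 px from the border. It emulates contrast
and shot noise only — no defocus, astigmatism, stain gradients or
aggregation — so pipeline tests demonstrate correctness of the
computational chain, not robustness to every TEM artifact.

## Discovery loop

The search is coordinate ascent over generator parameters with two
overlap thresholds: a step whose ensemble overlaps the previous one
below `backtrack_ovl` (default 0.01) is a discontinuous jump — the step
is halved and retried; a readout is spent only when the candidate's
overlap with the last assayed ensemble is at or below `ovl_gate`
(default 0.05), because contiguous distributions carry no new
biological information. After a non-improving readout the direction
reverses, then rotates to the next parameter; the run stops at the step
budget or when all steps fall below 1/64 of their initial size. This
reverse-then-rotate rule is the minimal deterministic realization of a
manual gradient-like search; surrogate-model optimization is left as
future work.

Pairwise overlaps are computed in a pooled PCA refit of each pair, as
everywhere else in the package. The surrogate readout, however, needs a
stationary coordinate system across the run, so trajectory centroids are
tracked in a reference space fitted once on the starting ensemble
(m = 3, K = 64 harmonics by default inside the loop — the readout
landscape is low-dimensional and the smaller K keeps per-step refits
cheap). The surrogate is a sum of isotropic Gaussian bumps standing in
for an assay- or transcriptome-derived response; the interface takes any
callable-equivalent landscape so a real assay table can replace it.
The structure–function table is the greedy in-order subsequence of
assayed ensembles that are *pairwise* independent at the gate.

## Problem sizes and numerical choices

Statistical defaults were fixed before measurement: 200 particles per
ensemble for family comparisons, 60 rendered particles for pipeline
recovery, 40 particles and 12–15 steps per discovery trajectory, 10–20
trajectory replicates. KDE grids are 512 points; all tolerances quoted
in docstrings assume the forward-1/N transform. Degenerate inputs fail
loudly: zero-variance projections, collinear ellipse inputs, all-equal
distance distributions and sub-minimum ensembles raise ValueError rather
than returning NaN.

## Known limitations

Shapes are 2D projections; 3D information is out of scope. The radial
signature folds on strongly non-star-shaped outlines (flagged, not
rejected). OVL is estimated along one axis (the inter-centroid line), by
design — multivariate KDE overlap is not attempted. No watershed
splitting of touching particles. The generator does not model growth
kinetics; its parameters stand in for reactor parameters only in the
sense that both index a family of ensembles.
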