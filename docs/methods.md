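# Methods

## The measurement model

A kinase translocation reporter (KTR) is exported from the nucleus when its
kinase phosphorylates it, so the instantaneous activity of the kinase in
one cell is summarised by the C/N ratio: the mean reporter intensity over
the cell's cytoplasmic pixels divided by the mean over its nuclear pixels.
The pipeline assumes three simultaneously imaged channels — a nuclear
marker (used only for segmentation and tracking), an Akt reporter and an
ERK reporter — acquired every 3.5 min in 12-bit counts, with the stimulus
added during (1-based) time point 7 and a 0.5 min acquisition stagger
between consecutive wells of a plate.

## Image preprocessing

* Nuclear-marker channel: subtract a constant 250 counts (clamped at 0) to
  remove residual cytoplasmic signal from marker overexpression, then
  threshold at 330 counts for segmentation.
* Akt channel: rolling-ball background subtraction with radius 70 px. The
  ball is rolled on a local-minimum-downsampled copy for large radii
  (factor `radius // 10`), the background is upscaled bilinearly and
  clipped to lie at or below the image, so the output is nonnegative and
  features narrower than the ball radius are preserved. On a flat
  background the second application removes < 1% additional signal.
* ERK channel: used raw for quantification; blurred (Gaussian σ = 2,
  reflective padding) and thresholded on the inclusive window
  [300, 65535] to give the binary cell mask. Channels are not spectrally
  unmixed; cross-talk is assumed negligible.

## Segmentation, tracking, quality control

Nuclei are 8-connected components above the 330-count threshold, declumped
by a watershed on the inverted smoothed intensity seeded at intensity
maxima at least `d_min` apart, then gated to an equivalent diameter
2·sqrt(area/π) in [8, 20] px (the gate is applied after declumping).
Cells are nuclei expanded up to 5 px (Euclidean) within the cell mask;
contested pixels go to the nearest nucleus, and a cell always contains its
nucleus. Cytoplasm is the set difference cell − nucleus; nucleus and
cytoplasm pixel sets are disjoint by construction and this is asserted at
run time.

Measured features per object and frame: centroid (0-based, x = column),
pixel area, mean radius (mean of the Euclidean distance-to-background
transform over the object, so 1–2 px slivers score ≤ 1), and per-channel
mean intensity.

Linking is greedy nearest-centroid between consecutive frames with a 3 px
Euclidean gate, candidates taken in ascending distance (ties by lower
object id), one-to-one. There is no gap closing or merge/split handling:
only tracks present as exactly one object in every frame survive, matching
the downstream requirement that every trajectory covers the full
acquisition.

QC gates (applied to both compartments before tracking): every channel
mean intensity within [260, 4000] counts, area ≥ 100 px, mean radius > 1.

## Trajectory processing

Acquisition times are (tp − 1)·3.5 + (well − 1)·0.5 min. Each cell's
series is linearly interpolated onto the well-1 nominal grid; grid points
outside a cell's observed span are dropped rather than extrapolated, and
cells with fewer than two observations are dropped. Normalization
subtracts the mean C/N at time points 5 and 6 (the two points before
stimulation); the subtracted mean is kept as the cell's start ratio, used
to stratify cells into basal-activity pools with half-open bins
[0.15, 0.35), [0.35, 0.60), [0.60, 1.00). The response measure is the AUC,
deliberately defined as the plain sum (not a trapezoid integral) of
normalized C/N over time points 9–18 (7–38.5 min post-stimulation); cells
missing any window point are excluded rather than imputed.

## Concentration–response

Per concentration, the response is the unweighted mean over biological
replicates of the within-replicate mean AUC, so a replicate with many
cells does not dominate. The four-parameter logistic is fitted by
unweighted least squares in the log-logistic parameterisation
y = c + (d − c)/(1 + exp(b(ln x − ln e))), initialised from the data range
and the concentration nearest the midpoint response, with e bounded
positive and b left free in sign. The negative control enters at a
pseudo-concentration of 1e−4 × the lowest tested concentration. A fit that
fails to converge is returned flagged with its diagnostics; an all-flat
response is flagged degenerate.

## Clustering and validation

Clustering operates on the n_cells × 10 matrix of normalized C/N at time
points 9–18. Hierarchical clustering uses the Lance–Williams Ward update:
*Ward2* squares the supplied dissimilarities first and reports
square-rooted heights (with Euclidean input this is exactly coordinate-
space minimum-variance Ward, verified against a brute-force oracle), while
plain *Ward* applies the update to the dissimilarities as given; both are
computed through `scipy.cluster.hierarchy.linkage(method="ward")`, using
the square-root trick for the plain variant since cutting into k clusters
is invariant to monotone height transforms. K-means is best-of-25 Lloyd
restarts with a fixed seed.

The candidate grid per kinase is five methods (four hierarchical variants
plus k-means) × three k values — 15 combinations; the defaults are
k ∈ {8, 9, 10} for ERK and {3, 4, 5} for Akt, reflecting the larger
dynamic range and shape diversity of ERK responses. Six internal metrics
score each combination; BW ratio, Dunn, silhouette, Pearson gamma and
connectivity are computed on the clustering's own distance matrix, while
Calinski–Harabasz is always computed in coordinate space (a documented
choice — the coordinates are always available, and this avoids an
ill-defined distance-matrix generalisation for Manhattan runs). Each
metric is divided by its maximum over the grid and the six normalized
values summed. Connectivity is lower-is-better, so it is transformed to
1/(1 + connectivity) before normalization; the raw value is reported
alongside. The top combined score selects the clustering, ties broken
toward fewer clusters; no visual-inspection step is modelled. When more
cells are available than the configured subsample cap (default 15 000),
a uniform seeded subsample is clustered.

Degenerate inputs raise rather than return sentinels: all-singleton
partitions (BW, Dunn), zero within-cluster variance (Calinski–Harabasz),
constant distance vectors (Pearson gamma), fewer than two clusters (all).
Neighbor ranking ties in connectivity are broken by index order (stable
sort).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
microscope physics. Trajectory tables: baseline C/N uniform in
[0.20, 0.75]; five response archetypes built from difference-of-
exponentials pulses normalized to unit peak — flat (amplitude 0), low
(0.12), transient (0.5, rise 5 min / decay 25 min, peak ≈ 10 min
post-stimulation, back below 25% of peak by 60 min), sustained (0.45, 60%
plateau fraction), biphasic (0.4, second pulse delayed 25 min so the
second peak sits ≈ 35 min post-stimulation, inside the analysis window) —
with mean-preserving lognormal cell-to-cell amplitude jitter (CV 0.25 by
default, amplitudes being positive and right-skewed) and additive Gaussian
ratio noise (sd 0.02 default). Dose series scale the mean transient
amplitude by a Hill curve with lower asymptote 0, so the downstream AUC
inherits the planted EC50 exactly (AUC is linear in amplitude).

The renderer draws non-overlapping nuclei as disks (diameter 12–16 px by
default — inside the 8–20 px segmentation gate and above the 100 px area
gate) with cytoplasmic annuli of width 5 px, nuclear-channel intensities
900 (nucleus) over 100 (background) so the 330-count threshold separates
them, and KTR-channel nucleus intensity 1500 with the ring set to
1500 × C/N, so the planted ratio is recovered exactly from the planted
masks. Per-frame centroid jitter is uniform within 1 px (≤ the 3 px
linking gate). Optional Poisson-plus-Gaussian count noise is off by
default. Not emulated: photobleaching, division/death, directed migration,
intracellular texture — so passing closure tests demonstrates correctness
of the measurement chain on well-behaved objects, not robustness to those
real-data effects.

## Problem sizes and numerical choices

The shipped study uses 50-cell noiseless renders for image-pipeline
closure (recovery ≥ 95% of planted cells, C/N error < 2%; measured ~100%
and ~0.1%), 100 cells per archetype for partition recovery
(Manhattan + Ward2 at the planted k; ARI ≥ 0.9 at ratio noise 0.05), 200
cells per concentration × 8 concentrations × 20 seeds for EC50 recovery,
and 100 random n ≤ 8 instances for the Ward2/brute-force equivalence
check. Under these conditions the EC50 estimator's spread is roughly 4–5%
(sd), so the worst of 20 seeds sits near the 10% mark and can exceed it
for some seed streams; the median error is ~2–3%. All randomness flows
from explicit seeds; rerunning any stage with the same seed reproduces its
outputs bit-for-bit.

## Known limitations

Declumping relies on intensity maxima ≥ d_min apart and will merge nuclei
whose intensity profiles lack distinct peaks; tracking has no motion model
and will swap adjacent cells that move > 3 px per frame; the 4PL fit is
unweighted and per-condition (no per-cell fitting); cluster selection is
purely score-based. Real-data constants (thresholds in counts) assume
12-bit acquisitions with the stated reporters and would need recalibration
for other setups.
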