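# Methods

`nucleoquant` quantifies whether a fluorescently labelled nucleolar component
behaves like a condensate formed by polymer–polymer phase separation (PPPS —
compressible, punctate, slow-exchanging) or by liquid–liquid phase separation
(LLPS — incompressible droplet, homogeneous, fast-exchanging). This note
documents the measurements, their assumptions and numerical conventions, the
synthetic data that ground-truths them, and the design choices that were
genuinely open.

## Input conventions

All analyses operate on cropped, single-signal z-stacks stored as multi-page
grayscale TIFF, axis order `(z, y, x)`. The conventional crop is 55 × 55
pixels spanning 3.5 × 3.5 μm laterally (pixel pitch ≈ 63.6 nm); arbitrary
extents are accepted. The axial step is acquisition-dependent and defaults to
0.3 μm; voxel geometry can be supplied per file via a YAML sidecar. Integer
pixel data are promoted to float64 on ingest. Cropping a signal out of a
full-field acquisition is an upstream, interactive step; only a center-crop
utility is provided.

## Background segmentation

Each stack (or projection, depending on the analysis) is split into cellular
background and signal foreground by a single Otsu threshold. The threshold is
computed on the exact multiset of observed intensities: every distinct value
is a candidate cut, and the value maximizing the between-class variance (first
maximizer on ties) is returned. Compared with a fixed 256-bin histogram this
makes two properties exact rather than approximate: equivalence with an
exhaustive intra-class-variance scan, and invariance under affine intensity
rescaling (the threshold transforms with the data). Foreground is strictly
`intensity > t`, so ties at the threshold are background — a deterministic
reading of "values below the threshold are removed". Thresholds are computed
per image stack, never shared across a population. Constant images raise an
error: a contrast-free crop indicates an upstream mistake, not a measurement.

Routing: homogeneity scoring thresholds the 2-D projection it scores;
volume/intensity/heterogeneity and two-channel analyses threshold the raw 3-D
stack. Both paths expose the same strict-inequality rule.

## Homogeneity (GLCM texture)

The stack is collapsed to a sum-intensity projection (a max-projection mode is
available as an option), thresholded, and its foreground min–max rescaled to
[0, 1]. Scaled values are quantized to 8 gray levels with left-closed
equal-width bins `[k/8, (k+1)/8)`, 1.0 clamped into level 8 — so 0 → 1,
0.5 → 5, 1 → 8, matching the scaling of the standard GLCM routine this
replaces. The 8 × 8 co-occurrence matrix counts ordered pairs at the single
horizontal offset (0, +1); any pair touching a sub-threshold pixel is skipped
and the accumulation is not symmetrized (|i − j| is symmetric, so the score is
unchanged either way; the pair count bookkeeping is what differs, and the
convention is recorded in the output). The score

    homogeneity = Σ_ij p(i, j) / (1 + |i − j|),   p = counts / n_pairs

lies in (0, 1] and equals 1 exactly when every valid pair lies on the
diagonal. A constant foreground is assigned score exactly 1 — the limiting
value — rather than erroring, so degenerate but real cells survive batch
runs. The score is invariant under affine intensity transforms (absorbed by
the rescaling) and under left–right mirroring.

## Morphometry and the compression readout

Per cropped stack, with threshold `t` from the raw voxels:

* **volume** — count of voxels `> t` (units: voxels);
* **mean intensity above background** — foreground sum / volume − t, the
  proxy for in vivo concentration;
* **compression** — mean above background / volume (intensity · voxel⁻¹);
* **heterogeneity** — SD of the foreground after min–max rescaling to [0, 1].
  Population SD (divide by N) by default, which makes the half-min/half-max
  two-point bound of 0.5 exact; the sample convention is a config option;
* bookkeeping fields used for outlier gating: integrated foreground
  intensity, in-focus area (above-threshold pixel count of the z-plane with
  the greatest total intensity — the operational reading of "in focus"),
  and the above-threshold areas of the max and sum projections, each with an
  Otsu threshold computed on that projection.

A compressible population (fixed amount, variable volume) shows a strong
anti-correlation between volume and mean intensity above background; an
incompressible droplet population at fixed concentration shows none. Pearson
r with the two-sided t-transform p-value (n − 2 df) is reported after outlier
gating: a record is excluded when any of the six measures above deviates from
its population median by more than 3 scaled median absolute deviations
(scale 1.4826). The MAD rule is the robust default of the numerical
environment the original analysis ran in; gating is applied per analysis
group, since groups (cell-cycle stage, treatment) are analyzed separately
throughout.

## Two-channel statistics

**Voxelwise Pearson correlation** is computed over the union of the two
foreground masks, using raw intensities on that support (thresholding defines
*which* voxels participate, not their values). The union rule is deliberate:
the phenomenon of interest is one signal excluded from the other's core, and
an intersection rule is blind to exclusion zones. Intersection and
single-channel supports are available as options.

**Relative positional variance (rpv)** summarizes where channel A sits
relative to channel B's signal: with `d_i` the Euclidean distances from each
foreground voxel of A (each counted once, regardless of intensity) to the
centre of B,

    rpv = σ²(d) / μ(d)

(population variance by default). The centre of B is the intensity-weighted
centroid of its foreground (robust to threshold jitter; the unweighted mask
centroid is an option). Distances default to physical micrometres via the
voxel size, since axial steps are usually anisotropic; a voxel-unit mode is
kept for isotropic work and agrees with the physical mode up to the scale
factor. rpv has units of length and scales linearly under isotropic spatial
rescaling. Fixed points: voxels intermixed uniformly through a ball of radius
R give μ = 3R/4, σ² = 3R²/80, hence rpv = R/20; a thin shell at radius R is
nearly equidistant from the centre and gives rpv ≈ 0. An intensity-weighted
rpv variant is exposed but is not the reference definition.

## FRAP

An experiment is (pre-bleach image, laser-spot image, timelapse); the default
acquisition is 50 frames spanning 30 s, frames uniformly spaced unless
timestamps are supplied. The recovery region is the intersection of the Otsu
foregrounds of the pre-bleach and laser images (an empty intersection means
the bleach missed the signal); the pre-bleach mean over that region anchors
the normalization — the pre-bleach image, not frame 0 of the timelapse.

Imaging photobleaching is estimated as the least-squares linear slope of a
reference region's per-frame mean. The reference defaults to the non-bleached
signal (pre-bleach foreground minus the recovery region): recovery itself
then cannot contaminate the estimate, and background pixels do not dilute
the relative rate. Whole-frame modes are available. The loss is undone by a
ratio correction against the fitted linear trend, `raw · a / (a + b·frame)` —
first-order equivalent to adding `|b|·frame`, but amplitude-matched, so a
region recovering to only a fraction of the reference intensity is not
over-corrected. If the corrected curve still overshoots the pre-bleach level
(negative unrecovered fraction), the applied correction is shrunk by 10% per
iteration, at most 100 iterations, until the final frame sits below the
pre-bleach level; whether and how far this loop ran is reported
(`rate_adjusted`, iteration count).

Two summaries are emitted, because both appear in practice:

* `percent_recovery` = normalized(final) − normalized(first post-bleach
  frame): the conventional definition. For an ideal fully bleached spot it
  equals m(1 − e^{−kT}) with mobile fraction m and recovery rate k;
* `unrecovered_fraction` = 1 − normalized(final): the pre-bleach-minus-final
  difference. This is the quantity the correction-adjustment loop bounds
  above zero — over-correction is the only mechanism that drives it
  negative, whereas the conventional difference only moves further from zero
  when the correction is reduced.

No diffusion or reaction-diffusion model is fitted; only percent recovery
and the normalized curves are reported.

## Synthetic data

The generators embody the statistical structure the measurements are designed
to discriminate, with every parameter surfaced in a `GroundTruth` record.
All images share one rendering path: Gaussian PSF blur, additive background,
then noise; all generators are bit-reproducible from (model, seed).

* **PPPS** (`PPPSModel`): 12 Gaussian puncta placed uniformly in an ellipsoid
  about the stack centre; raising `crosslink_density` from 0 to 1 shrinks the
  cluster radius 16 → 5 voxels and the punctum width 2.0 → 0.9 voxels while
  amplitudes are rescaled after placement so the integrated intensity is
  exactly `total_integrated_intensity` (2 × 10⁵ by default) at every density —
  conservation is the mechanism behind the anti-correlation. Default stack
  11 × 55 × 55, echoing the crop convention.
* **LLPS** (`LLPSModel`): a uniform ball of the requested volume at fixed
  concentration 100, at a random interior position with a 2-voxel margin.
  Cells carry ~15% lognormal concentration variability
  (`concentration_jitter`), emulating expression variation across a
  population; it is volume-independent, so the regime's defining property —
  expected concentration constant across volumes — is preserved. Without it
  the population is unrealistically sterile and a sub-percent partial-volume
  drift of the threshold with droplet size becomes the only variance left,
  which would read as a spurious volume–intensity correlation no real
  population exhibits. Default stack 27 × 55 × 55 so droplets up to ~4000
  voxels fit.
* **Two-channel** (`TwoChannelModel`): channel B is a uniform ball of radius
  R; channel A either fills it uniformly (`intermixed`) or occupies a
  spherical annulus of radial width `shell_thickness` centred on B's surface
  (`shell`), sharing B's centre.
* **FRAP** (`FrapModel`): a disc-shaped signal with a bleach spot inside it;
  spot intensity follows
  I(t) = [I_post + m (I_pre − I_post)(1 − e^{−kt})] e^{−βt}, the surrounding
  signal decays as e^{−βt}. Defaults: full bleach (I_post = 0) and zero
  additive background, so the noiseless β = 0 invariant
  percent_recovery = m(1 − e^{−kT}) holds exactly; both are parameters.

Noise defaults are Gaussian with σ = 5% of the signal scale (2% for
two-channel and FRAP); a Poisson mode is available for photon-limited stress
tests. For the PPPS generator the Gaussian σ is quoted against a fixed
reference intensity (100, the uncompressed concentration scale) rather than
the image peak: detector noise does not grow as compaction concentrates the
signal, and peak-proportional noise would flood the background for tightly
compressed puncta.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: optical anisotropy of the PSF and axial smearing,
depth-dependent attenuation, camera gain/offset structure, cell-to-cell
background variation, motion during acquisition, segmentation ambiguity from
neighbouring signals, and any real polymer physics (puncta are Gaussian
blobs, not chromatin simulations). The suite demonstrates that the
measurements recover the constructs' known structure, not that the biological
classification of any particular protein is correct.

## Group statistics and batch behaviour

Two-group comparisons use the two-sided Wilcoxon rank-sum test (exact null
distribution for small tie-free samples, normal approximation with tie
correction otherwise; the rank-sum W is reported). Three or more groups use
one-way ANOVA with Tukey HSD pairwise comparisons; the omnibus F is always
reported alongside the Tukey pairs rather than gating them. Batch runs write
a tidy per-record CSV, a summary JSON echoing every option and seed, and a
plain-text log with per-record timing; per-record failures are logged and
skipped. CSV content is deterministic in (config, seed).

## Problem sizes and tolerances

The reference checks run at: 500 random 12 × 12 quantized images against the
brute-force GLCM oracle (agreement to 1e−12); 200 random 8-bit images against
the exhaustive Otsu scan (exact equality); 200 stacks per regime for the
correlation dichotomy (r ≤ −0.8 vs |r| ≤ 0.2); 100 + 100 stacks for the
homogeneity dichotomy (rank-sum p < 0.001); 100 two-channel pairs for the
rpv ordering plus the analytic R/20 = 0.5 fixed point (±0.05); 20 FRAP
replicates per condition (recovery within ±0.05 of m(1 − e^{−kT}) without
bleaching, ±0.1 with β = 0.01 s⁻¹); 50-point density sweep for compression
monotonicity (Spearman ρ > 0.9). Null calibration of the rank-sum test uses
4,000 simulated pairs (binomial SE ≈ 0.0034 on a 0.05 target).

## Known limitations

* Exact-value Otsu on large float stacks sorts every distinct intensity;
  this is O(n log n) and fine at crop scale, but a binned variant would be
  preferable for full-field images.
* The linear photobleaching model is a first-order stand-in for exponential
  loss; for βT ≳ 0.5 the residual curvature biases the correction.
* The one-threshold/one-signal model deliberately excludes instance
  segmentation; crops containing two signals are measured as one.
* rpv compares configurations reliably; its absolute value depends on voxel
  anisotropy and threshold placement, so report units and conventions with
  any number.
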