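# Methods

## The measurement problem

Cyclic immunofluorescence on resin-protected specimens repeats a
label → image → elute → relabel loop on one physical sample. Everything
downstream hinges on a few quantitative questions: whether elution
actually removes the previous round's label, whether relabeling
reproduces the same spatial pattern, whether several proteins co-occupy
the same pixels more often than chance, and whether antibodies penetrate
the full depth of the specimen. This package implements those four
measurements plus the preprocessing they require and a generative
simulator that provides ground truth for all of them.

## Preprocessing

**Background subtraction.** The rolling-ball filter is realized as
grayscale morphological opening with a flat disk footprint of the given
radius (default 50 px); the opening is the tightest surface the
structuring element can support from below, so subtracting it removes any
background smoother than the element while passing puncta smaller than
it. Opening is idempotent, hence so is the subtraction. The result is
clipped at zero.

**Registration.** Inter-round drift of a fixed, taped-down specimen is
rigid translation to good approximation, so registration is
translation-only phase cross-correlation: integer-pixel by default,
subpixel via Fourier upsampling (upsample factor 20, i.e. 1/20 px grid)
when requested. Every round is aligned directly to round 1 of a
configurable reference channel rather than chained pairwise, so
registration errors do not accumulate. The reported shift is the
displacement the moving round's content has undergone; applying its
negative re-aligns the round. Pixels shifted in from outside the frame
are zero-filled, flagged in a validity mask, and excluded from every
downstream statistic. Reported quality is the Pearson correlation of the
re-aligned pair over the valid overlap.

**Mean equalization.** Before round comparison, the second round is
scaled by the ratio of masked means so that a pure gain difference (the
antigen-retrieval effect) cannot masquerade as pattern change.

## Round comparison

The minmax decomposition of equalized rounds *a*, *b* is
`shared = min(a, b)` and `difference = |a − b|`; the two reconstruct
`max(a, b)` pixelwise (exactly in real arithmetic; to one float rounding
of the sum in practice). The decomposition is symmetric in its inputs. A
signed variant (`difference = a − b`) is available for diagnostic
display; the absolute form is the default. The log₂ ratio
`(shared + ε)/(difference + ε)` with pseudocount ε = 1 intensity unit is
histogrammed on bins symmetric about 0; out-of-range values land in the
end bins so counts conserve the number of valid pixels. Pearson
correlation is computed over the valid mask on the
background-subtracted, equalized images.

Elution efficiency is `100 · (1 − Σ post / Σ pre)` over the valid mask.
Note a practical bias: on noisy images with imperfect background removal
the post-elution sum contains a noise floor, so the measured efficiency
underestimates the true stripped fraction. In the simulator's noise-free
regime the estimator recovers the configured residual fraction to
Monte-Carlo error; on noisy data, restricting the mask to regions of
genuine pre-elution signal reduces the bias.

## Occupancy statistics

A pixel is *occupied* in a channel when its intensity is at or above the
channel's threshold. Two thresholding rules are provided:

* **Otsu** (256-bin histogram): the cut minimizing weighted intra-class
  variance, delegated to `skimage.filters.threshold_otsu`; the test suite
  checks it against an exhaustive search over all histogram cuts.
* **Percentile**: the smallest pixel value such that the fraction of
  valid pixels strictly below it exceeds the requested fraction — i.e.
  the smallest attainable fraction at or above the request, with exact
  ties on quantized data resolved toward including more pixels below
  (on values 1..100 at 0.5 the threshold is 52, putting 51 pixels below).
  With heavy ties at the top of the range a requested fraction may be
  unattainable; the threshold then lands above the maximum and the
  channel has no occupied pixels, which downstream statistics record as
  missing.

The joint occupancy pattern of every valid pixel goes into a 2ᵏ-cell
table (channel 0 in the most significant bit). Mutual independence is
tested by chi-squared: expected counts are n · Π per-channel bit
probabilities from the empirical marginals; df = 2ᵏ − 1 − k (2ᵏ − 1 free
cells minus k fitted marginals); no continuity correction. Expected cells
below a configurable floor (default 1) attach a warning; a channel with
zero occupied or zero unoccupied pixels makes the test undefined and is
an error.

The exceedance sweep thresholds every channel at its own percentile
(common *fraction of pixels below*, not common intensity), from 1% to
95% in 1-point steps by default, and reports
`P(joint)/Π P(marginal)` per channel subset — by default all pairs plus
the full set. Ratios where a marginal occupancy is zero are recorded as
NaN, never 0 or ∞.

**Caveat carried on every result:** pixels are treated as independent
observations. Diffraction-blurred images are spatially autocorrelated, so
the effective sample size is below `n_pixels` and p-values on real
micrographs are anti-conservative. The table reports `n_pixels` so the
user can judge; no correction is applied (a permutation or block
bootstrap null would be the natural extension). The type-I error
calibration in the test suite therefore simulates i.i.d. pixels, and
passing it says nothing about autocorrelated real data.

## Depth profiling

The specimen exterior is the complement of a binary mask (user-supplied
masks are first-class; a convenience mask — Otsu on a smoothed copy,
largest connected component — is provided). Each in-mask voxel gets its
Euclidean distance to the nearest exterior voxel
(`scipy.ndimage.distance_transform_edt`, anisotropic spacing respected);
intensity is averaged in contiguous distance bins (default width 1 px or
1 physical unit when spacing is given). Empty bins are NaN; an optional
exclusion mask (nucleus, spindle) removes voxels from the averages. A
uniformly labeled specimen yields a flat profile; penetration failure
shows as decay with depth.

## The simulator

`SceneConfig`/`generate_scene`/`render_round` emulate the statistical
structure the analyses assume:

* **Sites and domains.** `n_sites` punctate epitope sites are assigned
  uniformly to `n_domains` domain centers (uniform over the image) and
  scattered around them with σ = 2 px. A domain site carries channel c's
  epitope with probability π_c (`channel_affinities`), conditionally
  independently given the domain — so triple membership occurs at rate
  Π π_c among domain sites, the planted colocalization.
  `background_site_rate` additional sites per channel carry exactly one
  channel's epitope, providing the independent floor.
* **Rounds.** Each round each channel labels its available sites
  independently with probability `label_prob` (default 0.8) — the
  stochastic epitope labeling that keeps inter-round correlation below 1.
  Spots are rendered by bilinear splatting at subpixel positions and a
  Gaussian PSF (σ = 1.5 px default), with integrated amplitude
  `spot_amplitude · round_gain^(round−1)`; `round_gain` (default 1.15)
  models the incidental antigen-retrieval brightening over the first
  cycles, whose true magnitude is uncharacterized — it is a free
  parameter here. Cumulative rigid drift (default (1.0, −0.5) px/round),
  a static smooth low-frequency background per channel, and additive
  Gaussian noise complete the image; values are clipped to the unsigned
  16-bit range.
* **Elution.** A post-elution image retains each of the *same* labeled
  sites with probability `residual_fraction` (default 0.055, i.e. the
  ~94.5 % stripping regime), so the expected post/pre signal ratio is the
  residual fraction and the residual image is sparse puncta, not a
  uniform dimming.
* **Determinism.** One root seed is split per round/channel/phase through
  `numpy` seed sequences; identical config + seed is bit-identical, and
  any single round can be regenerated alone.

What the simulator does **not** model: photon (Poisson) noise and camera
gain, PSF anisotropy or depth variation, photobleaching kinetics,
antibody off-target binding, spot amplitude heterogeneity, chromatic
aberration, non-rigid deformation, or 3-D optics (depth profiling is
tested on analytically constructed volumes instead). Tests passing on
simulated scenes therefore validate the statistical machinery, not the
microscope physics of any given dataset.

## Numerical choices and edge cases

* Intensities are promoted to float64 at the I/O boundary; TIFFs are
  written as uint16 (grayscale, one page per channel, one file per
  round) with a tab-separated manifest.
* Constant images are rejected by Otsu and by the Pearson correlation
  (zero variance) rather than returning arbitrary values; all-zero
  images are rejected by registration (no correlation peak).
* Otsu ties (two cuts with intra-class variance equal to float
  resolution) resolve to the lower cut via the underlying argmax.
* The ratio histogram's default half-range is the largest absolute
  log-ratio observed; passing `limit` fixes it for comparability across
  pairs.
* The chi-squared expected-count floor warns rather than refuses: at
  extreme sweep percentiles small expected cells are routine and the
  exceedance ratio, not the test, is the instrument of record there.
* Problem sizes in the test suite and the reproduction script (96–256 px
  scenes, 100-seed elution averages, 2000-simulation calibration at 10⁴
  pixels, 500-run exceedance null) were chosen as the smallest sizes at
  which the binomial/χ² sampling bounds asserted are meaningful.

## Known limitations

* No spatial-autocorrelation-corrected inference (see caveat above).
* Registration is translation-only; rotation, scaling and non-rigid
  warps are out of scope, as is chromatic-aberration correction.
* No object-level (punctum) segmentation: pixels are the sampling unit
  throughout, matching the occupancy framework's definition.
* The elution-efficiency estimator is noise-floor-biased on noisy data
  (see Round comparison).
* Colocalization metrics beyond Pearson (Manders, Costes) are not
  provided; the round-comparison question here is reproducibility, not
  cross-protein colocalization, which the occupancy framework handles.
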