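# remikit

Analysis chain for **resin-embedded multicycle imaging (REMI)** and related
cyclic multiplexed immunofluorescence: the same specimen is labeled with an
antibody, imaged, stripped by high-pH elution, and relabeled — round after
round — so that many proteins can be mapped onto one membrane or cell.
`remikit` quantifies what such experiments need quantified:

* **How well did elution work?** The *elution efficiency* is the percent of
  total fluorescence removed between a pre- and post-elution image,
  `100 · (1 − Σ post / Σ pre)`.
* **How reproducible is labeling between rounds?** Two aligned,
  brightness-equalized rounds *a*, *b* are decomposed with the **minmax**
  construction into a *shared* channel `min(a, b)` and a *difference*
  channel `|a − b|` (shared + difference = `max(a, b)` pixelwise), along
  with the Pearson correlation between rounds and a histogram of the
  per-pixel log₂ shared/difference ratio.
* **Do k proteins colocalize?** Each channel is binarized (Otsu or
  percentile threshold); every pixel's joint occupancy pattern is tallied
  into a 2ᵏ-cell contingency table; mutual independence is tested by
  chi-squared against the product of the empirical marginals
  (df = 2ᵏ − 1 − k); and the **exceedance ratio**
  `P(jointly occupied) / Π P(occupied)` is swept over thresholds placing
  1%–95% of pixels below the cut. Under independence the ratio is 1; genuine
  multi-protein domains push the triple-occupancy ratio far above the
  pairwise ones at high thresholds.
* **How deep does labeling reach?** Mean intensity binned by Euclidean
  distance from the specimen exterior (2-D or 3-D, anisotropic voxels),
  with optional exclusion masks for bright confounders.

Supporting stages: rolling-ball background subtraction (default radius
50 px), translation-only inter-round registration by phase
cross-correlation (integer or subpixel) with validity-mask propagation,
and mean equalization. A synthetic-scene simulator generates multi-round,
multi-channel images with planted domain colocalization, stochastic
per-round labeling, residual post-elution signal, round-over-round gain,
drift, background and noise — so the whole chain is testable end to end
without microscope data.

## Worked example

Run the bundled demo (simulated 3-round, 3-channel scene with planted
three-way colocalization domains):

```sh
remikit run --config examples/run_config.yaml --out demo --seed 1
```

The run writes CSVs into `demo/`. With seed 1:

* `round_comparison.csv` — Pearson r = **0.946** between rounds 1 and 2 of
  channel 0 after equalization: the same epitope field relabeled with
  stochastic dropout (label probability 0.8) stays highly but imperfectly
  correlated, the signature of stochastic epitope labeling.
* `chi2_summary.csv` — Chi² = 1.39 × 10⁶, df = **4**, p ≈ 0 over 65 024
  valid pixels: the three channels are very far from mutually independent,
  as they should be with planted shared domains. (The table also carries
  the caveat that pixels are treated as independent observations —
  diffraction blur makes real p-values anti-conservative.)
* `exceedance_curve.csv` — at the 90th-percentile threshold the pairwise
  ratios are ≈ 6.3 while the triple-occupancy ratio is ≈ **58**: triple
  occupancy detects the planted domain structure far more sensitively than
  any doublet, and the gap widens with threshold.
* `registration_shifts.csv` — the simulated cumulative drift
  (1.0, −0.5) px/round is recovered to the nearest pixel.
* `depth_profile.csv` — mean intensity per 1-px shell of distance from the
  specimen-mask exterior.

Python API equivalents live in `remikit` (`minmax_decompose`,
`exceedance_sweep`, `chi2_mutual_independence`, `profile_by_depth`, …);
the CLI subcommands `simulate`, `preprocess`, `minmax`, `occupancy`,
`depth` run individual stages.

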