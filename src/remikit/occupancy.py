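"""Pixel-occupancy colocalization statistics.

Each of *k* channels is binarized — a pixel is *occupied* when its
intensity reaches the channel's threshold — and the joint occupancy
pattern of every valid pixel is tallied into a 2^k-cell contingency
table.  Two inferential tools sit on the table:

* a chi-squared goodness-of-fit test of *mutual independence*, comparing
  observed cell counts with the counts expected from the product of the
  empirical per-channel marginals (df = 2^k - 1 - k: 2^k - 1 free cells
  minus k fitted marginal probabilities);

* the *exceedance ratio*, the observed joint-occupancy probability of a
  channel subset divided by the product of its marginal occupancy
  probabilities — exactly 1 in expectation under independence, above 1
  where the channels co-occupy pixels more often than chance.  Sweeping
  the per-channel thresholds from the 1st to the 95th intensity
  percentile traces how the exceedance develops across the dynamic range;
  triple occupancy responds more sensitively than the pairwise doublets
  when a genuine three-way domain structure is present.

A caveat carried on every test result: pixels are treated as independent
observations.  Diffraction-blurred images are spatially autocorrelated,
so the effective sample size is smaller than ``n_pixels`` and p-values
are anti-conservative on real micrographs; the table reports ``n_pixels``
so users can judge, but no correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "OccupancyTable",
    "ExceedanceCurve",
    "Chi2Result",
    "otsu_threshold",
    "percentile_threshold",
    "build_occupancy_table",
    "chi2_mutual_independence",
    "exceedance_sweep",
    "DEFAULT_SWEEP_PERCENTILES",
]

#: Default threshold sweep: 1% to 95% of pixels below threshold, 1-pt steps.
DEFAULT_SWEEP_PERCENTILES = np.round(np.arange(0.01, 0.9501, 0.01), 4)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram cut minimizing intra-class variance.

    Computed over an ``n_bins``-bin histogram (256 by default).  Pixels at
    or above the returned value count as occupied.  A constant image has
    no two classes to separate and raises.
    """
    image = np.asarray(image, dtype=np.float64)
    flat = image.ravel()
    if flat.size == 0 or np.all(flat == flat[0]):
        raise ValueError("constant image: Otsu threshold undefined")
    return float(threshold_otsu(flat, nbins=n_bins))


def percentile_threshold(image: np.ndarray, percentile: float,
                         mask: np.ndarray | None = None) -> float:
    """Threshold putting (just over) the requested fraction of pixels below it.

    Returns the smallest pixel value ``t`` such that the fraction of valid
    pixels strictly below ``t`` exceeds ``percentile`` — the smallest
    attainable fraction at or above the request, with exact ties on
    quantized data resolved toward including *more* pixels below.  On
    values 1..100 (one each) at percentile 0.5 this yields t = 52, i.e.
    51 pixels below.  If even excluding everything but the maximum cannot
    reach the request (heavy ties at the top), the threshold lands just
    above the maximum and no pixel is occupied.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must lie in (0, 1), got {percentile}")
    image = np.asarray(image, dtype=np.float64)
    values = image.ravel() if mask is None else image[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("no valid pixels")
    values = np.sort(values)
    n = values.size
    # fraction strictly below values[i] is i/n once duplicates are skipped;
    # find the first index where that fraction exceeds the request.
    k = int(np.ceil(percentile * n))
    if k / n <= percentile:  # exact tie on the grid -> include more below
        k += 1
    while k < n and values[k] == values[k - 1]:
        k += 1  # duplicated value: cut must clear the whole run
    if k >= n:
        return float(np.nextafter(values[-1], np.inf))
    return float(values[k])


@dataclass(frozen=True)
class OccupancyTable:
    """Joint occupancy counts of k binarized channels.

    ``counts[i]`` is the number of valid pixels whose occupancy pattern,
    read as a binary number with channel 0 in the most significant bit,
    equals ``i``.  Counts sum to ``n_pixels``.
    """

    k: int
    counts: np.ndarray
    n_pixels: int
    channel_names: tuple[str, ...]
    thresholds: tuple[float, ...] | None = None

    def marginal_occupied(self, channel: int) -> int:
        """Pixels occupied in ``channel``, regardless of the others."""
        bit = self.k - 1 - channel
        idx = np.arange(2 ** self.k)
        return int(self.counts[(idx >> bit) & 1 == 1].sum())

    def pattern_labels(self) -> list[str]:
        return [format(i, f"0{self.k}b") for i in range(2 ** self.k)]


def build_occupancy_table(masks: Sequence[np.ndarray],
                          valid: np.ndarray | None = None,
                          channel_names: Sequence[str] | None = None,
                          thresholds: Sequence[float] | None = None
                          ) -> OccupancyTable:
    """Tally every valid pixel into its joint occupancy pattern.

    ``masks`` are k boolean occupancy images of one shape; ``valid``
    restricts the tally (registration borders, ROI).  Requires k >= 2.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    k = len(masks)
    if k < 2:
        raise ValueError(f"need at least 2 channels, got {k}")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("occupancy masks disagree on shape")
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != shape:
            raise ValueError("validity mask shape must match")

    code = np.zeros(shape, dtype=np.int64)
    for m in masks:  # channel 0 ends in the most significant bit
        code = (code << 1) | m.astype(np.int64)
    counts = np.bincount(code[valid].ravel(), minlength=2 ** k)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(k))
    return OccupancyTable(
        k=k, counts=counts, n_pixels=int(valid.sum()),
        channel_names=tuple(channel_names),
        thresholds=tuple(float(t) for t in thresholds) if thresholds is not None else None,
    )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    n_pixels: int
    warnings: tuple[str, ...] = ()


def chi2_mutual_independence(table: OccupancyTable,
                             expected_floor: float = 1.0) -> Chi2Result:
    """Chi-squared test of mutual independence of the k channels.

    Expected count of a pattern is ``n_pixels`` times the product over
    channels of the empirical probability of that channel's bit value;
    the statistic is sum (obs - exp)^2 / exp over all 2^k cells, with
    df = 2^k - 1 - k and the p-value from the chi-squared upper tail.
    No continuity correction.  Cells whose expected count falls below
    ``expected_floor`` add a warning to the result (the asymptotic
    approximation degrades); a channel with zero occupied or zero
    unoccupied pixels makes the test degenerate and raises.
    """
    if table.n_pixels <= 0:
        raise ValueError("empty table")
    n = table.n_pixels
    p_occ = np.array([table.marginal_occupied(c) / n for c in range(table.k)])
    if np.any(p_occ == 0.0) or np.any(p_occ == 1.0):
        bad = [table.channel_names[c] for c in range(table.k)
               if p_occ[c] in (0.0, 1.0)]
        raise ValueError(
            f"degenerate marginal occupancy in channel(s) {bad}: "
            "mutual-independence test undefined"
        )
    idx = np.arange(2 ** table.k)
    expected = np.full(2 ** table.k, float(n))
    for c in range(table.k):
        bit = (idx >> (table.k - 1 - c)) & 1
        expected *= np.where(bit == 1, p_occ[c], 1.0 - p_occ[c])
    statistic = float(np.sum((table.counts - expected) ** 2 / expected))
    df = 2 ** table.k - 1 - table.k
    p_value = float(stats.chi2.sf(statistic, df))
    warnings = ()
    n_low = int(np.sum(expected < expected_floor))
    if n_low:
        warnings = (
            f"{n_low} of {2 ** table.k} expected cell counts fall below "
            f"{expected_floor}; the chi-squared approximation may be poor",
        )
    return Chi2Result(statistic=statistic, df=df, p_value=p_value,
                      expected=expected, n_pixels=n, warnings=warnings)


@dataclass(frozen=True)
class ExceedanceCurve:
    """Observed/expected joint-occupancy ratios across a threshold sweep.

    ``ratios[subset][i]`` is the exceedance of that channel subset at
    ``percentiles[i]``; NaN marks percentiles where a marginal occupancy
    was zero and the ratio is undefined (never recorded as 0 or inf).
    """

    percentiles: np.ndarray
    subsets: tuple[tuple[int, ...], ...]
    ratios: dict[tuple[int, ...], np.ndarray]
    channel_names: tuple[str, ...] = ()

    def subset_label(self, subset: tuple[int, ...]) -> str:
        names = self.channel_names or tuple(
            f"ch{i}" for i in range(max(max(s) for s in self.subsets) + 1))
        return "+".join(names[i] for i in subset)


def default_subsets(k: int) -> tuple[tuple[int, ...], ...]:
    """All pairs plus the full k-set (the doublets and the full multiple)."""
    pairs = tuple(itertools.combinations(range(k), 2))
    return pairs + ((tuple(range(k)),) if k > 2 else ())


def exceedance_sweep(images: Sequence[np.ndarray],
                     percentiles: Sequence[float] | None = None,
                     subsets: Sequence[Sequence[int]] | None = None,
                     valid: np.ndarray | None = None,
                     channel_names: Sequence[str] | None = None
                     ) -> ExceedanceCurve:
    """Sweep per-channel percentile thresholds and compute exceedance ratios.

    At each percentile p every channel is thresholded at its *own*
    p-quantile (a common fraction of pixels below, not a common
    intensity), pixels at or above the threshold are occupied, and for
    each requested subset the ratio P(jointly occupied) / prod
    P(occupied) is recorded.  Default grid: 1%..95% in 1-point steps;
    default subsets: all pairs plus the full set.
    """
    images = [np.asarray(im, dtype=np.float64) for im in images]
    k = len(images)
    if k < 2:
        raise ValueError("need at least 2 channels")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("images disagree on shape")
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
    if percentiles is None:
        percentiles = DEFAULT_SWEEP_PERCENTILES
    percentiles = np.asarray(percentiles, dtype=np.float64)
    if percentiles.size == 0 or np.any((percentiles <= 0) | (percentiles >= 1)):
        raise ValueError("percentile grid must lie within (0, 1)")
    if subsets is None:
        subsets = default_subsets(k)
    subsets = tuple(tuple(int(i) for i in s) for s in subsets)
    if not subsets:
        raise ValueError("empty subset list")
    for s in subsets:
        if len(s) < 2 or len(set(s)) != len(s) or any(i < 0 or i >= k for i in s):
            raise ValueError(f"invalid channel subset {s}")

    n_valid = int(valid.sum())
    flat = [im[valid] for im in images]
    ratios = {s: np.full(percentiles.size, np.nan) for s in subsets}
    for j, p in enumerate(percentiles):
        occ = []
        for c in range(k):
            t = percentile_threshold(flat[c], float(p))
            occ.append(flat[c] >= t)
        p_marg = np.array([o.mean() for o in occ])
        for s in subsets:
            if np.any(p_marg[list(s)] == 0.0):
                continue  # undefined: leave NaN
            joint = np.logical_and.reduce([occ[i] for i in s]).sum() / n_valid
            ratios[s][j] = joint / np.prod(p_marg[list(s)])
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(k))
    return ExceedanceCurve(percentiles=percentiles, subsets=subsets,
                           ratios=ratios, channel_names=tuple(channel_names))
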