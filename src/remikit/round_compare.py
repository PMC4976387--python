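"""Inter-round labeling reproducibility.

Two aligned, brightness-equalized labeling rounds *a* and *b* of the same
marker are compared through the *minmax decomposition*: a two-channel
composite whose "shared" channel is the pixelwise minimum (the signal the
rounds agree on) and whose "difference" channel is the pixelwise absolute
difference (the signal unique to either round).  The two reconstruct the
pixelwise maximum exactly.  On top of that sit the log-ratio histogram of
shared to difference signal, the Pearson correlation between rounds, and
the elution efficiency (fraction of total signal stripped between a
pre-elution and a post-elution image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MinmaxResult",
    "minmax_decompose",
    "ratio_histogram",
    "elution_efficiency",
]


@dataclass(frozen=True)
class MinmaxResult:
    """Minmax decomposition of a round pair.

    ``shared`` (the composite's "green" channel) is the pixelwise min of
    the two rounds; ``difference`` (the "red" channel) is the pixelwise
    absolute difference by default, or the signed difference a - b when
    requested.  ``pearson_r`` is computed over the valid mask.
    """

    shared: np.ndarray
    difference: np.ndarray
    pearson_r: float
    signed: bool = False


def _as_pair(a, b, mask):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match images")
        if not mask.any():
            raise ValueError("empty mask")
    return a, b, mask


def minmax_decompose(a: np.ndarray, b: np.ndarray,
                     mask: np.ndarray | None = None,
                     signed: bool = False) -> MinmaxResult:
    """Decompose rounds ``a`` and ``b`` into shared and difference channels.

    shared = min(a, b); difference = |a - b| (or a - b with ``signed``);
    shared + |difference| = max(a, b) pixelwise.  Inputs should already be
    background-subtracted, registered and mean-equalized.  The Pearson
    correlation is taken over the ``mask``; zero variance in either round
    makes it undefined and raises.
    """
    a, b, mask = _as_pair(a, b, mask)
    shared = np.minimum(a, b)
    difference = (a - b) if signed else np.abs(a - b)
    av, bv = a[mask], b[mask]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    if np.array_equal(av, bv):
        r = 1.0
    else:
        r = float(stats.pearsonr(av, bv).statistic)
    return MinmaxResult(shared=shared, difference=difference,
                        pearson_r=r, signed=signed)


def ratio_histogram(a: np.ndarray, b: np.ndarray,
                    n_bins: int = 64,
                    pseudocount: float = 1.0,
                    mask: np.ndarray | None = None,
                    limit: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the per-pixel log2 shared-to-difference ("green to red") ratio.

    The ratio is ``(shared + pseudocount) / (difference + pseudocount)``;
    a pseudocount of one intensity unit keeps zero-difference pixels
    finite.  Bin edges are symmetric about 0; ``limit`` sets the half
    range (default: the largest absolute log-ratio observed) and values
    beyond it land in the end bins, so counts always sum to the number of
    valid pixels.

    Returns ``(counts, bin_edges)``.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    a, b, mask = _as_pair(a, b, mask)
    shared = np.minimum(a, b)[mask]
    difference = np.abs(a - b)[mask]
    with np.errstate(divide="ignore"):
        log_ratio = np.log2((shared + pseudocount) / (difference + pseudocount))
    if limit is None:
        finite = np.abs(log_ratio[np.isfinite(log_ratio)])
        limit = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    edges = np.linspace(-limit, limit, n_bins + 1)
    clipped = np.clip(log_ratio, -limit, limit)
    counts, _ = np.histogram(clipped, bins=edges)
    return counts, edges


def elution_efficiency(pre: np.ndarray, post: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Percent of total signal stripped by elution.

    ``100 * (1 - sum(post)/sum(pre))`` over the mask.  Inputs should be
    background-subtracted and registered; a zero pre-elution sum leaves
    the efficiency undefined and raises.  Invariant under a common
    rescaling of both images.
    """
    pre, post, mask = _as_pair(pre, post, mask)
    total_pre = pre[mask].sum()
    if total_pre <= 0:
        raise ValueError("zero pre-elution signal: efficiency undefined")
    return float(100.0 * (1.0 - post[mask].sum() / total_pre))
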