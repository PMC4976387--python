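"""Independent brute-force oracles shared across test modules.

These deliberately avoid the code paths they check: exhaustive searches
and per-element loops only.
"""

import numpy as np


def otsu_oracle_cuts(data, nbins=256):
    """All histogram cuts achieving the minimal weighted intra-class variance.

    Returns the bin centers of every cut whose intra-class variance ties
    the minimum to within floating-point resolution.
    """
    counts, edges = np.histogram(data, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    n = counts.sum()
    within = np.full(nbins - 1, np.inf)
    for idx in range(nbins - 1):
        c1, c2 = counts[:idx + 1], counts[idx + 1:]
        if c1.sum() == 0 or c2.sum() == 0:
            continue
        m1 = (c1 * centers[:idx + 1]).sum() / c1.sum()
        m2 = (c2 * centers[idx + 1:]).sum() / c2.sum()
        v1 = (c1 * (centers[:idx + 1] - m1) ** 2).sum() / c1.sum()
        v2 = (c2 * (centers[idx + 1:] - m2) ** 2).sum() / c2.sum()
        within[idx] = (c1.sum() * v1 + c2.sum() * v2) / n
    best = within.min()
    tied = np.flatnonzero(within <= best * (1 + 1e-10))
    return centers[tied]


def brute_force_distance(mask, spacing=None):
    """Exhaustive nearest-exterior-voxel search (any dimensionality)."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.ones(mask.ndim) if spacing is None else np.asarray(spacing, float)
    coords = np.argwhere(~mask) * spacing
    out = np.zeros(mask.shape)
    for idx in np.argwhere(mask):
        d = np.sqrt((((idx * spacing) - coords) ** 2).sum(axis=1))
        out[tuple(idx)] = d.min()
    return out
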