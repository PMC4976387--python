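"""Background subtraction, inter-round registration, mean equalization.

Every comparison between rounds runs on images that have been background
subtracted (rolling-ball, default radius 50 px), rigidly aligned to a
reference round by Fourier cross-correlation, and brightness-equalized.
Pixels shifted in from outside the frame are tracked in a validity mask
that downstream statistics must respect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening
from skimage.registration import phase_cross_correlation

__all__ = [
    "DEFAULT_ROLLING_BALL_RADIUS",
    "RegistrationResult",
    "rolling_ball_subtract",
    "register_rounds",
    "apply_shift",
    "equalize_means",
]

#: Default structuring-element radius for background subtraction, px.
DEFAULT_ROLLING_BALL_RADIUS = 50


def rolling_ball_subtract(image: np.ndarray,
                          radius: int = DEFAULT_ROLLING_BALL_RADIUS) -> np.ndarray:
    """Subtract a rolling-ball background estimate from ``image``.

    The background is the grayscale morphological opening of the image
    with a disk of the given radius — the flat-element realization of the
    classic rolling-ball filter.  The result is clipped at zero.  Opening
    is idempotent, so re-subtracting from the output removes nothing more.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    image = np.asarray(image, dtype=np.float64)
    background = opening(image, disk(int(radius)))
    return np.clip(image - background, 0.0, None)


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated rigid displacement of a moving round against the reference.

    ``shift`` is (dy, dx): the translation the moving image's content has
    undergone relative to the reference, so applying ``-shift`` to the
    moving image aligns it.  ``peak_quality`` is the Pearson correlation
    between the reference and the re-aligned moving image over the valid
    overlap (1.0 for a perfect rigid translation of identical content).
    """

    shift: tuple[float, float]
    reference_round: int = 1
    peak_quality: float = float("nan")


def register_rounds(reference: np.ndarray, moving: np.ndarray,
                    subpixel: bool = False,
                    reference_round: int = 1,
                    upsample_factor: int = 20) -> RegistrationResult:
    """Estimate the translation of ``moving`` relative to ``reference``.

    Translation-only, via phase cross-correlation in the frequency
    domain; integer-pixel by default, with optional subpixel refinement
    (Fourier upsampling).  Rotation and non-rigid warps are out of scope:
    inter-round drift of a fixed specimen is rigid to good approximation.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {moving.shape}"
        )
    if not np.any(reference) or not np.any(moving):
        raise ValueError("all-zero input: no correlation peak exists")

    # plain cross-correlation, not spectrally whitened phase correlation:
    # whitening biases the peak when rounds partially decorrelate
    # (stochastic relabeling) or carry fresh noise
    est, _, _ = phase_cross_correlation(
        reference, moving,
        upsample_factor=upsample_factor if subpixel else 1,
        normalization=None,
    )
    # phase_cross_correlation returns the shift that registers `moving`
    # onto `reference`; the drift the content underwent is its negative.
    shift = tuple(float(-s) + 0.0 for s in est)  # + 0.0 normalizes -0.0

    aligned, valid = apply_shift(moving, tuple(-s for s in shift))
    ref_v = reference[valid]
    mov_v = aligned[valid]
    if ref_v.std() > 0 and mov_v.std() > 0:
        quality = float(np.corrcoef(ref_v, mov_v)[0, 1])
    else:
        quality = float("nan")
    return RegistrationResult(shift=shift, reference_round=reference_round,
                              peak_quality=quality)


def apply_shift(image: np.ndarray, shift: tuple[float, float]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Translate ``image`` by ``shift`` = (dy, dx).

    Returns ``(shifted, valid)`` where ``valid`` marks pixels whose value
    came from inside the original frame; shifted-in border pixels are 0
    and invalid, and must be excluded from downstream statistics.
    Integer shifts are exact; fractional shifts use linear interpolation.
    """
    image = np.asarray(image, dtype=np.float64)
    dy, dx = shift
    if float(dy).is_integer() and float(dx).is_integer():
        dy, dx = int(dy), int(dx)
        shifted = np.zeros_like(image)
        valid = np.zeros(image.shape, dtype=bool)
        src_r = slice(max(0, -dy), image.shape[0] - max(0, dy))
        src_c = slice(max(0, -dx), image.shape[1] - max(0, dx))
        dst_r = slice(max(0, dy), image.shape[0] + min(0, dy))
        dst_c = slice(max(0, dx), image.shape[1] + min(0, dx))
        shifted[dst_r, dst_c] = image[src_r, src_c]
        valid[dst_r, dst_c] = True
        return shifted, valid
    shifted = ndimage.shift(image, (dy, dx), order=1, mode="constant", cval=0.0)
    ones = np.ones_like(image)
    weight = ndimage.shift(ones, (dy, dx), order=1, mode="constant", cval=0.0)
    valid = weight > 1.0 - 1e-9
    shifted[~valid] = 0.0
    return shifted, valid


def equalize_means(a: np.ndarray, b: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Scale ``b`` so its mean over ``mask`` equals that of ``a``.

    Returns ``b * mean(a)/mean(b)`` with means over the mask (default:
    all pixels).  Raises on a non-positive mean of ``b``, where no gain
    can equalize the brightnesses.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mean_a, mean_b = a.mean(), b.mean()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match images")
        if not mask.any():
            raise ValueError("empty mask")
        mean_a, mean_b = a[mask].mean(), b[mask].mean()
    if mean_b <= 0:
        raise ValueError(f"mean of b over mask is {mean_b}; cannot equalize")
    return b * (mean_a / mean_b)
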