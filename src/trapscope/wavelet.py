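"""À trous (undecimated) wavelet decomposition with B3-spline scaling kernel.

The "with holes" algorithm smooths the image with a separable B3-spline
kernel whose taps are spaced ``2**(j-1)`` pixels apart at scale ``j``; the
wavelet plane at each scale is the difference between successive smooths.
Because no decimation takes place, every plane keeps the resolution of the
input and the planes plus the final smooth residual sum back to the input
exactly.  This preserves the original image resolution while letting noise
be identified and removed scale by scale, which is why it is the standard
multiscale detector for spots and zones in fluorescence microscopy.

Significant coefficients are those exceeding ``k`` times the per-scale
noise standard deviation.  The scale-1 sigma is estimated robustly from the
finest plane (median absolute deviation / 0.6745) and propagated to coarser
scales with fixed factors measured once from unit-variance white noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .errors import ScaleOverflowError, ValidationError
from .image import ImageChannel

#: Separable scaling kernel: B3-spline [1, 4, 6, 4, 1] / 16.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: Border extension rule (reflect about the edge pixel, no repeat).
BOUNDARY_MODE = "mirror"

#: Std. dev. of each wavelet plane of unit-variance 2-D white noise,
#: scales 1..6.  Monte-Carlo estimate over 50 seeded 512x512 rasters.
NOISE_SIGMA_WHITE = np.array(
    [0.890771, 0.200718, 0.085789, 0.041499, 0.020710, 0.010420]
)

#: Propagation factors sigma_j / sigma_1 used by :func:`estimate_noise_sigma`.
NOISE_SIGMA_FACTORS = NOISE_SIGMA_WHITE / NOISE_SIGMA_WHITE[0]

_MAD_TO_SIGMA = 0.6745  # Phi^-1(0.75): MAD of a Gaussian in sigma units


@dataclass(frozen=True)
class WaveletDecomposition:
    """Ordered wavelet planes w_1..w_J plus the smooth residual c_J.

    Invariant: ``sum(planes) + residual`` reproduces the input raster to
    within 1e-10 relative error (telescoping by construction).
    """

    planes: list[np.ndarray]
    residual: np.ndarray
    boundary_mode: str = BOUNDARY_MODE

    @property
    def n_scales(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.residual.shape


@dataclass(frozen=True)
class SignificanceMask:
    """Per-scale boolean masks of coefficients with |w_j| > k * sigma_j.

    ``positive`` additionally requires w_j > 0 (bright-on-dark structures,
    the immunofluorescence regime); zone construction uses it.
    """

    per_scale: list[np.ndarray]
    positive: list[np.ndarray]
    k: float
    sigma_per_scale: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.per_scale)


def export_decomposition(decomp: "WaveletDecomposition", path) -> None:
    """Write planes + residual as a multi-page 32-bit float TIFF."""
    import tifffile

    stack = np.stack(decomp.planes + [decomp.residual]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack", metadata={
        "pages": [f"w{j + 1}" for j in range(decomp.n_scales)] + ["residual"],
        "boundary_mode": decomp.boundary_mode,
    })


def max_scales(shape: tuple[int, int]) -> int:
    """Largest J such that the dilated kernel fits: 2**(J-1) * 4 < min(shape)."""
    j = 1
    while (2 ** j) * 4 < min(shape):
        j += 1
    return j


def _as_pixels(channel) -> np.ndarray:
    if isinstance(channel, ImageChannel):
        return channel.pixels
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D raster")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("raster contains non-finite values")
    return arr


def _smooth(arr: np.ndarray, scale_index: int) -> np.ndarray:
    """One à trous smoothing step: B3 kernel dilated by 2**scale_index."""
    step = 2 ** scale_index
    kernel = np.zeros(4 * step + 1)
    kernel[::step] = B3_KERNEL
    out = correlate1d(arr, kernel, axis=0, mode=BOUNDARY_MODE)
    return correlate1d(out, kernel, axis=1, mode=BOUNDARY_MODE)


def atrous_decompose(channel, n_scales: int) -> WaveletDecomposition:
    """Decompose a raster into ``n_scales`` wavelet planes plus residual.

    Raises :class:`ScaleOverflowError` if the dilated kernel at the coarsest
    scale would not fit inside the raster.
    """
    arr = _as_pixels(channel)
    if n_scales < 1:
        raise ValidationError(f"n_scales must be >= 1, got {n_scales}")
    feasible = max_scales(arr.shape)
    if 2 ** (n_scales - 1) * 4 >= min(arr.shape):
        raise ScaleOverflowError(n_scales, feasible)
    planes = []
    current = arr
    for j in range(n_scales):
        smoothed = _smooth(current, j)
        planes.append(current - smoothed)
        current = smoothed
    return WaveletDecomposition(planes=planes, residual=current)


def atrous_reconstruct(
    decomp: WaveletDecomposition, mask: SignificanceMask | None = None
) -> np.ndarray:
    """Sum planes + residual; with a mask, hard-threshold to flagged pixels."""
    if mask is not None:
        if mask.n_scales != decomp.n_scales:
            raise ValidationError(
                f"mask has {mask.n_scales} scales, decomposition {decomp.n_scales}"
            )
        for m in mask.per_scale:
            if m.shape != decomp.shape:
                raise ValidationError("mask shape does not match decomposition")
    out = decomp.residual.copy()
    for j, plane in enumerate(decomp.planes):
        if mask is None:
            out += plane
        else:
            out += np.where(mask.per_scale[j], plane, 0.0)
    return out


def estimate_noise_sigma(
    decomp: WaveletDecomposition, mode: str = "propagate"
) -> np.ndarray:
    """Per-scale noise standard deviations, estimated robustly.

    ``mode="propagate"``: the finest plane — dominated by noise in typical
    micrographs — gives a robust scale-1 sigma (MAD / 0.6745); coarser
    sigmas follow by multiplying with the fixed white-noise propagation
    factors (:data:`NOISE_SIGMA_FACTORS`).

    ``mode="per-scale"``: the MAD estimate is taken on every plane
    individually.  This stays calibrated when the noise is spatially
    correlated (e.g. after resampling the raster), where white-noise
    propagation underestimates coarse-scale noise; it assumes structures
    are sparse enough that the median of each plane is noise-dominated.
    """
    if decomp.n_scales < 1:
        raise ValidationError("decomposition has no planes")
    if mode == "per-scale":
        return np.array([
            float(np.median(np.abs(w))) / _MAD_TO_SIGMA for w in decomp.planes
        ])
    if mode != "propagate":
        raise ValidationError(f"unknown sigma mode {mode!r}")
    if decomp.n_scales > len(NOISE_SIGMA_FACTORS):
        raise ValidationError(
            f"noise propagation factors available for up to "
            f"{len(NOISE_SIGMA_FACTORS)} scales, got {decomp.n_scales}"
        )
    w1 = decomp.planes[0]
    sigma1 = float(np.median(np.abs(w1))) / _MAD_TO_SIGMA
    return sigma1 * NOISE_SIGMA_FACTORS[: decomp.n_scales]


def significant_coefficients(
    decomp: WaveletDecomposition, k: float = 3.0, sigma_mode: str = "propagate"
) -> SignificanceMask:
    """Flag coefficients with |w_j| > k * sigma_j at every scale."""
    if not (k > 0):
        raise ValidationError(f"k must be > 0, got {k}")
    sigmas = estimate_noise_sigma(decomp, mode=sigma_mode)
    per_scale = []
    positive = []
    for plane, sigma in zip(decomp.planes, sigmas):
        mask = np.abs(plane) > k * sigma
        per_scale.append(mask)
        positive.append(mask & (plane > 0))
    return SignificanceMask(
        per_scale=per_scale, positive=positive, k=float(k), sigma_per_scale=sigmas
    )
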