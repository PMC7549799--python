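"""Gaussian scale stack, difference-of-Gaussians, and statistical scale pruning.

The pipeline builds a single-octave stack of Gaussian-smoothed copies of the
ROI at scales sigma0 * k**i, takes adjacent differences (DoG), and then prunes
DoG samples against a threshold equal to the population standard deviation of
the DoG stack.  The pruning is the data-reduction step that makes downstream
extremum search cheap: samples failing the retention rule are masked out of
the keypoint candidate search entirely.

Two pruning rules are provided because the thresholding comparison
``D <= sigma_D`` can be read either as marking what to retain or as marking
what is redundant.  ``abs_le`` (default) reads it as a redundancy test on
magnitudes: samples with |D| <= sigma_D carry no salient structure and are
eliminated, which empirically removes a large fraction of samples without
touching the significant extrema.  ``signed_le`` reads it literally as a
retention rule (keep D <= sigma_D).  Both are first-class and tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import MIN_FEATURE_SIZE, GrayImage


@dataclass(frozen=True)
class ScaleStack:
    """Gaussian-smoothed levels L(x, y, sigma_i) with sigma_i = sigma0 * k**i."""

    levels: np.ndarray  # shape (n_levels, H, W)
    sigmas: np.ndarray  # shape (n_levels,), strictly increasing
    sigma0: float
    k: float

    def __post_init__(self) -> None:
        if self.levels.ndim != 3 or len(self.levels) != len(self.sigmas):
            raise ValueError("levels/sigmas mismatch")
        if len(self.sigmas) < 2:
            raise ValueError("a scale stack needs at least 2 levels")
        ratios = self.sigmas[1:] / self.sigmas[:-1]
        if not np.allclose(ratios, self.k, atol=1e-9):
            raise ValueError("sigmas must form a geometric progression with ratio k")


@dataclass(frozen=True)
class DoGStack:
    """Adjacent-level differences D_m = L(k*sigma) - L(sigma)."""

    diffs: np.ndarray  # shape (n_levels - 1, H, W)
    sigmas: np.ndarray  # lower sigma of each pair, shape (n_levels - 1,)
    k: float

    @property
    def n(self) -> int:
        return len(self.diffs)


@dataclass(frozen=True)
class ScaleThreshold:
    """Standard-deviation threshold sigma_D and the elementwise mean stack.

    ``value`` is the pooled population standard deviation over all DoG levels
    and pixels.  Under per-level pooling, ``per_level`` additionally carries
    one sigma per DoG level (the std of that level about the elementwise mean
    stack) and the retention rule compares each level against its own sigma.
    """

    value: float
    mean_stack: np.ndarray
    per_level: np.ndarray | None = None

    def level_value(self, m: int) -> float:
        return float(self.per_level[m]) if self.per_level is not None else self.value


@dataclass(frozen=True)
class ReducedDoG:
    """DoG stack plus the boolean retention mask from the sigma threshold."""

    diffs: np.ndarray
    sigmas: np.ndarray
    k: float
    retained: np.ndarray  # boolean, same shape as diffs

    @property
    def n(self) -> int:
        return len(self.diffs)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of size (2*radius + 1)^2.

    Values are proportional to exp(-(x^2 + y^2) / (2 sigma^2)) and sum to 1.
    The default radius ceil(3*sigma) captures > 99.7% of the mass per axis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = int(np.ceil(3.0 * sigma))
    if radius < 1:
        raise ValueError("radius must be >= 1")
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    kernel = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma * sigma))
    return kernel / kernel.sum()


def build_scale_stack(
    image: GrayImage, sigma0: float = 1.6, k: float = 2.0 ** 0.5, n_levels: int = 5
) -> ScaleStack:
    """Convolve the ROI with Gaussians at sigma0 * k**i, i = 0..n_levels-1.

    Replicate padding at the borders; each level is an explicit 2-D kernel
    convolution so the result is exactly the discrete Gaussian filter.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if k <= 1:
        raise ValueError("k must be > 1")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    if image.height < MIN_FEATURE_SIZE or image.width < MIN_FEATURE_SIZE:
        raise ValueError(
            f"image {image.height}x{image.width} too small for scale stack "
            f"(minimum {MIN_FEATURE_SIZE}x{MIN_FEATURE_SIZE})"
        )
    sigmas = sigma0 * k ** np.arange(n_levels, dtype=np.float64)
    levels = np.empty((n_levels, image.height, image.width))
    for i, sigma in enumerate(sigmas):
        # separable pass: 1-D kernel along each axis equals the 2-D product kernel
        radius = int(np.ceil(3.0 * sigma))
        ax = np.arange(-radius, radius + 1, dtype=np.float64)
        k1d = np.exp(-(ax * ax) / (2.0 * sigma * sigma))
        k1d /= k1d.sum()
        tmp = ndimage.correlate1d(image.pixels, k1d, axis=0, mode="nearest")
        levels[i] = ndimage.correlate1d(tmp, k1d, axis=1, mode="nearest")
    return ScaleStack(levels=levels, sigmas=sigmas, sigma0=sigma0, k=k)


def dog_differences(stack: ScaleStack) -> DoGStack:
    """Elementwise adjacent differences D_m = levels[m+1] - levels[m]."""
    return DoGStack(
        diffs=stack.levels[1:] - stack.levels[:-1],
        sigmas=stack.sigmas[:-1],
        k=stack.k,
    )


def dog_threshold(dog: DoGStack, pooling: str = "pooled") -> ScaleThreshold:
    """Population standard deviation of the DoG stack, used as retention threshold.

    The elementwise mean stack D-bar is taken over the scale index m; the
    threshold is sqrt( sum_m sum_xy (D_m - D_bar)^2 / (n * n_pixels) ) — a
    pooled population std over all scalar samples.  With ``per_level``
    pooling, each level m additionally gets sigma_m pooled over that level's
    pixels only.
    """
    if dog.n < 1:
        raise ValueError("DoG stack is empty")
    mean_stack = dog.diffs.mean(axis=0)
    sq = (dog.diffs - mean_stack[None]) ** 2
    value = float(np.sqrt(sq.mean()))
    per_level = None
    if pooling == "per_level":
        per_level = np.sqrt(sq.mean(axis=(1, 2)))
    elif pooling != "pooled":
        raise ValueError(f"unknown pooling mode: {pooling!r}")
    return ScaleThreshold(value=value, mean_stack=mean_stack, per_level=per_level)


def reduce_scales(
    dog: DoGStack, threshold: ScaleThreshold, mode: str = "abs_le"
) -> ReducedDoG:
    """Apply the sigma threshold to the DoG stack, masking non-retained samples.

    ``abs_le`` (default): samples with |D_m(x, y)| <= sigma_D are redundant
    and eliminated; the retained set is |D| > sigma_D, the salient samples.
    ``signed_le``: retain D_m(x, y) <= sigma_D (the comparison read as a
    retention rule).  ``none``: retain everything (pruning disabled).
    Non-retained samples are excluded from the downstream extremum search.
    """
    if threshold.mean_stack.shape != dog.diffs.shape[1:]:
        raise ValueError("threshold was not computed from this DoG stack")
    if threshold.per_level is not None:
        thr = threshold.per_level[:, None, None]
    else:
        thr = threshold.value
    if mode == "signed_le":
        retained = dog.diffs <= thr
    elif mode == "abs_le":
        retained = np.abs(dog.diffs) > thr
    elif mode == "none":
        retained = np.ones_like(dog.diffs, dtype=bool)
    else:
        raise ValueError(f"unknown reduce mode: {mode!r}")
    return ReducedDoG(diffs=dog.diffs, sigmas=dog.sigmas, k=dog.k, retained=retained)
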