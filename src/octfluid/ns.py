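"""Neutrosophic-domain transforms of OCT B-scans.

A B-scan ``g`` (values in [0, 1], rows = depth) is mapped to two planes:

* ``T`` — fluid-likeness membership.  Both transforms invert the normalized
  local-mean intensity, ``T = 1 - (gbar - gbar_min) / (gbar_max - gbar_min)``,
  so the dark fluid pockets receive the highest membership while
  hyper-reflective structures receive the lowest.
* ``I`` — indeterminacy (noise-likeness).

Two variants are provided:

``to_ns_proposed``
    The layered-structure transform: indeterminacy is the minimum absolute
    deviation between ``T`` and its filtering with a bank of 10 oriented
    elongated Gaussian kernels covering 180 degrees, so pixels on (near-)
    horizontal layer boundaries are *not* marked indeterminate; very noisy
    pixels (``I >= lambda``) are replaced by the most deviating filter
    response (lambda-correction), and the loop repeats until the entropy of
    ``I`` stabilizes.

``to_ns_conventional``
    The classical transform: indeterminacy is the normalized deviation of a
    pixel from its windowed mean, reduced iteratively by alpha-mean and
    beta-enhancement operations.

The falsity plane F is never computed: the downstream segmentation only uses
T and I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import DegenerateImageError, InvalidInputError, InvalidParameterError
from .config import NSParams
from .io import validate_gray

__all__ = [
    "NSImage",
    "FilterBank",
    "build_filter_bank",
    "to_ns_proposed",
    "to_ns_conventional",
    "lambda_correction",
    "indeterminacy_entropy",
]


@dataclass
class NSImage:
    """The T (membership) and I (indeterminacy) planes of a B-scan."""

    T: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        if self.T.shape != self.I.shape:
            raise InvalidInputError("T and I must have identical shape")
        for name, plane in (("T", self.T), ("I", self.I)):
            if plane.min() < -1e-12 or plane.max() > 1.0 + 1e-12:
                raise InvalidInputError(f"{name} values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.T.shape


@dataclass
class FilterBank:
    """Oriented elongated Gaussian kernels spanning 180 degrees.

    Orientation 0 is horizontal (long axis along columns); each kernel is
    normalized to unit sum, hence mean-preserving on constant input.
    """

    filters: list = field(repr=False)
    base_shape: tuple[int, int] = (3, 9)
    orientations: np.ndarray = field(default=None, repr=False)


def build_filter_bank(base_shape: tuple[int, int] = (3, 9),
                      n_orientations: int = 10) -> FilterBank:
    """Build ``n_orientations`` rotated copies of an anisotropic Gaussian.

    The base kernel is an anisotropic Gaussian whose +-3 sigma extent matches
    ``base_shape`` (sigma = dim/6 on each axis); rotation is applied to the
    covariance analytically on a fixed square support, avoiding the
    interpolation artifacts of rotating a discrete kernel.
    """
    rows, cols = base_shape
    if rows <= 0 or cols <= 0:
        raise InvalidParameterError("base_shape dimensions must be positive")
    if rows >= cols:
        raise InvalidParameterError("base_shape must be elongated (rows < cols)")
    if n_orientations < 1:
        raise InvalidParameterError("n_orientations must be >= 1")

    sigma_r, sigma_c = rows / 6.0, cols / 6.0
    support = cols if cols % 2 == 1 else cols + 1
    half = support // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)

    angles = np.arange(n_orientations) * (180.0 / n_orientations)
    filters = []
    for theta in np.deg2rad(angles):
        # u: along the (rotated) long axis, v: across it
        u = xx * np.cos(theta) + yy * np.sin(theta)
        v = -xx * np.sin(theta) + yy * np.cos(theta)
        k = np.exp(-0.5 * ((u / sigma_c) ** 2 + (v / sigma_r) ** 2))
        filters.append(k / k.sum())
    return FilterBank(filters=filters, base_shape=(rows, cols), orientations=angles)


def _local_mean(img: np.ndarray, window: int) -> np.ndarray:
    return ndimage.uniform_filter(img, size=window, mode="reflect")


def _inverse_normalized(img: np.ndarray) -> np.ndarray:
    """One minus the min-max normalized image."""
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        raise DegenerateImageError(
            "constant image: intensity normalization is undefined")
    return 1.0 - (img - lo) / (hi - lo)


def _inverse_normalized_mean(g: np.ndarray, window: int) -> np.ndarray:
    """One minus the min-max normalized local-mean image."""
    return _inverse_normalized(_local_mean(g, window))


def _filter_responses(T: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Stack of FI_k = T filtered with every oriented kernel (mirror padding)."""
    return np.stack([ndimage.correlate(T, k, mode="reflect") for k in bank.filters])


def indeterminacy_entropy(I: np.ndarray, n_bins: int = 100) -> float:
    """Shannon entropy (natural log) of the histogram of ``I`` over [0, 1]."""
    I = np.asarray(I, dtype=np.float64)
    if I.size == 0:
        raise InvalidInputError("cannot compute the entropy of an empty array")
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    counts, _ = np.histogram(I, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def lambda_correction(T: np.ndarray, I: np.ndarray, FIs,
                      lam: float) -> np.ndarray:
    """Replace high-indeterminacy pixels by the most deviating filter response.

    Where ``I < lam`` (strict) the membership is kept; elsewhere it becomes
    ``FI_Ind`` with ``Ind = argmax_k |T - FI_k|`` — the very noisy pixels are
    blurred with the filter that deviates the most from them.
    """
    if not 0.0 < lam < 1.0:
        raise InvalidParameterError("lam must lie in (0, 1)")
    T = np.asarray(T, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    stack = np.stack([np.asarray(f, dtype=np.float64) for f in FIs])
    if I.shape != T.shape or stack.shape[1:] != T.shape:
        raise InvalidInputError("T, I and every FI_k must share one shape")
    ind = np.argmax(np.abs(stack - T[None, ...]), axis=0)
    T_lam = np.take_along_axis(stack, ind[None, ...], axis=0)[0]
    return np.where(I < lam, T, T_lam)


def to_ns_proposed(g: np.ndarray, bank: FilterBank | None = None,
                   params: NSParams | None = None) -> NSImage:
    """Layered-structure transform to the neutrosophic domain.

    T starts as the inverted min-max-normalized intensity (so the darkest
    regions — fluid — get membership 1) and then iterates: directional
    filtering of T, indeterminacy as the minimum directional deviation,
    entropy test, lambda-correction of T — until the indeterminacy entropy
    changes by less than ``params.entropy_tol`` (or ``params.max_iters``
    is hit).
    """
    params = params or NSParams()
    bank = bank or build_filter_bank()
    g = validate_gray(g)

    if params.proposed_local_mean:
        T = _inverse_normalized_mean(g, params.conv_window)
    else:
        T = _inverse_normalized(g)
    I = np.zeros_like(T)
    prev_entropy = None
    for _ in range(params.max_iters):
        FIs = _filter_responses(T, bank)
        I = np.min(np.abs(T[None, ...] - FIs), axis=0)
        entropy = indeterminacy_entropy(I, params.entropy_bins)
        if prev_entropy is not None and abs(entropy - prev_entropy) < params.entropy_tol:
            break
        prev_entropy = entropy
        T = lambda_correction(T, I, FIs, params.lambda_corr)
    return NSImage(np.clip(T, 0.0, 1.0), np.clip(I, 0.0, 1.0))


def _beta_enhancement(T: np.ndarray) -> np.ndarray:
    """Classical S-shaped contrast sharpening of a membership plane."""
    return np.where(T <= 0.5, 2.0 * T ** 2, 1.0 - 2.0 * (1.0 - T) ** 2)


def to_ns_conventional(g: np.ndarray, params: NSParams | None = None) -> NSImage:
    """Conventional transform with alpha-mean and beta-enhancement.

    ``I`` is the normalized absolute deviation of each pixel from its
    windowed mean; pixels with ``I >= alpha`` have their membership replaced
    by the windowed mean of T (alpha-mean) and pixels with ``I >= beta`` are
    contrast-sharpened (beta-enhancement); both are iterated with the
    indeterminacy recomputed on the current T until the entropy stabilizes.
    """
    params = params or NSParams()
    g = validate_gray(g)
    w = params.conv_window

    gbar = _local_mean(g, w)
    T = _inverse_normalized_mean(g, w)
    delta = np.abs(g - gbar)
    lo, hi = float(delta.min()), float(delta.max())
    if hi - lo < 1e-12:
        raise DegenerateImageError("zero-range deviation image: I is undefined")
    I = (delta - lo) / (hi - lo)

    prev_entropy = None
    for _ in range(params.max_iters):
        entropy = indeterminacy_entropy(I, params.entropy_bins)
        if prev_entropy is not None and abs(entropy - prev_entropy) < params.entropy_tol:
            break
        prev_entropy = entropy
        Tbar = _local_mean(T, w)
        T = np.where(I >= params.alpha, Tbar, T)          # alpha-mean
        T = np.where(I >= params.beta, _beta_enhancement(T), T)  # beta-enhancement
        delta = np.abs(T - _local_mean(T, w))
        lo, hi = float(delta.min()), float(delta.max())
        if hi - lo < 1e-12:  # deviations collapsed: clean convergence
            I = np.zeros_like(T)
        else:
            I = (delta - lo) / (hi - lo)
    return NSImage(np.clip(T, 0.0, 1.0), np.clip(I, 0.0, 1.0))
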