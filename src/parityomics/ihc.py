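"""Mahalanobis-distance color segmentation of IHC micrographs.

Stained-pixel quantification (e.g. DAB-brown versican signal on a
hematoxylin counterstain) proceeds by fitting a reference RGB color
distribution (mean and covariance) to user-selected training pixels and
then calling every pixel whose squared Mahalanobis distance

    d^2(x) = (x - mu)' Sigma^-1 (x - mu)

falls within a chi-square(3 df) quantile of that reference.  The
positive fraction over an optional tissue mask is the reported
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ColorReference",
    "SegmentationResult",
    "MahalanobisSegmenter",
    "fit_color_reference",
    "segment_by_mahalanobis",
]


@dataclass(frozen=True)
class ColorReference:
    """Reference RGB color distribution learned from training pixels."""

    mu: np.ndarray  # (3,)
    sigma: np.ndarray  # (3, 3)
    n_training_pixels: int
    regularized: bool = False


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray  # (H, W) bool
    positive_fraction: float
    threshold_used: float  # squared-distance cutoff


def fit_color_reference(training_pixels) -> ColorReference:
    """Sample mean/covariance of >= 10 RGB training pixels.

    A near-singular covariance (e.g. identical pixels) is inflated on
    the diagonal and flagged, so the reference always stays usable.
    """
    px = np.asarray(training_pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise ValueError("training pixels must be an (n, 3) RGB array")
    if px.shape[0] < 10:
        raise ValueError("need at least 10 training pixels")
    mu = px.mean(axis=0)
    sigma = np.cov(px, rowvar=False)
    eigvals = np.linalg.eigvalsh(sigma)
    regularized = False
    scale = max(float(np.trace(sigma)) / 3.0, 1.0)
    if eigvals.min() < 1e-8 * scale:
        sigma = sigma + (1e-3 * scale) * np.eye(3)
        regularized = True
    return ColorReference(mu=mu, sigma=sigma, n_training_pixels=px.shape[0],
                          regularized=regularized)


def _check_pd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, float)
    if sigma.shape != (3, 3) or not np.allclose(sigma, sigma.T):
        raise ValueError("covariance must be symmetric 3x3")
    try:
        return linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc


def mahalanobis_sq(pixels: np.ndarray, ref: ColorReference) -> np.ndarray:
    """Squared Mahalanobis distance of RGB pixels to the reference."""
    chol = _check_pd(ref.sigma)
    flat = np.asarray(pixels, float).reshape(-1, 3) - ref.mu
    y = linalg.solve_triangular(chol, flat.T, lower=True)
    return (y**2).sum(axis=0).reshape(np.asarray(pixels).shape[:-1])


class MahalanobisSegmenter(BaseEstimator):
    """Color segmenter: fit on training pixels, predict stained masks.

    Parameters
    ----------
    quantile : chi-square(3) probability mass retained around the
        reference color; the squared-distance cutoff is the matching
        quantile.  On pixels drawn exactly from the reference Gaussian
        the positive rate equals ``quantile`` by construction.
    """

    def __init__(self, quantile: float = 0.99):
        self.quantile = quantile

    def fit(self, training_pixels, y=None) -> "MahalanobisSegmenter":
        self.reference_ = (
            training_pixels
            if isinstance(training_pixels, ColorReference)
            else fit_color_reference(training_pixels)
        )
        self.threshold_ = float(stats.chi2.ppf(self._q(), df=3))
        return self

    def _q(self) -> float:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        return self.quantile

    def predict(self, image, tissue_mask=None) -> np.ndarray:
        """Boolean stained-pixel mask for an (H, W, 3) image."""
        return self.segment(image, tissue_mask).mask

    def segment(self, image, tissue_mask=None) -> SegmentationResult:
        img = np.asarray(image, dtype=float)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be (H, W, 3) RGB")
        d2 = mahalanobis_sq(img, self.reference_)
        mask = d2 <= self.threshold_
        if tissue_mask is not None:
            tissue_mask = np.asarray(tissue_mask, bool)
            mask = mask & tissue_mask
            denom = int(tissue_mask.sum())
        else:
            denom = mask.size
        frac = float(mask.sum()) / denom if denom else 0.0
        return SegmentationResult(mask=mask, positive_fraction=frac,
                                  threshold_used=self.threshold_)


def segment_by_mahalanobis(
    image, ref: ColorReference, quantile: float = 0.99, tissue_mask=None
) -> SegmentationResult:
    """Segment one image against a fitted color reference."""
    return MahalanobisSegmenter(quantile=quantile).fit(ref).segment(image, tissue_mask)
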