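"""Handcrafted texture descriptors: GLCM, LBP, HOG, Gabor, wavelet.

Each extractor maps a grayscale patch (the windowed channel, values in
[0, 1]) to a fixed-length :class:`FeatureVector`; lengths depend only on
the configuration, never on the patch, so feature matrices stay
rectangular.  Hyperparameter defaults are declared here and exposed on
every function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import transform as sktransform

__all__ = [
    "FeatureVector",
    "DEFAULT_GLCM_OFFSETS",
    "GLCM_STAT_NAMES",
    "quantize_gray",
    "glcm_matrix",
    "glcm_features",
    "lbp_features",
    "hog_features",
    "gabor_features",
    "wavelet_features",
    "EXTRACTORS",
    "extract_features",
]


@dataclass
class FeatureVector:
    """Ordered real-valued descriptor of one patch."""

    values: np.ndarray
    descriptor_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.descriptor_name}: non-finite feature values")

    @property
    def length(self) -> int:
        return self.values.size


#: Four standard co-occurrence directions at distance 1: 0, 90, 45, 135 degrees.
DEFAULT_GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
GLCM_STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity", "entropy")


def quantize_gray(patch: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin a [0, 1] patch into integer gray levels 0..levels-1."""
    patch = np.asarray(patch, dtype=float)
    return np.clip((patch * levels).astype(int), 0, levels - 1)


def glcm_matrix(
    quantized: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset.

    Counts every ordered pixel pair ``(p, p + offset)`` inside the patch in
    both directions (symmetric), then normalizes to sum 1.
    """
    dr, dc = offset
    h, w = quantized.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} larger than patch of shape {quantized.shape}")
    from skimage.feature import graycomatrix

    angle = math.atan2(dr, dc)  # skimage: row offset = d*sin(angle), col = d*cos(angle)
    distance = math.hypot(dr, dc)
    glcm = graycomatrix(
        quantized.astype(np.uint8),
        distances=[distance],
        angles=[angle],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    return glcm[:, :, 0, 0]


def _glcm_stats(p: np.ndarray) -> np.ndarray:
    """Haralick subset on a normalized GLCM: contrast, correlation, energy
    (angular second moment), homogeneity, entropy (bits)."""
    levels = p.shape[0]
    i, j = np.mgrid[0:levels, 0:levels].astype(float)
    contrast = float(np.sum(p * (i - j) ** 2))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    if var_i > 0 and var_j > 0:
        correlation = float(
            np.sum(p * (i - mu_i) * (j - mu_j)) / math.sqrt(var_i * var_j)
        )
    else:
        correlation = 1.0  # degenerate single-level patch: perfectly correlated
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array([contrast, correlation, energy, homogeneity, entropy])


def glcm_features(
    patch: np.ndarray,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_GLCM_OFFSETS,
    stats: tuple[str, ...] = GLCM_STAT_NAMES,
) -> FeatureVector:
    """Haralick statistics of the co-occurrence matrix at each offset.

    Float input in [0, 1] is uniformly quantized to ``levels`` gray levels;
    integer input is taken as already quantized.  Length =
    ``len(offsets) * len(stats)``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    patch = np.asarray(patch)
    if np.issubdtype(patch.dtype, np.integer):
        q = patch.astype(int)
        if q.min() < 0 or q.max() >= levels:
            raise ValueError("integer patch values must lie in [0, levels)")
    else:
        q = quantize_gray(patch, levels)
    idx = [GLCM_STAT_NAMES.index(s) for s in stats]
    vals = [
        _glcm_stats(glcm_matrix(q, off, levels))[idx] for off in offsets
    ]
    return FeatureVector(np.concatenate(vals), "glcm")


def lbp_features(
    patch: np.ndarray, P: int = 8, R: float = 1.0, bins: int | None = None
) -> FeatureVector:
    """Normalized histogram of local binary pattern codes.

    Per pixel, each of ``P`` circularly interpolated neighbors at radius
    ``R`` is thresholded against the center (>= contributes bit 2^p); the
    histogram over all 2^P codes is normalized to sum 1.
    """
    if P < 4 or R < 1:
        raise ValueError("need P >= 4 and R >= 1")
    patch = np.asarray(patch, dtype=float)
    if min(patch.shape) <= 2 * R + 1:
        raise ValueError(
            f"patch of shape {patch.shape} too small for LBP radius {R}"
        )
    if bins is None:
        bins = 2**P
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = skfeature.local_binary_pattern(patch, P, R, method="default")
    # border pixels would compare against zero-padded out-of-patch values, so
    # only interior codes (all P neighbors inside the patch) are histogrammed
    b = int(np.ceil(R))
    codes = codes[b:-b, b:-b]
    hist, _ = np.histogram(codes, bins=bins, range=(0, 2**P))
    return FeatureVector(hist / hist.sum(), "lbp")


def hog_features(
    patch: np.ndarray,
    cell_size: tuple[int, int] = (8, 8),
    block_size: tuple[int, int] = (2, 2),
    orientation_bins: int = 9,
    resize_to: int = 64,
) -> FeatureVector:
    """Histogram-of-oriented-gradients descriptor on a fixed-size resize.

    The patch is resized to ``resize_to``² first so the descriptor length is
    constant for a given configuration.
    """
    patch = np.asarray(patch, dtype=float)
    if cell_size[0] > resize_to or cell_size[1] > resize_to:
        raise ValueError("cell larger than the resized patch")
    resized = sktransform.resize(
        patch, (resize_to, resize_to), order=1, mode="reflect", anti_aliasing=False
    )
    desc = skfeature.hog(
        resized,
        orientations=orientation_bins,
        pixels_per_cell=cell_size,
        cells_per_block=block_size,
        block_norm="L2-Hys",
        feature_vector=True,
    )
    return FeatureVector(desc, "hog")


DEFAULT_GABOR_FREQUENCIES = (0.1, 0.2, 0.3, 0.4)
DEFAULT_GABOR_ORIENTATIONS = tuple(k * math.pi / 4 for k in range(4))


def gabor_features(
    patch: np.ndarray,
    frequencies: tuple[float, ...] = DEFAULT_GABOR_FREQUENCIES,
    orientations: tuple[float, ...] = DEFAULT_GABOR_ORIENTATIONS,
) -> FeatureVector:
    """Mean and SD of the Gabor response magnitude per (frequency, orientation).

    Length = 2 * |frequencies| * |orientations|.
    """
    if not frequencies or not orientations:
        raise ValueError("need at least one frequency and one orientation")
    patch = np.asarray(patch, dtype=float)
    out = []
    for f in frequencies:
        for theta in orientations:
            real, imag = skfilters.gabor(patch, frequency=f, theta=theta)
            mag = np.hypot(real, imag)
            out.extend([mag.mean(), mag.std()])
    return FeatureVector(np.array(out), "gabor")


def wavelet_features(
    patch: np.ndarray, wavelet_name: str = "haar", levels: int = 2
) -> FeatureVector:
    """Per-subband energy and entropy of a 2-D discrete wavelet decomposition.

    Energy is the mean squared coefficient; entropy is the Shannon entropy
    (bits) of the normalized squared coefficients.  Subbands: one
    approximation + 3 details per level, so length = 2 * (1 + 3*levels).
    """
    patch = np.asarray(patch, dtype=float)
    if min(patch.shape) < 2**levels:
        raise ValueError(
            f"patch of shape {patch.shape} too small for {levels} wavelet levels"
        )
    coeffs = pywt.wavedec2(patch, wavelet_name, level=levels)
    subbands: list[np.ndarray] = [coeffs[0]]
    for detail in coeffs[1:]:
        subbands.extend(detail)
    out = []
    for band in subbands:
        sq = np.asarray(band, dtype=float) ** 2
        out.append(sq.mean())
        total = sq.sum()
        if total > 0:
            p = (sq / total).ravel()
            p = p[p > 0]
            out.append(float(-np.sum(p * np.log2(p))))
        else:
            out.append(0.0)
    return FeatureVector(np.array(out), f"wavelet-{wavelet_name}")


#: Registry used by the pipeline and CLI; each maps a [0,1] gray patch to features.
EXTRACTORS = {
    "glcm": glcm_features,
    "lbp": lbp_features,
    "hog": hog_features,
    "gabor": gabor_features,
    "wavelet": wavelet_features,
}


def extract_features(name: str, patch: np.ndarray, **kwargs) -> FeatureVector:
    """Dispatch to a registered texture extractor by name."""
    try:
        fn = EXTRACTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown extractor {name!r}; available: {sorted(EXTRACTORS)}"
        ) from None
    return fn(patch, **kwargs)
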