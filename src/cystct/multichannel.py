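"""HU patch -> 3-channel image: windowed grayscale, Canny edges, gradient magnitude.

A raw CT patch spans thousands of Hounsfield units; display windowing maps
the clinically relevant band [WL - WW/2, WL + WW/2] linearly onto [0, 1].
The other two channels make lesion-boundary structure explicit: a binary
Canny edge map and a max-normalized Sobel gradient magnitude, both computed
on the windowed plane.  Channel order is fixed (windowed, edges, gradient)
because downstream CNN inputs are order-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

__all__ = [
    "WindowSpec",
    "CannyParams",
    "MultichannelImage",
    "DEFAULT_WINDOW",
    "DEFAULT_CANNY",
    "window_image",
    "gradient_magnitude",
    "canny_edges",
    "assemble_multichannel",
]


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: level (WL) and width (WW), both in HU."""

    level: float = 40.0
    width: float = 400.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


@dataclass(frozen=True)
class CannyParams:
    """Canny settings; thresholds are fractions of the smoothed-gradient range."""

    gaussian_sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if not (0.0 <= self.low_threshold <= self.high_threshold <= 1.0):
            raise ValueError(
                "need 0 <= low_threshold <= high_threshold <= 1, got "
                f"({self.low_threshold}, {self.high_threshold})"
            )


#: Soft-tissue abdomen window, the standard display setting for pancreas CT.
DEFAULT_WINDOW = WindowSpec(level=40.0, width=400.0)
DEFAULT_CANNY = CannyParams()


@dataclass
class MultichannelImage:
    """Three same-shape planes: windowed in [0,1], edges in {0,1}, gradient in [0,1]."""

    windowed: np.ndarray
    edges: np.ndarray
    gradient: np.ndarray

    def __post_init__(self) -> None:
        if not (self.windowed.shape == self.edges.shape == self.gradient.shape):
            raise ValueError("all three channels must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.windowed.shape

    def stack(self) -> np.ndarray:
        """Channel-first array of shape (3, H, W)."""
        return np.stack(
            [self.windowed, self.edges.astype(float), self.gradient], axis=0
        )


def window_image(patch: np.ndarray, spec: WindowSpec = DEFAULT_WINDOW) -> np.ndarray:
    """Linear HU -> [0, 1] display mapping, clamped outside the window."""
    patch = np.asarray(patch, dtype=float)
    out = (patch - spec.lower) / spec.width
    return np.clip(out, 0.0, 1.0)


def gradient_magnitude(plane: np.ndarray) -> np.ndarray:
    """Euclidean norm of Sobel x/y derivatives, max-normalized to [0, 1].

    A constant plane yields all zeros (the max-0 case is defined as zeros).
    """
    plane = np.asarray(plane, dtype=float)
    if min(plane.shape) < 3:
        raise ValueError(
            f"plane of shape {plane.shape} is smaller than the 3x3 Sobel operator"
        )
    gr = ndimage.sobel(plane, axis=0, mode="reflect")
    gc = ndimage.sobel(plane, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def canny_edges(
    plane: np.ndarray, params: CannyParams = DEFAULT_CANNY
) -> np.ndarray:
    """Binary Canny edge map (smooth, gradient, NMS, hysteresis).

    The fractional thresholds are scaled by the maximum smoothed-gradient
    magnitude, so they are invariant to the plane's absolute contrast.
    """
    plane = np.asarray(plane, dtype=float)
    smoothed = ndimage.gaussian_filter(plane, params.gaussian_sigma, mode="reflect")
    gmax = float(
        np.hypot(
            ndimage.sobel(smoothed, axis=0, mode="reflect"),
            ndimage.sobel(smoothed, axis=1, mode="reflect"),
        ).max()
    )
    if gmax == 0.0:
        return np.zeros_like(plane, dtype=bool)
    edges = skfeature.canny(
        plane,
        sigma=params.gaussian_sigma,
        low_threshold=params.low_threshold * gmax,
        high_threshold=params.high_threshold * gmax,
        use_quantiles=False,
    )
    return edges


def assemble_multichannel(
    patch: np.ndarray,
    window: WindowSpec = DEFAULT_WINDOW,
    canny: CannyParams = DEFAULT_CANNY,
) -> MultichannelImage:
    """Build the 3-channel image from a raw HU patch.

    Channel 1 is the windowed patch; channels 2 and 3 (edges, gradient) are
    both derived from channel 1, so the whole product is deterministic in
    the patch and the two parameter sets.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("patch is empty")
    windowed = window_image(patch, window)
    edges = canny_edges(windowed, canny)
    grad = gradient_magnitude(windowed)
    return MultichannelImage(windowed=windowed, edges=edges, gradient=grad)
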