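"""CNN feature-extractor contract: multichannel image -> fixed-length vector.

The classifier stack downstream never trains the network; the CNN is a
frozen feature map whose output length is part of the configuration
contract (2048 for a ResNet-style global-pooling output).  Three backends:

``tiny_cnn``
    A small fixed convolution stack (numpy, seeded He-initialized random
    weights, ReLU, max-pooling, global average pool).  Runs anywhere, fast,
    fully reproducible offline; the tested default.
``resnet_pool`` / ``alexnet_pool``
    torchvision backbones truncated at the global-pooling layer.  Require a
    deep-learning runtime; when torch is not importable these raise
    :class:`BackendUnavailableError` naming the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .multichannel import MultichannelImage

__all__ = [
    "ExtractorConfig",
    "BackendUnavailableError",
    "BACKEND_FEATURE_LENGTHS",
    "prepare_input",
    "extract_deep_features",
]

BACKEND_FEATURE_LENGTHS = {"resnet_pool": 2048, "alexnet_pool": 256, "tiny_cnn": 64}


class BackendUnavailableError(RuntimeError):
    """Raised when a requested CNN backend cannot run in this environment."""


@dataclass(frozen=True)
class ExtractorConfig:
    backend: str = "tiny_cnn"
    input_size: int = 64
    weights: str = "random"
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKEND_FEATURE_LENGTHS:
            raise ValueError(
                f"backend must be one of {sorted(BACKEND_FEATURE_LENGTHS)}"
            )
        if self.input_size <= 0:
            raise ValueError("input_size must be > 0")
        if self.weights not in ("pretrained", "random"):
            raise ValueError("weights must be 'pretrained' or 'random'")

    @property
    def feature_length(self) -> int:
        return BACKEND_FEATURE_LENGTHS[self.backend]


def prepare_input(mc: MultichannelImage, input_size: int) -> np.ndarray:
    """Resize each channel bilinearly to ``input_size``² and standardize.

    Per-channel standardization subtracts the mean and divides by the SD; a
    zero-SD (constant) channel becomes all zeros.  Aspect ratio is not
    preserved.  Returns shape ``(3, input_size, input_size)``.
    """
    h, w = mc.shape
    if h == 0 or w == 0:
        raise ValueError("multichannel image has zero area")
    planes = []
    for chan in mc.stack():
        resized = sktransform.resize(
            chan, (input_size, input_size), order=1, mode="reflect",
            anti_aliasing=False,
        )
        sd = resized.std()
        planes.append((resized - resized.mean()) / sd if sd > 0 else np.zeros_like(resized))
    return np.stack(planes, axis=0)


# --- tiny_cnn: a fixed numpy convolution stack -------------------------------

_TINY_CHANNELS = (3, 16, 32, 64)


def _tiny_cnn_weights(seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    weights = []
    for c_in, c_out in zip(_TINY_CHANNELS[:-1], _TINY_CHANNELS[1:]):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization for 3x3 kernels
        weights.append(rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)))
    return weights


def _conv3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid 3x3 cross-correlation, channel-first: (C,H,W) x (O,C,3,3) -> (O,H-2,W-2)."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    # windows: (C, H-2, W-2, 3, 3) -> tensordot over C and the 3x3 taps
    return np.tensordot(w, windows, axes=([1, 2, 3], [0, 3, 4]))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def _tiny_cnn_forward(x: np.ndarray, weights: list[np.ndarray]) -> np.ndarray:
    for w in weights:
        x = np.maximum(_conv3x3(x, w), 0.0)
        x = _maxpool2(x)
    return x.mean(axis=(1, 2))  # global average pool -> (64,)


# --- torchvision backends ----------------------------------------------------


def _torch_features(x: np.ndarray, config: ExtractorConfig) -> np.ndarray:
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:
        raise BackendUnavailableError(
            f"backend {config.backend!r} needs torch/torchvision, which are not "
            "installed; fall back to backend='tiny_cnn' or a texture extractor"
        ) from exc
    torch.manual_seed(config.weight_seed)
    pretrained = config.weights == "pretrained"
    if config.backend == "resnet_pool":
        net = tvm.resnet50(weights="IMAGENET1K_V2" if pretrained else None)
        modules = list(net.children())[:-1]  # stop at global average pool
    else:
        net = tvm.alexnet(weights="IMAGENET1K_V1" if pretrained else None)
        modules = [net.features, torch.nn.AdaptiveAvgPool2d(1)]
    trunk = torch.nn.Sequential(*modules).eval()
    with torch.no_grad():
        out = trunk(torch.from_numpy(x[None]).float())
    return out.numpy().ravel()


def extract_deep_features(
    mc: MultichannelImage, config: ExtractorConfig | None = None
) -> np.ndarray:
    """Forward pass to the global-pooling layer; returns the pooled vector.

    Deterministic given (backend, weights, weight_seed).  Output length is
    ``config.feature_length`` regardless of the input patch size.
    """
    config = config or ExtractorConfig()
    x = prepare_input(mc, config.input_size)
    if config.backend == "tiny_cnn":
        feats = _tiny_cnn_forward(x, _tiny_cnn_weights(config.weight_seed))
    else:
        feats = _torch_features(x, config)
    if feats.size != config.feature_length:
        raise RuntimeError(
            f"backend {config.backend} produced {feats.size} features, "
            f"expected {config.feature_length}"
        )
    return feats
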