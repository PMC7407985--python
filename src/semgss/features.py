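"""Image-feature extraction: one 1000-dimensional vector per spectrogram image.

Two backends share one contract (length-1000 output, deterministic, finite):

``pretrained_backbone``
    The 1000-way classification-head activations of a large pretrained image
    classifier.  Weights are an optional plug-in; when they are not available
    the backend raises :class:`BackendUnavailableError` pointing at the
    fallback.

``deterministic_fallback``
    A seeded fixed random projection requiring no downloads.  The image is
    reduced to a linear spatial descriptor — 8x8 and 4x4 grids of block
    means, 80 numbers preserving coarse image geometry — then mapped through
    a fixed Gaussian matrix to 1000 dimensions and passed through a ramp
    (ReLU) nonlinearity.  The map before the ramp is linear, so the zero
    image maps to the zero vector (plus the bias when enabled) and the whole
    extractor is Lipschitz with constant bounded by the projection's operator
    norm.

Per sample, channel features are kept in two views: a 6 x 1000 sequence
matrix (rows in channel order, one time-step per channel for recurrent
decoders) and its row-major flattening, the 6000-long concatenated vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrogram import SpectrogramParams, SpectrogramStack, build_stack
from .synthetic import ParameterError, RawRecording

__all__ = [
    "ExtractorSpec",
    "FeatureBundle",
    "BackendUnavailableError",
    "extract_image_features",
    "extract_sample_features",
    "featurize_dataset",
    "Standardizer",
]

FEATURE_DIM = 1000
POOL_GRIDS = (8, 4)  # block-mean grids of the fallback descriptor


class BackendUnavailableError(RuntimeError):
    """Requested extractor backend cannot run in this installation."""


@dataclass(frozen=True)
class ExtractorSpec:
    """Backend choice and its parameters; ``feature_dim`` is fixed at 1000."""

    backend: str = "deterministic_fallback"
    feature_dim: int = FEATURE_DIM
    seed: int = 0
    input_side: int = 299
    use_bias: bool = False

    def __post_init__(self) -> None:
        if self.backend not in ("pretrained_backbone", "deterministic_fallback"):
            raise ParameterError(f"backend: unknown backend {self.backend!r}")
        if self.feature_dim != FEATURE_DIM:
            raise ParameterError(f"feature_dim: fixed at {FEATURE_DIM}, got {self.feature_dim}")


@dataclass
class FeatureBundle:
    """Per-sample features: ``sequence`` (channels x 1000) and its flattening."""

    sequence: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.sequence = np.asarray(self.sequence, dtype=np.float64)
        if self.sequence.ndim != 2 or self.sequence.shape[1] != FEATURE_DIM:
            raise ParameterError(
                f"sequence: expected channels x {FEATURE_DIM}, got {self.sequence.shape}"
            )
        if not np.all(np.isfinite(self.sequence)):
            raise ParameterError("sequence: contains non-finite values")

    @property
    def concat(self) -> np.ndarray:
        """Row-major flattening of ``sequence`` (length channels x 1000)."""
        return self.sequence.reshape(-1)

    @property
    def n_channels(self) -> int:
        return self.sequence.shape[0]


def _pooled_descriptor(img: np.ndarray) -> np.ndarray:
    """Linear spatial descriptor: concatenated block means on each grid."""
    side = img.shape[0]
    parts = []
    for g in POOL_GRIDS:
        edges = np.linspace(0, side, g + 1).astype(int)
        pooled = np.empty((g, g))
        for i in range(g):
            for j in range(g):
                block = img[edges[i]:edges[i + 1], edges[j]:edges[j + 1]]
                pooled[i, j] = block.mean()
        parts.append(pooled.reshape(-1))
    return np.concatenate(parts)


def _projection_matrix(spec: ExtractorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fixed Gaussian projection (and bias) for the fallback backend."""
    d_in = sum(g * g for g in POOL_GRIDS)
    rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal((spec.feature_dim, d_in)) / np.sqrt(d_in)
    b = rng.standard_normal(spec.feature_dim) * 0.1 if spec.use_bias else np.zeros(spec.feature_dim)
    return w, b


def fallback_linear_map(img: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    """The fallback extractor's pre-activation linear map (no ramp)."""
    w, b = _projection_matrix(spec)
    return w @ _pooled_descriptor(img) + b


def extract_image_features(img: np.ndarray, spec: ExtractorSpec = ExtractorSpec()) -> np.ndarray:
    """Map one square grayscale raster in [0, 1] to a length-1000 vector."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape != (spec.input_side, spec.input_side):
        raise ParameterError(
            f"img: expected {spec.input_side} x {spec.input_side}, got {img.shape}"
        )
    if spec.backend == "pretrained_backbone":
        raise BackendUnavailableError(
            "pretrained_backbone requires a deep-learning runtime with downloaded "
            "weights, which this installation does not provide; use "
            "backend='deterministic_fallback' instead"
        )
    return np.maximum(fallback_linear_map(img, spec), 0.0)


def extract_sample_features(
    stack: SpectrogramStack, spec: ExtractorSpec = ExtractorSpec()
) -> FeatureBundle:
    """Stack per-channel image features into the per-sample bundle."""
    rows = [extract_image_features(img, spec) for img in stack.images]
    return FeatureBundle(sequence=np.vstack(rows), label=stack.label)


def featurize_dataset(
    recordings: list[RawRecording],
    sp_params: SpectrogramParams = SpectrogramParams(),
    spec: ExtractorSpec = ExtractorSpec(),
) -> list[FeatureBundle]:
    """One :class:`FeatureBundle` per recording; labels carried through."""
    if not recordings:
        raise ParameterError("recordings: empty collection")
    return [extract_sample_features(build_stack(rec, sp_params), spec) for rec in recordings]


class Standardizer:
    """Per-dimension standardization fitted on the training split only.

    Zero-variance dimensions are mapped to exactly zero rather than dividing
    by zero.  The fitted statistics are stored so validation/test bundles are
    transformed with training statistics, never their own (no leakage).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer used before fit()")
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        out = (np.asarray(x, dtype=np.float64) - self.mean_) / sd
        out[:, self.sd_ == 0] = 0.0
        return out

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
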