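"""Spectrogram computation and square-image rendering.

Each conditioned channel is transformed into a time–frequency power matrix,
``|STFT(x)|^2``, and rendered as a fixed-size square grayscale image; the six
per-channel images of one sample form an ordered stack which downstream
stages treat like a short fixed-length video.

The STFT here is the bare windowed transform: the signal is cut into
``win_len``-sample segments advanced by ``hop = win_len * (1 - overlap_frac)``
with no zero-padding at the boundaries, each segment is multiplied by the
taper and Fourier-transformed, and the squared magnitude is kept.  No
normalization by the window sum is applied — the matrix is exactly
``|FFT(w . segment)|^2`` column by column, which keeps the published contract
checkable against a direct FFT.

The nominal parameter set is [hanning, 512, 1000 Hz, 50% overlap]; the
effective FFT length is ``max(win_len, nfft)`` since an FFT shorter than the
window is not computable by a standard STFT (a configured shorter value is
kept as metadata and flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.signal import get_window

from .synthetic import ParameterError, RawRecording

__all__ = [
    "SpectrogramParams",
    "SpectrogramStack",
    "compute_spectrogram",
    "render_image",
    "build_stack",
    "n_stft_columns",
]

LOG_EPS = 1e-12


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT and rendering parameters.

    ``window`` is any scipy taper name ('hann'/'hanning', 'hamming', ...);
    periodic (DFT-even) tapers are used.  ``overlap_frac`` in [0, 1).
    ``image_side`` is the rendered square size in pixels (299 matches the
    input geometry of large pretrained image backbones).
    """

    window: str = "hann"
    win_len: int = 512
    fs: float = 1000.0
    overlap_frac: float = 0.5
    nfft: int | None = None
    log_scale: bool = True
    image_side: int = 299

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ParameterError(f"overlap_frac: must lie in [0, 1), got {self.overlap_frac}")
        if self.win_len < 2:
            raise ParameterError(f"win_len: must be >= 2, got {self.win_len}")
        if self.image_side < 32:
            raise ParameterError(f"image_side: must be >= 32, got {self.image_side}")
        if self.nfft is not None and self.nfft < self.win_len:
            warnings.warn(
                f"nfft={self.nfft} is shorter than win_len={self.win_len} and cannot be "
                f"realized by a standard STFT; using effective nfft={self.win_len} "
                "(the configured value is kept as metadata only)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def effective_nfft(self) -> int:
        return max(self.win_len, self.nfft or 0)

    @property
    def hop(self) -> int:
        h = int(round(self.win_len * (1.0 - self.overlap_frac)))
        return max(h, 1)

    @property
    def taper_name(self) -> str:
        # accept the common alias
        return "hann" if self.window == "hanning" else self.window

    def taper(self) -> np.ndarray:
        return get_window(self.taper_name, self.win_len, fftbins=True)

    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.effective_nfft, d=1.0 / self.fs)


@dataclass
class SpectrogramStack:
    """Per-channel power matrices and rendered images, in acquisition order."""

    matrices: list[np.ndarray]
    images: list[np.ndarray]
    params: SpectrogramParams
    label: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.matrices)


def n_stft_columns(n: int, params: SpectrogramParams) -> int:
    """Number of full STFT segments: floor((n - win_len)/hop) + 1."""
    if n < params.win_len:
        return 0
    return (n - params.win_len) // params.hop + 1


def compute_spectrogram(x: np.ndarray, params: SpectrogramParams = SpectrogramParams()) -> np.ndarray:
    """Return the frequency x time power matrix ``|STFT(x)|^2``.

    Frequency axis spans 0..fs/2 over ``effective_nfft // 2 + 1`` bins.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError(f"compute_spectrogram: expected 1-D signal, got shape {x.shape}")
    if len(x) < params.win_len:
        raise ParameterError(
            f"compute_spectrogram: signal length {len(x)} is below the required "
            f"minimum of one window ({params.win_len} samples)"
        )
    hop, win_len = params.hop, params.win_len
    n_cols = n_stft_columns(len(x), params)
    idx = np.arange(win_len)[None, :] + hop * np.arange(n_cols)[:, None]
    segments = x[idx] * params.taper()[None, :]
    spec = np.fft.rfft(segments, n=params.effective_nfft, axis=1)
    return (np.abs(spec) ** 2).T  # frequency x time


def render_image(p: np.ndarray, params: SpectrogramParams = SpectrogramParams()) -> np.ndarray:
    """Render a power matrix as an ``image_side`` x ``image_side`` raster in [0, 1].

    Optional log compression (``10 log10(P + eps)``), min–max normalization,
    then bilinear resize.  A constant matrix (including all-zero) maps to the
    all-0.5 raster rather than failing on the degenerate normalization.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ParameterError("render_image: empty power matrix")
    if np.any(p < 0):
        raise ParameterError("render_image: power values must be non-negative")
    z = 10.0 * np.log10(p + LOG_EPS) if params.log_scale else p.copy()
    lo, hi = z.min(), z.max()
    if hi - lo < 1e-300:
        z = np.full_like(z, 0.5)
    else:
        z = (z - lo) / (hi - lo)
    side = params.image_side
    im = Image.fromarray(z.astype(np.float32), mode="F")
    im = im.resize((side, side), resample=Image.BILINEAR)
    return np.clip(np.asarray(im, dtype=np.float64), 0.0, 1.0)


def build_stack(rec: RawRecording, params: SpectrogramParams = SpectrogramParams()) -> SpectrogramStack:
    """One power matrix and one rendered image per channel, order preserved."""
    matrices = [compute_spectrogram(rec.data[ch], params) for ch in range(rec.n_channels)]
    images = [render_image(m, params) for m in matrices]
    return SpectrogramStack(matrices=matrices, images=images, params=params, label=rec.label)


def save_image_png(img: np.ndarray, path: str) -> None:
    """Persist a [0, 1] raster as 8-bit grayscale PNG (lossless)."""
    arr = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")
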