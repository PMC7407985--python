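"""Signal conditioning for silent-speech sEMG.

Three stages, applied per channel in a fixed order:

1. zero-phase Butterworth bandpass (0.15–300 Hz by default) removing DC bias
   and out-of-band high-frequency content;
2. comb notch suppressing 50 Hz powerline interference and its harmonics;
3. quadratic variation reduction (QVR) removing residual baseline wander.

QVR subtracts the smooth solution of a quadratic-variation-penalized
regularization problem::

    z = z_tilde - y,   (I + lam * D^T D) y = z_tilde

where ``D`` is the (n-1) x n first-difference matrix and ``lam`` (default 100)
controls smoothness.  ``I + lam * D^T D`` is symmetric positive-definite and
tridiagonal, so the solve is O(n) via a banded Cholesky factorization; a dense
explicit-inverse path is retained for small n as a cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import solveh_banded

from .synthetic import ParameterError, RawRecording

__all__ = [
    "FilterConfig",
    "QVRConfig",
    "bandpass",
    "comb_notch",
    "qvr_detrend",
    "qvr_detrend_dense",
    "preprocess_recording",
]

#: above this length the dense QVR path refuses to run (O(n^2) memory)
DENSE_QVR_MAX_N = 2000


@dataclass(frozen=True)
class FilterConfig:
    """Bandpass and comb-notch parameters.

    ``bp_order`` is the overall order of the Butterworth bandpass (an order-8
    bandpass arises from a 4th-order prototype).  The comb notch is a cascade
    of second-order IIR notches at ``notch_base * k`` with a constant
    ``notch_bandwidth`` (default 2 Hz, i.e. quality factor 25 at 50 Hz), for
    harmonics up to min(bp_high, Nyquist).
    """

    bp_order: int = 8
    bp_low_hz: float = 0.15
    bp_high_hz: float = 300.0
    notch_base_hz: float = 50.0
    notch_harmonics: int = 6
    notch_bandwidth_hz: float = 2.0

    def validate(self, fs: float) -> None:
        if not (0 < self.bp_low_hz < self.bp_high_hz < fs / 2):
            raise ParameterError(
                f"bandpass edges: need 0 < bp_low < bp_high < fs/2, got "
                f"({self.bp_low_hz}, {self.bp_high_hz}) at fs={fs}"
            )
        if self.bp_order < 2 or self.bp_order % 2:
            raise ParameterError(f"bp_order: must be an even integer >= 2, got {self.bp_order}")
        if self.notch_base_hz >= fs / 2:
            raise ParameterError(
                f"notch_base_hz: {self.notch_base_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    def bandpass_sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(
            self.bp_order // 2,
            (self.bp_low_hz, self.bp_high_hz),
            btype="bandpass",
            fs=fs,
            output="sos",
        )

    def notch_frequencies(self, fs: float) -> list[float]:
        """Harmonic frequencies actually notched: capped below min(bp_high, Nyquist)."""
        cap = min(self.bp_high_hz, fs / 2 - 1.0)
        freqs = []
        for k in range(1, self.notch_harmonics + 1):
            f_k = self.notch_base_hz * k
            if f_k > cap:
                break
            freqs.append(f_k)
        return freqs

    def notch_sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        sections = []
        for f_k in self.notch_frequencies(fs):
            q = f_k / self.notch_bandwidth_hz
            b, a = sps.iirnotch(f_k, q, fs=fs)
            sections.append(np.hstack([b, a]))
        if not sections:
            raise ParameterError("notch_harmonics: no notch frequency below Nyquist/bp_high")
        return np.vstack(sections)


@dataclass(frozen=True)
class QVRConfig:
    """Quadratic-variation-reduction regularization strength (lam >= 0)."""

    lam: float = 100.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ParameterError(f"lam: must be >= 0, got {self.lam}")


def _check_signal(x: np.ndarray, min_len: int, op: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError(f"{op}: expected a 1-D signal, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ParameterError(f"{op}: input contains non-finite values")
    if len(x) < min_len:
        raise ParameterError(f"{op}: signal length {len(x)} below required minimum {min_len}")
    return x


def bandpass(x: np.ndarray, fs: float, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass; length-preserving."""
    sos = cfg.bandpass_sos(fs)
    x = _check_signal(x, 3 * cfg.bp_order + 1, "bandpass")
    # maximal padding: the 0.15 Hz edge settles over seconds, so absorb as
    # much of the transient as the signal length allows
    return sps.sosfiltfilt(sos, x, padlen=len(x) - 1)


def comb_notch(x: np.ndarray, fs: float, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Zero-phase cascade of narrow notches at the powerline base and harmonics."""
    sos = cfg.notch_sos(fs)
    x = _check_signal(x, 3 * (2 * sos.shape[0]) + 1, "comb_notch")
    return sps.sosfiltfilt(sos, x, padlen=len(x) - 1)


def qvr_detrend(x: np.ndarray, cfg: QVRConfig = QVRConfig()) -> np.ndarray:
    """Remove baseline wander: ``z = x - y`` with ``(I + lam D'D) y = x``.

    Solved in O(n) via the symmetric-banded Cholesky solver; never builds the
    dense n x n system.  ``lam = 0`` returns exactly zero (y = x); constant
    input returns exactly zero for any ``lam`` (constants lie in D's null
    space, so y reproduces them).
    """
    x = _check_signal(x, 2, "qvr_detrend")
    n = len(x)
    lam = cfg.lam
    if lam == 0.0:
        return np.zeros(n)
    # banded (upper) storage of I + lam*D'D: diagonal and one superdiagonal
    ab = np.zeros((2, n))
    ab[1, :] = 1.0 + 2.0 * lam
    ab[1, 0] = 1.0 + lam
    ab[1, -1] = 1.0 + lam
    ab[0, 1:] = -lam
    y = solveh_banded(ab, x)
    return x - y


def qvr_detrend_dense(x: np.ndarray, cfg: QVRConfig = QVRConfig()) -> np.ndarray:
    """Dense explicit-inverse QVR, ``z = [I - (I + lam D'D)^-1] x``.

    O(n^3) cross-check oracle; refuses n > DENSE_QVR_MAX_N.
    """
    x = _check_signal(x, 2, "qvr_detrend_dense")
    n = len(x)
    if n > DENSE_QVR_MAX_N:
        raise ParameterError(
            f"qvr_detrend_dense: n={n} exceeds dense-path limit {DENSE_QVR_MAX_N}"
        )
    d = np.diff(np.eye(n), axis=0)  # (n-1) x n first-difference matrix
    a = np.eye(n) + cfg.lam * d.T @ d
    return x - np.linalg.inv(a) @ x


def preprocess_recording(
    rec: RawRecording,
    cfg: FilterConfig = FilterConfig(),
    qvr: QVRConfig = QVRConfig(),
) -> RawRecording:
    """Condition every channel: bandpass -> comb notch -> QVR, in that order."""
    out = np.empty_like(rec.data)
    for ch in range(rec.n_channels):
        y = bandpass(rec.data[ch], rec.fs, cfg)
        y = comb_notch(y, rec.fs, cfg)
        out[ch] = qvr_detrend(y, qvr)
    return rec.copy_with(out)
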