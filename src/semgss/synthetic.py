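"""Synthetic multi-channel surface-EMG generator.

Silent-speech sEMG has no public reference corpus, so downstream stages are
exercised on surrogate recordings that reproduce the statistical structure the
pipeline assumes: per-channel band-limited bursts with amplitude generally
below 1 mV and spectral content at or below 300 Hz, contaminated by 50 Hz
powerline interference with harmonics, DC bias, slow baseline wander and
broadband instrumentation noise.  Word classes differ in which channels burst,
when, and in which frequency band — a stand-in for the distinct articulatory
muscle synergies of different words.

Burst synthesis: white Gaussian noise gated by a raised-cosine amplitude
envelope over the active interval, then zero-phase bandpassed to the class's
burst band.  Band-limiting last keeps the burst's power inside the band even
for very short envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "WordClassSpec",
    "NoiseSpec",
    "RawRecording",
    "ChannelEnvelope",
    "generate_sample",
    "generate_dataset",
    "default_class_specs",
    "corpus_class_proportions",
]

DEFAULT_FS = 1000.0
DEFAULT_CHANNELS = 6
DEFAULT_DURATION_S = 2.0

#: Per-class valid-sample counts of the reference 10-word corpus, used to
#: reproduce its mild class imbalance as proportions.
CORPUS_CLASS_COUNTS = (7964, 6707, 6814, 6978, 6593, 6510, 6682, 6883, 7614, 6524)


class ParameterError(ValueError):
    """A generator parameter is out of its valid range; names the field."""


@dataclass(frozen=True)
class ChannelEnvelope:
    """Burst window for one channel: onset/duration in seconds, amplitude in mV."""

    onset_s: float
    duration_s: float
    amplitude_mv: float


@dataclass(frozen=True)
class WordClassSpec:
    """Activation pattern of one word class across channels.

    Parameters
    ----------
    class_id : int
        Integer label in ``0..9``.
    envelopes : tuple of ChannelEnvelope
        One burst envelope per channel (onset, duration, amplitude in mV).
    burst_band : (float, float)
        Frequency interval of the burst activity, Hz, within [20, 300].
    channel_gains : tuple of float
        Dimensionless per-channel multipliers.
    """

    class_id: int
    envelopes: tuple[ChannelEnvelope, ...]
    burst_band: tuple[float, float]
    channel_gains: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.burst_band
        if not (0 < lo < hi <= 300.0):
            raise ParameterError(
                f"burst_band: must satisfy 0 < low < high <= 300 Hz, got {self.burst_band}"
            )
        for env in self.envelopes:
            if not (0 < env.amplitude_mv <= 1.0):
                raise ParameterError(
                    f"envelope_params: amplitude must lie in (0, 1] mV, got {env.amplitude_mv}"
                )
            if env.duration_s <= 0 or env.onset_s < 0:
                raise ParameterError(
                    "envelope_params: onset must be >= 0 and duration > 0, "
                    f"got onset={env.onset_s}, duration={env.duration_s}"
                )
        if not self.channel_gains:
            object.__setattr__(self, "channel_gains", (1.0,) * len(self.envelopes))
        if len(self.channel_gains) != len(self.envelopes):
            raise ParameterError("channel_gains: length must match envelope count")

    @property
    def n_channels(self) -> int:
        return len(self.envelopes)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: powerline, drift, DC bias and white noise.

    ``drift_freq`` must sit below the conditioning bandpass low cutoff
    (0.15 Hz by default) so the preprocessing stage can remove the wander.
    """

    powerline_amp_mv: float = 0.2
    n_harmonics: int = 3
    drift_amp_mv: float = 0.5
    drift_freq_hz: float = 0.05
    dc_offset_mv: float = 0.3
    white_noise_sd_mv: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "powerline_amp_mv",
            "drift_amp_mv",
            "dc_offset_mv",
            "white_noise_sd_mv",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: amplitude must be >= 0")
        if not (0 <= self.drift_freq_hz <= 0.5):
            raise ParameterError(f"drift_freq_hz: must lie in [0, 0.5], got {self.drift_freq_hz}")
        if self.n_harmonics < 0:
            raise ParameterError("n_harmonics: must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All contamination amplitudes zero (clean burst component only)."""
        return cls(0.0, 0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class RawRecording:
    """One labeled sEMG sample: ``data`` is channels x samples in mV."""

    data: np.ndarray
    fs: float
    label: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("data: expected a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data: contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        return RawRecording(data=data, fs=self.fs, label=self.label, seed=self.seed)


def _raised_cosine_envelope(n: int, fs: float, env: ChannelEnvelope) -> np.ndarray:
    """Tukey-like gate: raised-cosine ramps over the burst window, zero outside."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    start, stop = env.onset_s, env.onset_s + env.duration_s
    inside = (t >= start) & (t < stop)
    if not inside.any():
        return out
    phase = (t[inside] - start) / env.duration_s  # 0..1 across the burst
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out * env.amplitude_mv


def _gated_bandlimited_burst(
    rng: np.random.Generator, gate: np.ndarray, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Envelope-gated white noise, zero-phase bandpassed to ``band``.

    Band-limiting is the last step so the burst's power stays inside
    ``band`` regardless of how short the envelope is (a gate applied after
    filtering would smear short bursts across the spectrum).  The output is
    rescaled to the gated noise's total power, so the envelope amplitude
    keeps its meaning in mV.
    """
    white = rng.standard_normal(len(gate))
    gated = gate * white
    rms_in = np.sqrt(np.mean(gated**2))
    if rms_in == 0.0:
        return gated
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, gated, padlen=len(gate) - 1)
    rms_out = np.sqrt(np.mean(shaped**2))
    if rms_out > 0:
        shaped *= rms_in / rms_out
    return shaped


def generate_sample(
    spec: WordClassSpec,
    noise: NoiseSpec,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> RawRecording:
    """Generate one labeled multi-channel recording.

    Per channel: band-limited Gaussian noise shaped by the class envelope,
    plus powerline sinusoids at 50 Hz and harmonics, a drift sinusoid, a DC
    offset and white noise.  Identical inputs (including ``seed``) give
    bit-identical output.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s: must be > 0, got {duration_s}")
    if fs < 2.0 * spec.burst_band[1]:
        raise ParameterError(
            f"fs: must be >= 2 x burst_band upper edge ({2 * spec.burst_band[1]} Hz), got {fs}"
        )
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    data = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        gate = _raised_cosine_envelope(n, fs, spec.envelopes[ch])
        burst = spec.channel_gains[ch] * _gated_bandlimited_burst(rng, gate, fs, spec.burst_band)

        contamination = np.zeros(n)
        if noise.powerline_amp_mv > 0 and noise.n_harmonics > 0:
            # fixed per-channel phase so reruns are reproducible
            for k in range(1, noise.n_harmonics + 1):
                f_k = 50.0 * k
                if f_k >= fs / 2:
                    break
                phase = rng.uniform(0, 2 * np.pi)
                # harmonics fall off as 1/k, as typical of mains pickup
                contamination += (noise.powerline_amp_mv / k) * np.sin(2 * np.pi * f_k * t + phase)
        if noise.drift_amp_mv > 0 and noise.drift_freq_hz > 0:
            phase = rng.uniform(0, 2 * np.pi)
            contamination += noise.drift_amp_mv * np.sin(2 * np.pi * noise.drift_freq_hz * t + phase)
        contamination += noise.dc_offset_mv
        if noise.white_noise_sd_mv > 0:
            contamination += noise.white_noise_sd_mv * rng.standard_normal(n)

        data[ch] = burst + contamination

    return RawRecording(data=data, fs=fs, label=spec.class_id, seed=seed)


def generate_dataset(
    class_specs: list[WordClassSpec],
    n_per_class: int | list[int],
    noise: NoiseSpec | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> list[RawRecording]:
    """Generate a labeled collection, ``n_per_class`` samples for each class.

    ``n_per_class`` may be a single integer (balanced) or a per-class list.
    Each sample gets a unique seed derived from ``seed`` so the collection is
    reproducible yet samples are independent.  Storage order is grouped by
    class, in the order of ``class_specs``.
    """
    if len(class_specs) < 2:
        raise ParameterError("class_specs: need at least 2 classes")
    ids = [s.class_id for s in class_specs]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"class_specs: duplicate class_ids in {ids}")
    if noise is None:
        noise = NoiseSpec()
    if isinstance(n_per_class, int):
        counts = [n_per_class] * len(class_specs)
    else:
        counts = list(n_per_class)
        if len(counts) != len(class_specs):
            raise ParameterError("n_per_class: per-class counts must match class count")
    if any(c < 1 for c in counts):
        raise ParameterError("n_per_class: every count must be >= 1")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(sum(counts))]
    out: list[RawRecording] = []
    k = 0
    for spec, count in zip(class_specs, counts):
        for _ in range(count):
            out.append(generate_sample(spec, noise, duration_s, fs, seed=child_seeds[k]))
            k += 1
    return out


def corpus_class_proportions(n_classes: int = 10) -> np.ndarray:
    """Class proportions mirroring the reference corpus's mild imbalance."""
    counts = np.asarray(CORPUS_CLASS_COUNTS[:n_classes], dtype=float)
    return counts / counts.sum()


def default_class_specs(
    n_classes: int = 3,
    n_channels: int = DEFAULT_CHANNELS,
    duration_s: float = DEFAULT_DURATION_S,
) -> list[WordClassSpec]:
    """Deterministic family of mutually distinct word-class specs.

    Class ``k`` bursts in a class-specific band and activates a class-specific
    subset of channels with staggered onsets, so classes differ in spectral
    content, spatial pattern and timing — the three cues real word classes
    present to the decoder.
    """
    if not (2 <= n_classes <= 10):
        raise ParameterError("n_classes: supported range is 2..10")
    specs = []
    for k in range(n_classes):
        lo = 30.0 + 22.0 * k
        hi = min(lo + 60.0, 300.0)
        envelopes = []
        gains = []
        for ch in range(n_channels):
            # channels whose index is congruent to the class (mod 3) are strong
            strong = (ch % 3) == (k % 3)
            amp = 0.8 if strong else 0.15
            onset = 0.2 + 0.08 * ((ch + k) % 3)
            duration = min(0.9 + 0.1 * (k % 2), duration_s - onset - 0.05)
            envelopes.append(ChannelEnvelope(onset_s=onset, duration_s=duration, amplitude_mv=amp))
            gains.append(1.0 if strong else 0.6)
        specs.append(
            WordClassSpec(
                class_id=k,
                envelopes=tuple(envelopes),
                burst_band=(lo, hi),
                channel_gains=tuple(gains),
            )
        )
    return specs
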