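"""Container I/O: HDF5 run containers and CSV exports.

Recordings live in an HDF5 file with one group per sample
(``/samples/<index>``) holding the channels x samples matrix plus ``fs``,
``label`` and ``seed`` attributes.  Feature sets live under ``/features``
(one dataset per sample plus a labels vector).  CSV export writes one file
per recording with a ``ch1..chK`` header, one column per channel.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .features import FeatureBundle
from .synthetic import RawRecording

__all__ = [
    "save_recordings",
    "load_recordings",
    "export_recording_csv",
    "load_recording_csv",
    "save_features",
    "load_features",
    "save_spectrogram_matrices",
]


def save_recordings(path: str, recordings: list[RawRecording]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("samples")
        for i, rec in enumerate(recordings):
            g = grp.create_group(str(i))
            g.create_dataset("data", data=rec.data)
            g.attrs["fs"] = rec.fs
            g.attrs["label"] = rec.label
            g.attrs["seed"] = rec.seed
        f.attrs["n_samples"] = len(recordings)


def load_recordings(path: str) -> list[RawRecording]:
    out = []
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_samples"])
        grp = f["samples"]
        for i in range(n):
            g = grp[str(i)]
            out.append(
                RawRecording(
                    data=g["data"][()],
                    fs=float(g.attrs["fs"]),
                    label=int(g.attrs["label"]),
                    seed=int(g.attrs["seed"]),
                )
            )
    return out


def export_recording_csv(path: str, rec: RawRecording) -> None:
    cols = {f"ch{c + 1}": rec.data[c] for c in range(rec.n_channels)}
    pd.DataFrame(cols).to_csv(path, index=False)


def load_recording_csv(path: str, fs: float = 1000.0, label: int = 0) -> RawRecording:
    df = pd.read_csv(path)
    return RawRecording(data=df.to_numpy().T, fs=fs, label=label)


def save_features(path: str, bundles: list[FeatureBundle], backend: str = "", seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("features")
        labels = np.array([b.label for b in bundles], dtype=np.int64)
        grp.create_dataset("labels", data=labels)
        seqs = np.stack([b.sequence for b in bundles])
        grp.create_dataset("sequences", data=seqs)
        grp.attrs["backend"] = backend
        grp.attrs["seed"] = seed
        grp.attrs["feature_dim"] = seqs.shape[2]


def load_features(path: str) -> list[FeatureBundle]:
    with h5py.File(path, "r") as f:
        grp = f["features"]
        labels = grp["labels"][()]
        seqs = grp["sequences"][()]
    return [FeatureBundle(sequence=s, label=int(l)) for s, l in zip(seqs, labels)]


def export_features_csv(path: str, bundles: list[FeatureBundle]) -> None:
    """One row per sample: the concatenated feature vector plus a label column."""
    rows = np.stack([b.concat for b in bundles])
    df = pd.DataFrame(rows, columns=[f"f{i}" for i in range(rows.shape[1])])
    df["label"] = [b.label for b in bundles]
    df.to_csv(path, index=False)


def save_spectrogram_matrices(path: str, stacks: list) -> None:
    """Persist per-sample, per-channel power matrices under ``/spectrograms``."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("spectrograms")
        for i, stack in enumerate(stacks):
            g = grp.create_group(str(i))
            g.attrs["label"] = stack.label
            for ch, m in enumerate(stack.matrices):
                g.create_dataset(f"ch{ch + 1}", data=m)
        f.attrs["n_samples"] = len(stacks)
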