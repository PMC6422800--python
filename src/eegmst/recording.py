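"""In-memory containers for continuous and epoched multichannel recordings,
plus plain-text I/O (delimited sample matrix + JSON sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MultichannelRecording:
    """Continuous multichannel signal.

    data
        Array of shape (n_channels, n_samples), amplitudes in microvolts.
    channel_labels
        One label per channel, montage order preserved.
    fs
        Sampling rate in Hz.
    """

    data: np.ndarray
    channel_labels: list[str]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels")
        if self.data.shape[0] == 0:
            raise ValueError("empty channel set")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "MultichannelRecording":
        return MultichannelRecording(data, list(self.channel_labels), self.fs,
                                     dict(self.meta))


@dataclass
class EpochedRecording:
    """A recording cut into fixed-length, non-overlapping epochs.

    data
        Array of shape (n_epochs, n_channels, n_samples_per_epoch).
    kept_mask
        Boolean per epoch; False marks epochs rejected by artifact screening.
    """

    data: np.ndarray
    channel_labels: list[str]
    fs: float
    epoch_len_s: float
    kept_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        expected = round(self.epoch_len_s * self.fs)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} samples != "
                f"round(epoch_len_s * fs) = {expected}")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.data.shape[0],):
                raise ValueError("kept_mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def kept_data(self) -> np.ndarray:
        """(n_kept, n_channels, n_samples) view of retained epochs."""
        return self.data[self.kept_mask]


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as a tab-delimited matrix (header = channel labels,
    rows = samples) with a JSON sidecar ``<path>.json`` carrying fs and meta.
    """
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "duration_s": rec.duration_s,
        **rec.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, sep="\t")
    meta = {k: v for k, v in sidecar.items()
            if k not in ("fs", "n_channels", "n_samples", "duration_s")}
    return MultichannelRecording(df.to_numpy().T, list(df.columns),
                                 float(sidecar["fs"]), meta)
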