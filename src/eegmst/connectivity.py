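"""Phase lag index (PLI) connectivity.

The PLI between two signals is computed from the time series of their
instantaneous phase differences dphi(t_k), k = 1..N:

    PLI = | < sign[ sin( dphi(t_k) ) ] > |

where <.> is the time average and sign is the signum function, with
sign(0) = 0 exactly.  The PLI lies in [0, 1] and quantifies the asymmetry
of the phase-difference distribution around 0 mod pi: it is 1 when the
phase difference keeps a constant sign of sin(dphi) (a consistent non-zero
lag) and 0 when the distribution is symmetric — in particular for
zero-lag (volume-conducted) coupling, where dphi = 0 gives sin(dphi) = 0
term by term.

Instantaneous phase is taken from the analytic signal (Hilbert transform)
of band-filtered data, epoch by epoch.  Because the Hilbert transform is
unreliable near the ends of a finite window, a configurable fraction of
samples at each epoch edge (default 5%) is excluded from the signum
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .recording import EpochedRecording

__all__ = ["ConnectivityMatrix", "instantaneous_phase", "pli_pair",
           "pli_matrix", "average_pli", "global_pli", "EDGE_TRIM_DEFAULT"]

#: Fraction of samples dropped at each epoch edge before the signum average.
EDGE_TRIM_DEFAULT = 0.05


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal matrix of pairwise PLI values in [0, 1]."""

    values: np.ndarray
    channel_labels: list[str]
    band: str
    epoch_index: "int | str" = 0    # epoch number, or "averaged"
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.channel_labels)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}")
        if not np.allclose(v, v.T):
            raise ValueError("values must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def instantaneous_phase(epoch_signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase of each channel via the analytic signal.

    Parameters
    ----------
    epoch_signal
        Band-filtered array (..., n_samples); the Hilbert transform runs
        along the last axis.

    Returns
    -------
    Phase array of the same shape, values in (-pi, pi].

    Raises
    ------
    ValueError
        If any channel is constant (zero variance), for which phase is
        undefined.
    """
    x = np.asarray(epoch_signal, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    flat = x.reshape(-1, x.shape[-1])
    if np.any(flat.std(axis=-1) == 0):
        bad = np.nonzero(flat.std(axis=-1) == 0)[0]
        raise ValueError(f"constant (zero-variance) channel(s) {bad.tolist()}: "
                         "instantaneous phase undefined")
    return np.angle(hilbert(x, axis=-1))


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI of two equal-length phase series.

    |mean over k of sign(sin(phase_i[k] - phase_j[k]))|, with sign(0)
    contributing 0 — no epsilon thresholding, exactly as the estimator is
    defined.
    """
    phase_i = np.asarray(phase_i, dtype=np.float64)
    phase_j = np.asarray(phase_j, dtype=np.float64)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must have equal length")
    if phase_i.size == 0:
        raise ValueError("empty phase series")
    return float(abs(np.sign(np.sin(phase_i - phase_j)).mean()))


def _trim_slice(n_samples: int, edge_trim: float) -> slice:
    k = int(edge_trim * n_samples)
    return slice(k, n_samples - k if k else n_samples)


def pli_matrix(epoched: EpochedRecording, band: str = "",
               edge_trim: float = EDGE_TRIM_DEFAULT,
               pooled: bool = False) -> list[ConnectivityMatrix]:
    """Per-epoch PLI matrices over all channel pairs of the kept epochs.

    Parameters
    ----------
    epoched
        Band-filtered epoched recording; only kept epochs are used.
    band
        Band name recorded on the output matrices.
    edge_trim
        Fraction of samples excluded at each epoch edge (Hilbert edge
        effects); 0 disables trimming.
    pooled
        If True, concatenate the signum series of all kept epochs and
        return a single matrix instead of one per epoch.

    Returns
    -------
    One symmetric ConnectivityMatrix per kept epoch (or a single pooled
    matrix), entries in [0, 1], zero diagonal.
    """
    data = epoched.kept_data()
    if data.shape[0] == 0:
        raise ValueError("no kept epochs")
    phases = instantaneous_phase(data)          # (E, C, S)
    sl = _trim_slice(phases.shape[-1], edge_trim)
    phases = phases[..., sl]
    n_ep = phases.shape[0]
    # signum of sin of all pairwise phase differences, one epoch at a time
    # (keeps the (C, C, S) intermediate bounded): sin(a-b) = sin a cos b - cos a sin b
    per_epoch = np.empty((n_ep,) + (phases.shape[1],) * 2)
    for e in range(n_ep):
        sin_p, cos_p = np.sin(phases[e]), np.cos(phases[e])
        diff_sin = (sin_p[:, None, :] * cos_p[None, :, :]
                    - cos_p[:, None, :] * sin_p[None, :, :])
        per_epoch[e] = np.sign(diff_sin).mean(axis=-1)
    if pooled:
        mats = np.abs(per_epoch.mean(axis=0))[None]
    else:
        mats = np.abs(per_epoch)                # (E, C, C)
    out = []
    kept_idx = np.nonzero(epoched.kept_mask)[0]
    for e in range(mats.shape[0]):
        m = mats[e]
        np.fill_diagonal(m, 0.0)
        m = 0.5 * (m + m.T)  # exact symmetry against float noise
        out.append(ConnectivityMatrix(
            values=m,
            channel_labels=list(epoched.channel_labels),
            band=band,
            epoch_index="pooled" if pooled else int(kept_idx[e]),
            n_epochs_averaged=data.shape[0] if pooled else 1,
        ))
    return out


def average_pli(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch PLI matrices."""
    if not matrices:
        raise ValueError("empty matrix list")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous matrix shapes: {shapes}")
    mean = np.mean([m.values for m in matrices], axis=0)
    first = matrices[0]
    return ConnectivityMatrix(mean, list(first.channel_labels), first.band,
                              epoch_index="averaged",
                              n_epochs_averaged=len(matrices))


def global_pli(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Mean of the n(n-1)/2 upper-triangle entries: whole-head connectivity."""
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(v[iu].mean())
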