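"""Synthetic recordings, trees, and two-group cohorts.

The signal model is a per-channel narrowband oscillator: instantaneous
frequency jitters around the band centre (smoothed Gaussian jitter, so the
oscillation wanders within the band), and phase is its running integral.
Pairwise coupling is imposed by *sharing* a source phase: a coupled channel
mixes its own oscillator with the source oscillator delayed by a fixed
phase lag, with mixing weight equal to the coupling strength.  This gives
direct control over the phase-difference distribution that the phase lag
index measures — at strength 1 and zero noise the phase difference is
exactly the specified lag, at strength 0 the channels are independent.
Additive 1/f ("pink") noise models the broadband background.

Cohorts emulate a two-group case-control design: one recording per
subject plus a metadata row (group IA/HC, age, sex, IAT score, with IA
scores in the excessive-use range 50-79 and HC in 20-49).  Group effects
are expressed per band as (a) strength boosts on named channel pairs and
(b) a topology bias that interpolates the subject's coupling graph between
line-like (chain) and star-like (single hub) shapes; the bias can also be
tied to the subject's IAT score to induce severity correlations.
"""

from __future__ import annotations

import math
import heapq
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .bands import BandDefinition, get_band
from .montage import MONTAGE_64
from .mst import TreeGraph
from .recording import MultichannelRecording

__all__ = [
    "CouplingSpec", "GroupEffects", "CohortSpec",
    "gen_coupled_signals", "gen_tree", "gen_biased_tree", "gen_cohort",
    "iter_cohort", "inject_artifacts", "tree_to_pli_matrix",
]


# ---------------------------------------------------------------------------
# Coupled narrowband signals


@dataclass
class CouplingSpec:
    """Specification of a coupled multichannel narrowband signal.

    edges are directed (source, target, lag, strength): the target channel
    mixes ``strength`` of the source oscillator delayed by ``lag`` radians
    with ``1 - strength`` of its own.  A lag of 0 produces a zero-lag
    (phase-symmetric) pair, i.e. zero expected PLI.
    """

    n_channels: int
    band: "BandDefinition | str | tuple[float, float]" = "alpha2"
    edges: Sequence[tuple[int, int, float, float]] = ()
    noise_sd: float = 1.0          # microvolts, 1/f background
    seed: int = 0
    amplitude: float = 20.0        # microvolts, oscillator amplitude
    freq_jitter_hz: float | None = None   # default: band width / 6
    channel_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("empty channel set")
        self.band = get_band(self.band)
        seen: set[tuple[int, int]] = set()
        incoming: dict[int, float] = {}
        for i, j, lag, strength in self.edges:
            if i == j:
                raise ValueError(f"self-coupling ({i},{i}) not allowed")
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"edge ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)
            if not -math.pi < lag < math.pi:
                raise ValueError(f"lag {lag} outside (-pi, pi)")
            if not 0 <= strength <= 1:
                raise ValueError(f"strength {strength} outside [0, 1]")
            incoming[j] = incoming.get(j, 0.0) + strength
        over = {c: s for c, s in incoming.items() if s > 1 + 1e-9}
        if over:
            raise ValueError(f"total incoming strength > 1 at channels {over}")
        if self.channel_labels is not None and \
                len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")

    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        return [f"ch{i:02d}" for i in range(self.n_channels)]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit standard deviation per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _intrinsic_phases(rng: np.random.Generator, n_channels: int,
                      n_samples: int, fs: float, f_center: float,
                      jitter_hz: float) -> np.ndarray:
    """Per-channel oscillator phases: integral of a jittered frequency."""
    f_inst = np.full((n_channels, n_samples), f_center)
    if jitter_hz > 0:
        wander = gaussian_filter1d(rng.standard_normal((n_channels, n_samples)),
                                   sigma=0.1 * fs, axis=-1, mode="wrap")
        sd = wander.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        f_inst = f_inst + jitter_hz * wander / sd
    phase0 = rng.uniform(0, 2 * math.pi, size=(n_channels, 1))
    return phase0 + 2 * math.pi * np.cumsum(f_inst, axis=-1) / fs


def gen_coupled_signals(spec: CouplingSpec, duration_s: float,
                        fs: float) -> MultichannelRecording:
    """Generate a multichannel recording with the specified phase coupling.

    Raises
    ------
    ValueError
        On Nyquist violation (fs <= 2 x band upper edge) or an empty
        channel set.
    """
    band = get_band(spec.band)
    if fs <= 2 * band.high:
        raise ValueError(f"fs={fs} Hz must exceed twice the band upper edge "
                         f"({band.high} Hz)")
    n_samples = round(duration_s * fs)
    if n_samples < 2:
        raise ValueError("duration too short")
    rng = np.random.default_rng(spec.seed)
    jitter = (band.width / 6.0 if spec.freq_jitter_hz is None
              else spec.freq_jitter_hz)
    theta = _intrinsic_phases(rng, spec.n_channels, n_samples, fs,
                              band.center, jitter)

    self_weight = np.ones(spec.n_channels)
    for _, j, _, strength in spec.edges:
        self_weight[j] -= strength
    x = self_weight[:, None] * np.cos(theta)
    for i, j, lag, strength in spec.edges:
        x[j] += strength * np.cos(theta[i] - lag)
    x *= spec.amplitude
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * _pink_noise(rng, x.shape, fs)
    return MultichannelRecording(
        x, spec.labels(), fs,
        meta={"seed": spec.seed, "band": band.name,
              "n_edges": len(spec.edges)})


def inject_artifacts(recording: MultichannelRecording,
                     epoch_indices: Sequence[int],
                     epoch_len_s: float = 2.0,
                     amplitude_uv: float = 300.0,
                     channel: int = 0) -> MultichannelRecording:
    """Insert a high-amplitude spike into the middle of the given epochs on
    one channel, for exercising amplitude-based epoch rejection."""
    out = recording.copy_with(recording.data.copy())
    spe = round(epoch_len_s * recording.fs)
    for e in epoch_indices:
        t = e * spe + spe // 2
        if t >= recording.n_samples:
            raise ValueError(f"epoch {e} beyond recording end")
        out.data[channel, t] = amplitude_uv
    out.meta["artifact_epochs"] = sorted(int(e) for e in epoch_indices)
    return out


# ---------------------------------------------------------------------------
# Trees


def _prufer_to_edges(seq: Sequence[int], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence (length n - 2, labels 0..n-1) into the edge
    list of the labelled tree it encodes."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, x), max(leaf, x)))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = sorted(leaves)
    edges.append((u, v))
    return edges


def gen_tree(topology: str, n_nodes: int, seed: int = 0,
             node_labels: Sequence[str] | None = None) -> TreeGraph:
    """Generate a labelled tree of a given shape.

    topology
        "star"  — node 0 is the hub, all others attach to it;
        "path"  — chain 0-1-2-...;
        "random_tree" — uniform over labelled trees via a random Prüfer
        sequence.

    All edges carry weight 1.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if node_labels is None:
        node_labels = [f"ch{i:02d}" for i in range(n_nodes)]
    if topology == "star":
        pairs = [(0, i) for i in range(1, n_nodes)]
    elif topology == "path":
        pairs = [(i, i + 1) for i in range(n_nodes - 1)]
    elif topology == "random_tree":
        if n_nodes == 2:
            pairs = [(0, 1)]
        else:
            rng = np.random.default_rng(seed)
            seq = rng.integers(0, n_nodes, size=n_nodes - 2)
            pairs = _prufer_to_edges([int(s) for s in seq], n_nodes)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return TreeGraph(list(node_labels), [(u, v, 1.0) for u, v in pairs])


def gen_biased_tree(n_nodes: int, topology: str = "none", weight: float = 0.0,
                    hub: int = 0, seed: int = 0,
                    rng: np.random.Generator | None = None,
                    node_labels: Sequence[str] | None = None) -> TreeGraph:
    """Random attachment tree interpolating between shapes.

    Nodes attach one at a time in random order.  With probability
    ``weight`` a new node attaches to the hub ("star_bias") or to the
    previously added node ("line_bias"); otherwise to a uniformly random
    already-placed node.  weight = 0 gives a random recursive tree for any
    topology; star_bias weight = 1 gives an exact star on ``hub``;
    line_bias weight = 1 gives a chain.

    Edges are directed source -> target in attachment order (the target is
    the newcomer), which downstream signal synthesis uses to decide which
    channel inherits which phase.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if topology not in ("none", "star_bias", "line_bias"):
        raise ValueError(f"unknown topology bias {topology!r}")
    if not 0 <= weight <= 1:
        raise ValueError("bias weight must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if node_labels is None:
        node_labels = [f"ch{i:02d}" for i in range(n_nodes)]
    others = [i for i in range(n_nodes) if i != hub]
    order = [hub] + [others[k] for k in rng.permutation(len(others))]
    edges: list[tuple[int, int, float]] = []
    for k in range(1, n_nodes):
        new = order[k]
        if topology != "none" and rng.random() < weight:
            target = hub if topology == "star_bias" else order[k - 1]
        else:
            target = order[int(rng.integers(0, k))]
        edges.append((target, new, 1.0))
    return TreeGraph(list(node_labels), edges)


def tree_to_pli_matrix(tree: TreeGraph, on_weight: float = 0.8,
                       off_weight: float = 0.05) -> np.ndarray:
    """Noiseless connectivity matrix whose maximum spanning tree is exactly
    ``tree``: tree edges get ``on_weight``, all other pairs ``off_weight``."""
    n = tree.n_nodes
    if not 0 <= off_weight < on_weight <= 1:
        raise ValueError("need 0 <= off_weight < on_weight <= 1")
    m = np.full((n, n), off_weight)
    np.fill_diagonal(m, 0.0)
    for u, v, _ in tree.edges:
        m[u, v] = m[v, u] = on_weight
    return m


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class GroupEffects:
    """Per-band group-difference injection, applied to the IA group.

    pli_edge_boost
        (channel_a, channel_b, delta_strength) triples: extra coupling
        strength on that pair for IA subjects.
    topology / bias_weight
        Extra topology bias for IA subjects: "star_bias" pushes the IA
        coupling graph toward a single-hub star (raising downstream MaxDeg,
        Kappa and lowering Diameter, Eccentricity), "line_bias" toward a
        chain.
    hub
        Hub channel label for star_bias (default: first montage channel).
    """

    pli_edge_boost: Sequence[tuple[str, str, float]] = ()
    topology: str = "none"
    bias_weight: float = 0.0
    hub: str | None = None


@dataclass
class CohortSpec:
    """A two-group synthetic cohort.

    Defaults emulate the study design this package targets: 30 subjects
    per group on the 64-channel montage, 500 Hz, 6 min eyes-closed, IAT
    scores 59.0 +/- 7.88 (IA, clipped to the excessive-use range 50-79)
    versus 34.4 +/- 8.53 (HC, clipped to 20-49), ages ~21 +/- 2, and a
    sex ratio of roughly 7:23 male:female.  Desk-scale analyses override
    n_per_group / channel_labels / fs / duration_s explicitly.
    """

    n_per_group: int = 30
    channel_labels: Sequence[str] = MONTAGE_64
    fs: float = 500.0
    duration_s: float = 360.0
    signal_bands: Sequence[str] = ("alpha2",)
    group_effects: dict[str, GroupEffects] = field(default_factory=dict)
    base_strength: float = 0.55
    strength_jitter: float = 0.10
    base_bias: float = 0.0                # shared (HC) star-bias weight
    bias_sd: float = 0.08                 # subject-level bias noise
    iat_bias_slope: float = 0.0           # adds slope*(iat-60)/40 to star bias
    noise_sd: float = 4.0
    amplitude: float = 20.0
    iat_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"IA": (59.0, 7.88), "HC": (34.4, 8.53)})
    iat_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"IA": (50, 79), "HC": (20, 49)})
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"IA": (21.0, 2.13), "HC": (20.5, 1.59)})
    sex_ratio: dict[str, float] = field(
        default_factory=lambda: {"IA": 7 / 30, "HC": 6 / 30})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for band in self.group_effects:
            get_band(band)  # validates the name
        for band in self.signal_bands:
            get_band(band)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def _sample_iat(rng: np.random.Generator, group: str,
                spec: CohortSpec) -> int:
    mean, sd = spec.iat_params[group]
    lo, hi = spec.iat_ranges[group]
    for _ in range(1000):
        score = int(round(rng.normal(mean, sd)))
        if lo <= score <= hi:
            return score
    return int(np.clip(round(mean), lo, hi))


def _subject_metadata(rng: np.random.Generator, group: str, idx: int,
                      spec: CohortSpec) -> dict:
    mean_age, sd_age = spec.age_params[group]
    return {
        "subject_id": f"{group}{idx:03d}",
        "group": group,
        "age": float(np.clip(rng.normal(mean_age, sd_age), 17, 35)),
        "sex": "M" if rng.random() < spec.sex_ratio[group] else "F",
        "iat": _sample_iat(rng, group, spec),
    }


def _subject_coupling(rng: np.random.Generator, group: str, iat: int,
                      band: str, spec: CohortSpec,
                      seed: int) -> CouplingSpec:
    """Draw one subject's coupling graph for one band."""
    eff = spec.group_effects.get(band, GroupEffects())
    labels = list(spec.channel_labels)
    n = len(labels)

    # both groups run the same biased-attachment process (exchangeable under
    # the null); only the bias weight differs between groups
    w = float(spec.base_bias)
    topology = "star_bias"
    if group == "IA" and eff.topology != "none":
        w += eff.bias_weight
        topology = eff.topology
    w += spec.iat_bias_slope * (iat - 60.0) / 40.0
    w += rng.normal(0.0, spec.bias_sd)
    w = float(np.clip(w, 0.0, 1.0))

    hub_idx = labels.index(eff.hub) if eff.hub is not None else 0
    tree = gen_biased_tree(n, topology, w, hub=hub_idx, rng=rng)

    edges: list[tuple[int, int, float, float]] = []
    strength_in: dict[int, float] = {}
    for src, dst, _ in tree.edges:
        s = float(np.clip(rng.normal(spec.base_strength, spec.strength_jitter),
                          0.05, 0.95))
        lag = float(rng.uniform(0.15 * math.pi, 0.85 * math.pi)
                    * (1 if rng.random() < 0.5 else -1))
        edges.append((src, dst, lag, s))
        strength_in[dst] = strength_in.get(dst, 0.0) + s

    if group == "IA":
        existing = {(min(i, j), max(i, j)) for i, j, _, _ in edges}
        for ch_a, ch_b, delta in eff.pli_edge_boost:
            a, b = labels.index(ch_a), labels.index(ch_b)
            key = (min(a, b), max(a, b))
            if key in existing:
                edges = [(i, j, lag, min(0.95, s + delta))
                         if (min(i, j), max(i, j)) == key else (i, j, lag, s)
                         for i, j, lag, s in edges]
            else:
                room = 0.95 - strength_in.get(b, 0.0)
                s = float(np.clip(delta, 0.0, max(room, 0.0)))
                if s > 0:
                    lag = float(rng.uniform(0.15 * math.pi, 0.85 * math.pi))
                    edges.append((a, b, lag, s))
                    strength_in[b] = strength_in.get(b, 0.0) + s
                    existing.add(key)

    return CouplingSpec(n_channels=n, band=band, edges=edges,
                        noise_sd=spec.noise_sd, seed=seed,
                        amplitude=spec.amplitude, channel_labels=labels)


def iter_cohort(spec: CohortSpec) -> Iterator[tuple[dict, MultichannelRecording]]:
    """Yield (metadata_row, recording) per subject, IA group first.

    Recordings are generated lazily so that full-scale cohorts (64
    channels, 6 minutes, 60 subjects) never need to be resident in memory
    at once.  Fixed spec.seed gives bit-identical output.
    """
    master = np.random.SeedSequence(spec.seed)
    subject_seeds = master.spawn(2 * spec.n_per_group)
    k = 0
    for group in ("IA", "HC"):
        for idx in range(spec.n_per_group):
            ss = subject_seeds[k]
            k += 1
            rng = np.random.default_rng(ss)
            meta = _subject_metadata(rng, group, idx, spec)
            x = None
            labels = list(spec.channel_labels)
            band_seeds = ss.spawn(len(spec.signal_bands))
            for band, bseed in zip(spec.signal_bands, band_seeds):
                cspec = _subject_coupling(
                    rng, group, meta["iat"], band, spec,
                    seed=int(bseed.generate_state(1)[0] % (2 ** 31)))
                rec = gen_coupled_signals(cspec, spec.duration_s, spec.fs)
                x = rec.data if x is None else x + rec.data
            recording = MultichannelRecording(
                x, labels, spec.fs,
                meta={"subject_id": meta["subject_id"], "group": group,
                      "cohort_seed": spec.seed})
            yield meta, recording


def gen_cohort(spec: CohortSpec) -> tuple[list[MultichannelRecording], pd.DataFrame]:
    """Materialise a full cohort: recordings list + metadata table.

    For large specs prefer :func:`iter_cohort`, which streams subjects.
    """
    metas, recs = [], []
    for meta, rec in iter_cohort(spec):
        metas.append(meta)
        recs.append(rec)
    return recs, pd.DataFrame(metas)
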