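"""End-to-end orchestration: recording -> band-limited PLI -> spanning tree
-> epoch-averaged metrics -> cohort metric table -> group statistics.

The unit of statistical analysis is the metric table: one row per subject
and band carrying metadata (group, age, sex, IAT), the band-power
covariate, global PLI, and the eight epoch-averaged tree measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import BROADBAND, get_band
from .connectivity import (EDGE_TRIM_DEFAULT, average_pli, global_pli,
                           pli_matrix)
from .mst import (GlobalMSTMetrics, epoch_average_metrics, find_hub,
                  global_metrics, max_spanning_tree, nodal_metrics)
from .preprocess import band_power, bandpass, reject_epochs, segment
from .recording import MultichannelRecording
from .stats import (BONFERRONI_M, ancova, bonferroni, regional_ttest,
                    severity_correlation)
from .synth import CohortSpec, iter_cohort

__all__ = ["SubjectBandResult", "CohortResult", "GLOBAL_MEASURES",
           "analyze_subject", "analyze_cohort", "group_statistics",
           "severity_table", "hub_report", "regional_comparison"]

#: Global measures entering the per-band statistical family, in report order.
GLOBAL_MEASURES = ("pli", "max_degree", "ecc", "max_bc", "kappa", "r",
                   "diameter", "leaf", "th")


@dataclass
class SubjectBandResult:
    """Epoch-averaged outputs of one subject in one band."""

    band: str
    pli: float                       # whole-head mean PLI
    metrics: GlobalMSTMetrics        # epoch-averaged tree measures
    band_power: float
    nodal_degree: np.ndarray         # (n_channels,), epoch-averaged
    nodal_bc: np.ndarray
    n_epochs: int
    n_epochs_kept: int
    avg_matrix: np.ndarray | None = None


def analyze_subject(rec: MultichannelRecording,
                    bands: Sequence[str] = ("alpha2",),
                    epoch_len_s: float = 2.0,
                    amp_threshold_uv: float = 150.0,
                    min_epochs: int = 80,
                    edge_trim: float = EDGE_TRIM_DEFAULT,
                    broadband_prefilter: bool = True,
                    pooled: bool = False,
                    keep_matrices: bool = False,
                    subject_id: str = "") -> dict[str, SubjectBandResult]:
    """Run the single-subject pipeline for each requested band.

    The amplitude-rejection mask is computed once on the broadband signal
    (artifact screening happens before narrowband decomposition) and
    re-applied to every band's epochs.  Each kept epoch yields a PLI
    matrix and a maximum spanning tree; global and nodal tree measures are
    averaged across epochs.
    """
    base = rec
    if broadband_prefilter and BROADBAND.high < rec.fs / 2:
        base = bandpass(rec, BROADBAND)
    broadband_epochs = reject_epochs(segment(base, epoch_len_s),
                                     amp_threshold_uv, min_epochs,
                                     subject_id=subject_id)
    mask = broadband_epochs.kept_mask
    out: dict[str, SubjectBandResult] = {}
    for band_name in bands:
        band = get_band(band_name)
        filtered = bandpass(base, band)
        epochs = segment(filtered, epoch_len_s)
        epochs.kept_mask = mask.copy()
        if mask.sum() == 0:
            raise ValueError(f"no kept epochs for subject {subject_id!r}")
        mats = pli_matrix(epochs, band=band.name, edge_trim=edge_trim,
                          pooled=pooled)
        per_epoch_global = []
        per_epoch_deg = np.empty((len(mats), rec.n_channels))
        per_epoch_bc = np.empty((len(mats), rec.n_channels))
        for e, mat in enumerate(mats):
            tree = max_spanning_tree(mat.values, mat.channel_labels)
            nod = nodal_metrics(tree)
            per_epoch_global.append(global_metrics(tree, nod))
            per_epoch_deg[e] = nod.degree
            per_epoch_bc[e] = nod.bc
        avg = average_pli(mats)
        out[band.name] = SubjectBandResult(
            band=band.name,
            pli=global_pli(avg),
            metrics=epoch_average_metrics(per_epoch_global),
            band_power=band_power(epochs, band),
            nodal_degree=per_epoch_deg.mean(axis=0),
            nodal_bc=per_epoch_bc.mean(axis=0),
            n_epochs=epochs.n_epochs,
            n_epochs_kept=int(mask.sum()),
            avg_matrix=avg.values if keep_matrices else None,
        )
    return out


@dataclass
class CohortResult:
    """Cohort-level analysis products."""

    metric_table: pd.DataFrame           # one row per subject x band
    metadata: pd.DataFrame               # one row per subject
    channel_labels: list[str]
    nodal_degree: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    nodal_bc: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # keys: (band, group) -> (n_subjects, n_channels)


def analyze_cohort(subjects: "CohortSpec | Iterable[tuple[dict, MultichannelRecording]]",
                   bands: Sequence[str] = ("alpha2",),
                   **subject_kwargs) -> CohortResult:
    """Analyse every subject of a cohort and assemble the metric table.

    ``subjects`` is either a :class:`CohortSpec` (generated lazily) or an
    iterable of (metadata_row, recording) pairs; metadata rows must carry
    subject_id, group, age, sex, iat.
    """
    if isinstance(subjects, CohortSpec):
        subjects = iter_cohort(subjects)
    rows = []
    metas = []
    deg_acc: dict[tuple[str, str], list[np.ndarray]] = {}
    bc_acc: dict[tuple[str, str], list[np.ndarray]] = {}
    labels: list[str] = []
    for meta, rec in subjects:
        labels = list(rec.channel_labels)
        metas.append(meta)
        results = analyze_subject(rec, bands=bands,
                                  subject_id=str(meta.get("subject_id", "")),
                                  **subject_kwargs)
        for band_name, res in results.items():
            row = {**{k: meta[k] for k in
                      ("subject_id", "group", "age", "sex", "iat")},
                   "band": band_name, "band_power": res.band_power,
                   "pli": res.pli,
                   "n_epochs": res.n_epochs,
                   "n_epochs_kept": res.n_epochs_kept,
                   **res.metrics.as_dict()}
            rows.append(row)
            key = (band_name, meta["group"])
            deg_acc.setdefault(key, []).append(res.nodal_degree)
            bc_acc.setdefault(key, []).append(res.nodal_bc)
    return CohortResult(
        metric_table=pd.DataFrame(rows),
        metadata=pd.DataFrame(metas),
        channel_labels=labels,
        nodal_degree={k: np.vstack(v) for k, v in deg_acc.items()},
        nodal_bc={k: np.vstack(v) for k, v in bc_acc.items()},
    )


def group_statistics(metric_table: pd.DataFrame,
                     measures: Sequence[str] = GLOBAL_MEASURES,
                     m: int = BONFERRONI_M,
                     log_power: bool = True) -> pd.DataFrame:
    """Per-band ANCOVA of each global measure, Bonferroni-corrected per band.

    Produces the familiar group-comparison layout: per measure and band the
    group means/SDs, F, p, Bonferroni-adjusted p, partial eta-squared, and
    direction.  Rows with an undefined measure (NaN, e.g. degree
    correlation on degenerate trees) are dropped listwise for that measure
    with the count recorded.
    """
    out_rows = []
    for band_name, sub in metric_table.groupby("band", sort=False):
        band_results = []
        for measure in measures:
            vals = sub[measure].to_numpy(float)
            ok = np.isfinite(vals)
            d = sub[ok]
            res = ancova(
                d[measure].to_numpy(float), d["group"].to_numpy(),
                covariates=d[["age", "sex", "band_power"]],
                measure=measure, band=band_name, log_power=log_power)
            res.notes = f"n_dropped={int((~ok).sum())}" if (~ok).any() else ""
            band_results.append(res)
        p_adj, threshold = bonferroni([r.p for r in band_results], m=m)
        for res, adj in zip(band_results, p_adj):
            res.p_adjusted = float(adj)
            out_rows.append({
                "band": res.band, "measure": res.measure,
                "mean_IA": res.group_means.get("IA", np.nan),
                "sd_IA": res.group_sds.get("IA", np.nan),
                "mean_HC": res.group_means.get("HC", np.nan),
                "sd_HC": res.group_sds.get("HC", np.nan),
                "F": res.stat, "p": res.p, "p_adjusted": res.p_adjusted,
                "eta_sq_partial": res.effect, "direction": res.direction,
                "bonferroni_threshold": threshold, "notes": res.notes,
            })
    return pd.DataFrame(out_rows)


def severity_table(metric_table: pd.DataFrame,
                   measures: Sequence[str] = GLOBAL_MEASURES) -> pd.DataFrame:
    """Pearson correlation of each global measure with the IAT score,
    per band (severity association layout)."""
    rows = []
    for band_name, sub in metric_table.groupby("band", sort=False):
        for measure in measures:
            vals = sub[measure].to_numpy(float)
            ok = np.isfinite(vals)
            res = severity_correlation(vals[ok],
                                       sub["iat"].to_numpy(float)[ok],
                                       measure=measure, band=band_name)
            rows.append({"band": band_name, "measure": measure,
                         "r": res.stat, "p": res.p,
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)


def hub_report(cohort: CohortResult) -> pd.DataFrame:
    """Hub channel per band, group, and statistic (max of group-mean nodal
    degree / betweenness)."""
    rows = []
    for (band, group), deg in sorted(cohort.nodal_degree.items()):
        rows.append({"band": band, "group": group, "statistic": "degree",
                     "hub": find_hub(deg, cohort.channel_labels)})
        bc = cohort.nodal_bc[(band, group)]
        rows.append({"band": band, "group": group, "statistic": "bc",
                     "hub": find_hub(bc, cohort.channel_labels)})
    return pd.DataFrame(rows)


def regional_comparison(cohort: CohortResult, band: str,
                        welch: bool = False) -> pd.DataFrame:
    """Per-channel two-sample t tests (IA vs HC) on nodal degree and
    betweenness in one band."""
    frames = []
    for measure, table in (("degree", cohort.nodal_degree),
                           ("bc", cohort.nodal_bc)):
        frames.append(regional_ttest(
            table[(band, "IA")], table[(band, "HC")],
            cohort.channel_labels, measure=measure, band=band, welch=welch))
    return pd.concat(frames, ignore_index=True)
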